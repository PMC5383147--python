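"""Domain types and closed-form building blocks shared by the solver and the
analytic layer.

Unit conventions (fixed for the whole package)
----------------------------------------------
depth ``z``            cm internally (CLI and exports use µm)
RF concentration ``C`` weight percent (%)
intensity ``I``        mW/cm²
time ``t``             s
dose ``E``             mJ/cm²  (1 mW/cm² × 1 s = 1 mJ/cm²)
extinction ``ε``       (%·cm)⁻¹
background ``Q``       cm⁻¹
rate constant ``a``    cm²·mJ⁻¹, so that ``a·I`` is s⁻¹ and ``a·E`` is
                       dimensionless
chain ratio ``K``      (%·s)⁻¹, so that ``K·a·C·I`` is s⁻²

With these conventions the photolysis rate constant is

    a = 83.6 · λ · φ · ε₁          (λ in cm)

giving a = 0.6225·φ cm²/mJ at λ = 365 nm, ε₁ = 204 (%·cm)⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import math

import numpy as np
import yaml

__all__ = [
    "InvalidParameterError",
    "PhotochemParams",
    "RiboflavinProfile",
    "IrradiationProtocol",
    "Grid1D",
    "derive_a",
    "rf_shape_F",
    "rf_shape_G",
    "absorption_A",
    "mean_attenuation_H",
]

#: Numeric prefactor of the photolysis rate constant a = 83.6·λ·φ·ε₁.
A_PREFACTOR = 83.6

CM_PER_UM = 1e-4


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def derive_a(params: "PhotochemParams") -> float:
    """Photolysis rate constant a = 83.6·λ·φ·ε₁ in cm²·mJ⁻¹.

    ``a·E`` (E in mJ/cm²) is the dimensionless exponent of riboflavin
    depletion, C = C₀F(z)·exp(−aE); ``a·I`` is the surface depletion rate
    in s⁻¹.
    """
    _require(params.phi > 0, f"quantum yield must be positive, got {params.phi}")
    _require(params.epsilon1 > 0, f"epsilon1 must be positive, got {params.epsilon1}")
    return A_PREFACTOR * params.lambda_uv * params.phi * params.epsilon1


@dataclass(frozen=True)
class PhotochemParams:
    """Physical constants of the riboflavin/UVA photoreaction.

    Parameters
    ----------
    epsilon1 : float
        Extinction coefficient of unreacted riboflavin, (%·cm)⁻¹.
    epsilon2 : float
        Extinction coefficient of the photolysis product, (%·cm)⁻¹.
        Measured estimates range 80–120; steady-state scenario work in this
        package uses 50 unless overridden.
    Q : float
        Background stromal absorption (RF-independent), cm⁻¹.
    phi : float
        Quantum yield of riboflavin photolysis, in (0, 1].
    lambda_uv : float
        UV wavelength in cm (default 365 nm UVA).
    K : float
        Ratio of polymer-chain growth to termination rate constants,
        (%·s)⁻¹.  Scales the efficacy exponent S uniformly; orderings and
        ratios of profiles are K-invariant.
    """

    epsilon1: float = 204.0
    epsilon2: float = 50.0
    Q: float = 13.9
    phi: float = 0.5
    lambda_uv: float = 3.65e-5
    K: float = 1.0

    def __post_init__(self) -> None:
        _require(self.epsilon1 > 0, f"epsilon1 must be > 0, got {self.epsilon1}")
        _require(self.epsilon2 >= 0, f"epsilon2 must be >= 0, got {self.epsilon2}")
        _require(self.Q >= 0, f"Q must be >= 0, got {self.Q}")
        _require(0 < self.phi <= 1, f"phi must be in (0, 1], got {self.phi}")
        _require(self.lambda_uv > 0, f"lambda_uv must be > 0, got {self.lambda_uv}")
        _require(self.K > 0, f"K must be > 0, got {self.K}")

    @property
    def a(self) -> float:
        """Derived photolysis rate constant, cm²·mJ⁻¹ (always recomputed)."""
        return derive_a(self)


@dataclass(frozen=True)
class RiboflavinProfile:
    """Pre-soak riboflavin depth distribution C₀·F(z).

    ``C0`` is the surface concentration in weight % and ``D`` the diffusion
    depth in cm, defined as the half-width at half maximum of the linear
    ramp: F(D) = 0.5.  F is clamped at zero below z = 2D.
    """

    C0: float = 0.1
    D: float = 0.05

    def __post_init__(self) -> None:
        _require(self.C0 > 0, f"C0 must be > 0, got {self.C0}")
        _require(self.D > 0, f"D must be > 0, got {self.D}")

    def F(self, z):
        return rf_shape_F(z, self)

    def G(self, z):
        return rf_shape_G(z, self)

    def concentration(self, z):
        """Initial concentration C₀·F(z) in weight %."""
        return self.C0 * rf_shape_F(z, self)


def rf_shape_F(z, profile: RiboflavinProfile):
    """Riboflavin shape function F(z) = max(0, 1 − 0.5 z/D).

    Accepts scalars or arrays; z in cm, z ≥ 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise InvalidParameterError("depth z must be non-negative")
    out = np.clip(1.0 - 0.5 * z / profile.D, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def rf_shape_G(z, profile: RiboflavinProfile):
    """Running depth-mean of F: G(z) = (1/z)∫₀ᶻ F(z′)dz′.

    Equals 1 − 0.25 z/D on z ≤ 2D; for z > 2D the clamped F integrates to a
    constant D, so G continues as D/z.  G(0) = 1 by the limit.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise InvalidParameterError("depth z must be non-negative")
    D = profile.D
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(z <= 2.0 * D, 1.0 - 0.25 * z / D, D / np.maximum(z, 1e-300))
    return float(out) if out.ndim == 0 else out


def absorption_A(which: str, z, profile: RiboflavinProfile, params: PhotochemParams):
    """Napierian absorption coefficient Aⱼ(z) = 2.3[Q + εⱼ·C₀·G(z)], cm⁻¹.

    ``which='initial'`` uses ε₁ (unbleached riboflavin, t = 0);
    ``which='steady'`` uses ε₂ (fully photolysed, t → ∞).
    """
    if which == "initial":
        eps = params.epsilon1
    elif which == "steady":
        eps = params.epsilon2
    else:
        raise InvalidParameterError(f"which must be 'initial' or 'steady', got {which!r}")
    G = rf_shape_G(z, profile)
    return 2.3 * (params.Q + eps * profile.C0 * G)


def mean_attenuation_H(z, profile: RiboflavinProfile, params: PhotochemParams):
    """Mean attenuation H(z) = ½[exp(−A₁z) + exp(−A₂z)], dimensionless.

    The average of the initial and steady-state Beer–Lambert factors; the
    analytic efficacy layer uses I(z) ≈ I₀·H(z).
    """
    z = np.asarray(z, dtype=float)
    A1 = absorption_A("initial", z, profile, params)
    A2 = absorption_A("steady", z, profile, params)
    out = 0.5 * (np.exp(-A1 * z) + np.exp(-A2 * z))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IrradiationProtocol:
    """UV irradiation settings.

    ``I0`` surface intensity (mW/cm²), ``t_end`` exposure time (s);
    ``d_epi`` epithelium thickness in cm with absorption coefficient
    ``A_epi`` (cm⁻¹) for epi-on treatment — the intact epithelium attenuates
    the stromal surface intensity by exp(−A_epi·d_epi).  ``d_epi = 0`` is
    the epi-off case.
    """

    I0: float = 10.0
    t_end: float = 10.0
    d_epi: float = 0.0
    A_epi: float = 32.0

    def __post_init__(self) -> None:
        _require(self.I0 > 0, f"I0 must be > 0, got {self.I0}")
        _require(self.t_end > 0, f"t_end must be > 0, got {self.t_end}")
        _require(self.d_epi >= 0, f"d_epi must be >= 0, got {self.d_epi}")
        _require(self.A_epi >= 0, f"A_epi must be >= 0, got {self.A_epi}")

    @property
    def E0(self) -> float:
        """Surface dose I₀·t_end in mJ/cm²."""
        return self.I0 * self.t_end

    @property
    def I0_effective(self) -> float:
        """Intensity reaching the stromal surface: I₀·exp(−A_epi·d_epi)."""
        return self.I0 * math.exp(-self.A_epi * self.d_epi)


#: Splitting-accuracy contract for the time step: a·I₀·dt must not exceed this.
STABILITY_LIMIT = 0.05


@dataclass(frozen=True)
class Grid1D:
    """Uniform space–time grid for the finite-difference solver.

    ``dz``/``z_max`` in cm, ``dt`` in s.  The solver requires
    a·I₀·dt ≤ 0.05 so that the per-step riboflavin depletion stays small
    (operator-splitting accuracy, not stability — the exponential update is
    unconditionally stable).
    """

    z_max: float = 0.05
    dz: float = 1e-4
    dt: float = 0.01

    def __post_init__(self) -> None:
        _require(self.dz > 0, f"dz must be > 0, got {self.dz}")
        _require(self.dt > 0, f"dt must be > 0, got {self.dt}")
        _require(self.z_max >= self.dz, "z_max must be at least dz")

    @property
    def nz(self) -> int:
        return round(self.z_max / self.dz) + 1

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.nz) * self.dz

    def n_steps(self, t_end: float) -> int:
        return max(1, math.ceil(t_end / self.dt - 1e-9))

    @classmethod
    def for_protocol(
        cls,
        params: PhotochemParams,
        protocol: IrradiationProtocol,
        z_max: float = 0.05,
        dz: float = 1e-4,
        margin: float = STABILITY_LIMIT,
    ) -> "Grid1D":
        """Grid with dt chosen from the contract a·I₀·dt = ``margin``."""
        dt = margin / (params.a * protocol.I0)
        return cls(z_max=z_max, dz=dz, dt=dt)

    def halved(self) -> "Grid1D":
        return Grid1D(z_max=self.z_max, dz=self.dz / 2, dt=self.dt / 2)


# ---------------------------------------------------------------------------
# Flat config serialization with unit-suffixed keys
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    # key -> (dataclass, field name, scale factor internal = key_value * scale)
    "epsilon1_per_pct_cm": (PhotochemParams, "epsilon1", 1.0),
    "epsilon2_per_pct_cm": (PhotochemParams, "epsilon2", 1.0),
    "Q_per_cm": (PhotochemParams, "Q", 1.0),
    "phi": (PhotochemParams, "phi", 1.0),
    "lambda_nm": (PhotochemParams, "lambda_uv", 1e-7),
    "K_per_pct_s": (PhotochemParams, "K", 1.0),
    "C0_pct": (RiboflavinProfile, "C0", 1.0),
    "D_um": (RiboflavinProfile, "D", CM_PER_UM),
    "I0_mW_cm2": (IrradiationProtocol, "I0", 1.0),
    "t_s": (IrradiationProtocol, "t_end", 1.0),
    "d_epi_um": (IrradiationProtocol, "d_epi", CM_PER_UM),
    "A_epi_per_cm": (IrradiationProtocol, "A_epi", 1.0),
    "z_max_um": (Grid1D, "z_max", CM_PER_UM),
    "dz_um": (Grid1D, "dz", CM_PER_UM),
    "dt_s": (Grid1D, "dt", 1.0),
}


def to_config_dict(
    params: PhotochemParams,
    profile: RiboflavinProfile,
    protocol: IrradiationProtocol,
    grid: Grid1D | None = None,
) -> dict:
    """Flatten a parameter set to a dict with unit-suffixed keys."""
    objs = {PhotochemParams: params, RiboflavinProfile: profile, IrradiationProtocol: protocol}
    if grid is not None:
        objs[Grid1D] = grid
    out = {}
    for key, (cls, name, scale) in _CONFIG_FIELDS.items():
        if cls in objs:
            out[key] = getattr(objs[cls], name) / scale
    return out


def from_config_dict(cfg: dict, with_grid: bool = False):
    """Build (params, profile, protocol[, grid]) from a flat unit-suffixed dict.

    Unknown keys are rejected; missing keys take the dataclass defaults.
    """
    unknown = set(cfg) - set(_CONFIG_FIELDS)
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[type, dict] = {PhotochemParams: {}, RiboflavinProfile: {}, IrradiationProtocol: {}, Grid1D: {}}
    for key, value in cfg.items():
        cls, name, scale = _CONFIG_FIELDS[key]
        kwargs[cls][name] = float(value) * scale
    out = [
        PhotochemParams(**kwargs[PhotochemParams]),
        RiboflavinProfile(**kwargs[RiboflavinProfile]),
        IrradiationProtocol(**kwargs[IrradiationProtocol]),
    ]
    if with_grid:
        out.append(Grid1D(**kwargs[Grid1D]) if kwargs[Grid1D] else None)
    return tuple(out)


def save_config(path, params, profile, protocol, grid=None) -> None:
    """Write a YAML (or .json) config file with unit-suffixed keys."""
    cfg = to_config_dict(params, profile, protocol, grid)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path, with_grid: bool = False):
    """Read a YAML or JSON config file written by :func:`save_config`."""
    path = str(path)
    with open(path) as fh:
        cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg:
        raise InvalidParameterError(f"empty or malformed config file: {path}")
    return from_config_dict(cfg, with_grid=with_grid)
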