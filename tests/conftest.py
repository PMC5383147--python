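"""Shared fixtures: canonical parameter sets and pre-solved fields.

Solver runs are session-scoped so the expensive scenarios are computed once
and shared across test modules.  Everything is deterministic — there is no
randomness anywhere in the pipeline.
"""

import pytest

from cxlsim import (
    Grid1D,
    IrradiationProtocol,
    PhotochemParams,
    RiboflavinProfile,
    solve,
    solve_to_steady_state,
)


@pytest.fixture(scope="session")
def params():
    """Default photochemistry: ε₁=204, ε₂=50, Q=13.9, φ=0.5, λ=365 nm, K=1."""
    return PhotochemParams()


@pytest.fixture(scope="session")
def rf01():
    """Standard soak: C₀ = 0.1 %, D = 500 µm."""
    return RiboflavinProfile(C0=0.1, D=0.05)


@pytest.fixture(scope="session")
def rf02():
    """High-concentration soak: C₀ = 0.2 %, D = 500 µm."""
    return RiboflavinProfile(C0=0.2, D=0.05)


@pytest.fixture(scope="session")
def proto_10mw():
    """10 mW/cm² for 10 s (the transient-profile workhorse)."""
    return IrradiationProtocol(I0=10.0, t_end=10.0)


@pytest.fixture(scope="session")
def fields_10mw(params, rf01, proto_10mw):
    """Solved fields for the standard transient scenario."""
    return solve(params, rf01, proto_10mw)


@pytest.fixture(scope="session")
def fields_10mw_c02(params, rf02, proto_10mw):
    """Same irradiation, doubled riboflavin concentration."""
    return solve(params, rf02, proto_10mw)


@pytest.fixture(scope="session")
def steady_10mw(params, rf01):
    """Fully depleted (steady-state) run at 10 mW/cm²."""
    fields, converged = solve_to_steady_state(params, rf01, 10.0)
    assert converged
    return fields


@pytest.fixture(scope="session")
def oracle_setup():
    """Idealized configuration with a closed-form solution: Q=0, ε₂=0, F≡1."""
    params = PhotochemParams(Q=0.0, epsilon2=0.0)
    profile = RiboflavinProfile(C0=0.1, D=1e6)    # D >> stromal depth: F ≈ 1
    protocol = IrradiationProtocol(I0=10.0, t_end=30.0)
    return params, profile, protocol


@pytest.fixture(scope="session")
def oracle_fields(oracle_setup):
    params, profile, protocol = oracle_setup
    return solve(params, profile, protocol, Grid1D.for_protocol(params, protocol))
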