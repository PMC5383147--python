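"""Effect of intra-operative corneal thinning on the optimal crosslink depth.

Thinning during UV exposure makes the riboflavin soak effectively deeper
relative to the remaining stroma; the package models this as an increase of
the diffusion depth D.  Two otherwise identical runs (10 mW/cm², 10 s,
0.1 % RF) with D = 300 µm and D = 400 µm show the optimum moving deeper.
"""

from cxlsim import IrradiationProtocol, PhotochemParams, thinning_scenario

params = PhotochemParams()
protocol = IrradiationProtocol(I0=10.0, t_end=10.0)

res = thinning_scenario(D_before=0.03, D_after=0.04, params=params, protocol=protocol)
print(f"D = {res.D_before * 1e4:.0f} µm : z* = {res.before.z_star * 1e4:.0f} µm, "
      f"Ceff(z*) = {res.before.Ceff_max:.3f}")
print(f"D = {res.D_after * 1e4:.0f} µm : z* = {res.after.z_star * 1e4:.0f} µm, "
      f"Ceff(z*) = {res.after.Ceff_max:.3f}")
print(f"Δz* = {res.delta_z_star * 1e4:+.0f} µm — a 100 µm thinning (D 300→400 µm) "
      "deepens the crosslinked zone.")
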