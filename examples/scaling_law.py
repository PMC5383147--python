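"""Square-root dose–rate scaling versus Bunsen–Roscoe reciprocity.

Reciprocity (equal dose ⇒ equal effect) would let an accelerated protocol
scale exposure time as 1/I₀.  In this model the steady-state efficacy
exponent scales as √(C₀/I₀), so equal efficacy requires t ∝ I₀^(−1/2):
quadrupling the intensity only halves the time.  A dose-matched fast
protocol therefore under-delivers — quantified here as the efficacy
shortfall at the higher intensity.
"""

from cxlsim import PhotochemParams, RiboflavinProfile, compare_scaling_laws

params = PhotochemParams()
rf = RiboflavinProfile(C0=0.1, D=0.05)

cmp = compare_scaling_laws(target=0.10, z=0.0, I0_base=9.0, I0_alt=30.0,
                           params=params, profile=rf)
print(f"target surface efficacy      : {cmp.target:.2f}")
print(f"time at {cmp.I0_base:.0f} mW/cm²           : {cmp.t_base:.3f} s")
print(f"time at {cmp.I0_alt:.0f} mW/cm² (model)   : {cmp.t_alt:.3f} s")
print(f"time at {cmp.I0_alt:.0f} mW/cm² (BRL)     : {cmp.t_alt_brl:.3f} s")
print(f"BRL efficacy shortfall       : {cmp.brl_shortfall:.4f}")

small = compare_scaling_laws(0.01, 0.0, 10.0, 40.0, params, rf)
print(f"\nSmall-demand limit, 10 → 40 mW/cm²: model time ratio "
      f"{small.time_ratio:.3f} (√4 = 2; reciprocity would give 4).")
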