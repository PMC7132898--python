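"""Inspect the built-in low/high event-rate scenarios.

Prints the control-arm survival at the administrative horizon for both
presets, the step hazard ratios of the early/late scenario grid, and the
change points t* that hit a target information fraction (the share of
control-arm events occurring before t*).
"""

from nphtest import (
    PiecewiseHREffect,
    information_fraction,
    make_lowrate_highrate_presets,
    solve_tstar_for_if,
    survival_research_arm,
)
from nphtest.simulate import PRESET_STEP_HRS

presets = make_lowrate_highrate_presets()
for rate, (dist, cens) in presets.items():
    s = float(dist.survival(cens.horizon))
    print(f"{rate}-event-rate preset: control survival at "
          f"{cens.horizon:.0f}y = {s:.3f} "
          f"({dist.family}, censoring U[{cens.low:.0f},{cens.high:.0f}])")

print("\nstep hazard ratios of the scenario grid:")
for (kind, rate), hr in PRESET_STEP_HRS.items():
    arrow = f"{hr} -> 1.0" if kind == "early" else f"1.0 -> {hr}"
    print(f"  {kind:5s} effect, {rate:4s} event rate: HR(t) {arrow}")

dist, cens = presets["low"]
print("\nchange points hitting target information fractions (low rate):")
for target in (0.2, 0.5, 0.8):
    t = solve_tstar_for_if(dist, cens, target)
    check = information_fraction(dist, cens, t).value
    print(f"  IF {target:.1f} -> t* = {t:.2f}y (round trip {check:.4f})")

eff = PiecewiseHREffect.late(0.3, 2.0)
s1 = survival_research_arm(dist, eff, 5.0)
print(f"\nresearch-arm survival at 5y under a late HR 0.3 from t*=2: {float(s1):.3f} "
      f"(control: {float(dist.survival(5.0)):.3f})")
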