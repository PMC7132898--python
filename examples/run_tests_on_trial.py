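"""Apply all nine tests to one simulated trial with a delayed benefit.

Simulates a 1000-patient trial whose research arm only starts to benefit
two years in (hazard ratio 1 before t* = 2, 0.5 after), then prints each
test's statistic and two-sided p-value.  Late-effect-sensitive tests (LRL,
WC, the versatile tests) should produce the smallest p-values; the plain
logrank dilutes the late benefit over the whole follow-up.
"""

import numpy as np

from nphtest import PiecewiseHREffect, high_event_rate_preset, run_tests, sample_trial

dist, cens = high_event_rate_preset()
effect = PiecewiseHREffect.late(hr=0.5, t_star=2.0)
data = sample_trial(1000, dist, effect, cens, seed=7)
print(f"simulated trial: n={data.n}, events={data.n_events}\n")

results = run_tests(data, permutations=2000, seed=11)
print(f"{'test':9s} {'statistic':>9s} {'p-value':>8s}  reference null")
for name, r in results.items():
    print(f"{name:9s} {r.statistic:9.3f} {r.p_value:8.4f}  {r.null_dist}")

print(
    "\nSmaller p-values for lrl/wc/vwlr/vwlr2 than for lr indicate the"
    "\ndelayed separation of the survival curves that weighted and"
    "\ncomposite tests are designed to detect."
)
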