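"""Extend an abridged lifetable beyond age 84 with Holt-Winters forecasting.

Builds the packaged Gompertz-Makeham lifetable (life expectancy ~75 years,
published through age 84), extrapolates the log mortality hazard to 94, and
prints the forecast annual death probabilities. The closing row at 95 (q=1)
keeps every simulated life finite.
"""

import numpy as np

from prostasim import extrapolate_lifetable, make_lifetable

lt = make_lifetable(target_life_expectancy=75.0)
full = extrapolate_lifetable(lt, target_max_age=94)

print("observed tail (ages 80-84):")
for a, q in zip(lt.ages[-5:], lt.q[-5:]):
    print(f"  age {a}: q = {q:.4f}")
print("forecast (ages 85-94) and closure:")
for a, q in zip(full.ages[85:], full.q[85:]):
    print(f"  age {a}: q = {q:.4f}")

surv = np.cumprod(1 - full.q)
print(f"\nimplied life expectancy at birth: {surv.sum() + 0.5:.1f} years")
print("q is the probability a man alive at that birthday dies within the year;")
print("the forecast continues the observed log-hazard trend in age.")
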