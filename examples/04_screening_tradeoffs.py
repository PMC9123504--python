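"""Harm-benefit trade-offs of one- and two-test screening strategies.

Calibrates the model, then simulates the six conservative strategies (one
or two PSA tests, biopsy only above 10 ng/mL) against a shared no-screening
arm under common random numbers, and prints resources per life saved.
"""

from prostasim import (
    ModelSpec,
    Strategy,
    build_population,
    calibrate_all,
    default_nh_params,
    default_survival_params,
    extrapolate_lifetable,
    harm_benefit,
    make_incidence_targets,
    make_lifetable,
    make_pyramid,
    run_screening_arm,
    simulate_lives,
    tally,
)
from prostasim.outcomes import StandardWeights

model = ModelSpec("P", default_nh_params("P"), default_survival_params(),
                  extrapolate_lifetable(make_lifetable(), 94), make_pyramid())
model, _ = calibrate_all(model, make_incidence_targets(), sim_budget=60_000, seed=1)

stubs = build_population(model.pyramid, 2020, 2040, multiplier=2)
lives = simulate_lives(model, stubs, seed=1)  # shared no-screening arm
weights = StandardWeights.from_pyramid(model.pyramid)

print(f"{'strategy':>10} {'tests':>8} {'lives saved':>12} {'tests/LS':>9} "
      f"{'biopsies/LS':>12} {'overdx/LS':>10}")
for ages in [(45,), (50,), (55,), (60,), (45, 55), (50, 60)]:
    arm = run_screening_arm(model, lives, Strategy(test_ages=ages), seed=1)
    t = tally(lives, arm, weights, count_scale=0.5)
    hb = harm_benefit(t)
    fmt = lambda v: f"{v:.1f}" if isinstance(v, float) else v
    print(f"{'+'.join(map(str, ages)):>10} {t.totals['tests']:>8.0f} "
          f"{t.totals['lives_saved']:>12.1f} {fmt(hb['tests_per_life_saved']):>9} "
          f"{fmt(hb['biopsies_per_life_saved']):>12} {fmt(hb['overdiagnoses_per_life_saved']):>10}")

print("\nLater single tests cost fewer tests per life saved (older men carry")
print("more detectable, more lethal disease) at the price of more overdiagnosis.")
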