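"""Propagate a measurement error budget to dose uncertainty.

Evaluates the analytic quadrature budget at midrange film response with
the default component uncertainties (saturation 0.5%, slope 1%, pixel
readout 1%, background 0.5%), compares the exact propagation weights with
the conventional rounded ones, and cross-checks the total against a
Monte-Carlo simulation of the same perturbations.
"""

import math

from filmcal import (
    CalibrationParams,
    ROUNDED_COEFFICIENTS,
    UncertaintyBudget,
    propagate_analytic,
    propagate_monte_carlo,
    propagation_coefficients,
)

params = CalibrationParams(245.0, 3271.0, 31.7)
budget = UncertaintyBudget(rel_sigma_Ps=0.005, rel_sigma_m=0.01,
                           rel_sigma_P=0.01, rel_sigma_P0=0.005)

exact = propagation_coefficients(params, response_fraction=0.5)
print("propagation weights (c_Ps, c_m, c_P, c_P0) at midrange response:")
print("  exact analytic : ({:.3f}, {:.3f}, {:.3f}, {:.3f})".format(*exact))
print("  rounded        : ({}, {}, {}, {})".format(*ROUNDED_COEFFICIENTS))

for label, coeffs in (("rounded", ROUNDED_COEFFICIENTS), ("exact", exact)):
    res = propagate_analytic(budget, coeffs)
    print(f"\nanalytic budget with {label} weights:")
    print(f"  sigma_D/D = {res.percent:.2f}%  "
          f"(systematic {100*res.systematic_component:.2f}%, "
          f"random {100*res.random_component:.2f}%)")

dose = -(params.Ps / params.m) * math.log(0.5)  # midrange response dose
mc = propagate_monte_carlo(params, budget, dose, n_draws=100_000, seed=1)
print(f"\nMonte-Carlo at D={dose:.1f} cGy (10^5 draws):")
print(f"  sigma_D/D = {100*mc.rel_sigma_D:.2f}%  "
      f"95% CI [{100*mc.ci_low:.2f}, {100*mc.ci_high:.2f}]%")
print("\nThe ~2% 1-sigma total (4% at 95% confidence) is the expected dose")
print("accuracy when model-based parameters drive the calibration.")
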