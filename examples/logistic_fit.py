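"""Logistic growth fitting and the carrying-capacity ratio.

Generates two noisy growth curves with a 4:1 capacity difference (the
tolerant line plateaus higher), fits the three-parameter logistic model to
each and prints the estimates with standard errors and the capacity ratio.
"""

import numpy as np

from exclusim import carrying_capacity_ratio, fit_logistic, synthetic_growth_curve

times = np.linspace(0, 8, 33)  # 6-hourly sampling over 8 days
tolerant = synthetic_growth_curve(K=5000, rate=1.2, tau=4.0, times=times,
                                  noise_sd=150, seed=1)
inhibited = synthetic_growth_curve(K=1250, rate=1.2, tau=4.0, times=times,
                                   noise_sd=60, seed=2)

fits = {}
for name, df in [("tolerant", tolerant), ("inhibited", inhibited)]:
    fit = fit_logistic(df["time"], df["value"])
    fits[name] = fit
    print(f"{name:>9}: K = {fit.K:7.1f} +/- {fit.K_se:5.1f}   "
          f"rate = {fit.growth_rate:.3f} +/- {fit.growth_rate_se:.3f} /day   "
          f"tau = {fit.tau:.3f} +/- {fit.tau_se:.3f} days")

ratio, se = carrying_capacity_ratio(fits["tolerant"], fits["inhibited"])
print(f"\ncarrying-capacity ratio: {ratio:.2f} +/- {se:.2f}")
print(
    "\nK is the plateau density, tau the half-capacity time (N(tau) = K/2)."
    "\nA capacity ratio ~4 with matched rate and tau reproduces how a"
    "\n10:1 seeding proportion can relax toward ~4:1 as both lines saturate."
)
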