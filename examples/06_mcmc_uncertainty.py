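"""MCMC parameter uncertainty and credible bands on a simulated profile.

Generates a sparse noisy plasma profile from the cyromazine rat model (10%
lognormal noise), calibrates the four ADME parameters by adaptive Metropolis
under two-fold log-uniform priors, and summarizes posterior recovery and the
pointwise credible bands of the concentration curve.
"""

import numpy as np

import qivikit as qk
from qivikit.pbk import build_model
from qivikit.records import DoseEvent, DosingSchedule
from qivikit.sensitivity import credible_bands, mcmc_calibrate
from qivikit.synthetic import GeneratorConfig, gen_invivo_profile

rat = qk.default_physiology("rat")
model = build_model(qk.CYROMAZINE, rat)
schedule = DosingSchedule(events=[DoseEvent(time=0.0, amount=1.05)],
                          duration=24.0)
t_obs, c_obs, truth = gen_invivo_profile(
    model, schedule, GeneratorConfig(seed=3, cv=0.10), n_obs=10, horizon=24.0)
print(f"observations at t = {np.round(t_obs, 2)} h")

post = mcmc_calibrate(model, t_obs, c_obs, schedule, n_steps=400, burn_in=150,
                      seed=5, rtol=1e-5)
print(f"acceptance rate {post.acceptance_rate:.2f}, "
      f"{post.draws.shape[0]} retained draws")
for name in ("fub", "papp"):
    m = post.mean()[name]
    print(f"  {name}: truth {truth[name]:.3g}, posterior mean {m:.3g} "
          f"({abs(m - truth[name]) / truth[name] * 100:.1f}% off)")

grid = np.linspace(0.25, 24.0, 40)
bands = credible_bands(post, model, schedule, grid, n_draws=20, rtol=1e-5)
w = bands["wide_high"] - bands["wide_low"]
print(f"95% band is widest at t = {grid[int(np.argmax(w))]:.1f} h "
      f"(the absorption peak is at t = {grid[int(np.argmax(bands['mean']))]:.1f} h); "
      "uncertainty concentrates around Cmax and decays with elimination.")
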