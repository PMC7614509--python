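"""Calibration run that fixed the default meander-lognormal parameters.

Grid search over (meander_mu, meander_sigma): for each candidate, run the
stationary dispersed-TBM simulation at observed conditions and record the
mean clearance rate.  The shipped default is the candidate whose stationary
rate is closest to the observed-condition target (1.21 %/min); migratory and
random-placement conditions are *not* used in the selection and serve as
independent checks afterwards.

The output of the run that selected the shipped defaults
(meander_mu=-1.08, meander_sigma=0.50) is archived in
docs/calibration_run.log.  Re-running takes ~10 minutes on one core.
"""

import numpy as np

from gcsearch.abm import SimConfig, replicate_rates
from gcsearch.calibration import MotilityModel


def stationary_rate(mu, sigma, reps, seed=12345):
    m = MotilityModel(meander_mu=mu, meander_sigma=sigma)
    cfg = SimConfig(tbm_mode="stationary", motility=m, seed=seed)
    r = replicate_rates(cfg, reps)
    return r.mean(), r.std(ddof=1) / np.sqrt(reps)


if __name__ == "__main__":
    # stage 1: coarse grid
    print("stage 1: coarse")
    coarse = []
    for sigma in (0.5, 0.75, 1.0):
        for mu in (-1.4, -1.2, -1.0, -0.8):
            mean, se = stationary_rate(mu, sigma, reps=6)
            coarse.append((mu, sigma, mean, se))
            print(f"  mu={mu:+.2f} sigma={sigma:.2f}: {mean:.3f} +- {se:.3f} %/min")
    # stage 2: refine around the best per-sigma bracket of 1.21
    print("stage 2: refine")
    best = None
    for sigma in (0.5, 0.75, 1.0):
        pts = sorted([(mu, m) for mu, s, m, _ in coarse if s == sigma])
        mus = np.array([p[0] for p in pts])
        ms = np.array([p[1] for p in pts])
        mu_star = float(np.interp(1.21, ms, mus))
        mean, se = stationary_rate(mu_star, sigma, reps=24)
        print(f"  sigma={sigma:.2f}: mu*={mu_star:+.3f} -> {mean:.3f} +- {se:.3f} %/min")
        if best is None or abs(mean - 1.21) < abs(best[2] - 1.21):
            best = (mu_star, sigma, mean)
    print(f"selected: meander_mu={best[0]:+.3f} meander_sigma={best[1]:.2f} (rate {best[2]:.3f})")
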