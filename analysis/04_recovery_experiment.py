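#!/usr/bin/env python
"""Monte-Carlo recovery of the generator's ground truth.

Fifty replicates of the default cohort are refit on the generative
scale; the experiment asks how reliably the pipeline recovers the
trajectory's dip/peak locations, the early/late window slopes, the
CAR(1) correlation and the intercept SD, and whether the flat
posterior series stays non-significant while the anterior smooth does
not.  Writes results/recovery.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pitgrowth import gamm
from pitgrowth import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 50


def main(base_seed: int = 0) -> None:
    seeds = [int(s % 2**31) for s in np.random.SeedSequence(base_seed).generate_state(N_REPLICATES)]
    rows = []
    for i, seed in enumerate(seeds):
        tab = syn.simulate_feature_table(syn.TrajectoryTruth(seed=seed))
        fit = gamm.fit_gamm(tab, "y_anterior")
        ext = gamm.principal_extrema(gamm.derivative_inference(fit))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            early = gamm.fit_window_lmm(tab, -5, 12, response_column="y_anterior")
            late = gamm.fit_window_lmm(tab, 12, 40, response_column="y_anterior")
        post = gamm.fit_gamm(tab, "y_posterior")
        rows.append(
            {
                "replicate": i,
                "rho_hat": fit.rho,
                "sigma_b_hat": float(np.sqrt(fit.sigma2_b)),
                "sigma_e_hat": float(np.sqrt(fit.sigma2_e)),
                "min_week": ext["min"]["week"] if ext["min"] else np.nan,
                "max_week": ext["max"]["week"] if ext["max"] else np.nan,
                "early_slope": early.slope,
                "late_slope": late.slope,
                "p_anterior": fit.f_pvalue,
                "p_posterior": post.f_pvalue,
            }
        )
    r = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    r.to_csv(OUT / "recovery.csv", index=False)

    print(f"{N_REPLICATES} replicates (truth: rho=0.34, sigma_b=0.30, "
          "min 10.6 wk, max 34.1 wk)")
    print(f"  rho_hat: median {r['rho_hat'].median():.3f}  mean {r['rho_hat'].mean():.3f}")
    print(f"  sigma_b_hat mean {r['sigma_b_hat'].mean():.3f}, sigma_e_hat mean {r['sigma_e_hat'].mean():.3f}")
    print(f"  min within 10.6±2.5 wk: {np.mean(np.abs(r['min_week']-10.6)<=2.5):.0%}")
    print(f"  max within 34.1±2.5 wk: {np.mean(np.abs(r['max_week']-34.1)<=2.5):.0%}")
    print(f"  early slope < 0: {np.mean(r['early_slope']<0):.0%}   "
          f"late slope > 0: {np.mean(r['late_slope']>0):.0%}")
    print(f"  anterior smooth significant: {np.mean(r['p_anterior']<0.05):.0%}   "
          f"posterior non-significant: {np.mean(r['p_posterior']>0.05):.0%}")
    print(f"wrote {OUT / 'recovery.csv'}")


if __name__ == "__main__":
    main()
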