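#!/usr/bin/env python
"""Fit the pituitary trajectory models to the simulated cohort.

Penalized-spline mixed models (k = 10 cubic B-spline, subject random
intercepts, CAR(1) residuals, joint REML) for person-centred anterior
and posterior volume, first-derivative significance bands, early/late
window linear mixed models, and leave-one-subject-out prediction.
Writes results/trajectory_fits.json, per-response derivative tables
and results/figures/trajectories.png.  Requires 01_simulate_cohort.py.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pitgrowth import gamm, pipeline

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    table = pipeline.read_session_table(OUT / "cohort_features.csv")
    summaries = {}
    for resp in ("z_vol_anterior", "z_vol_posterior"):
        fit = gamm.fit_gamm(table, resp)
        band = gamm.derivative_inference(fit)
        ext = gamm.principal_extrema(band)
        loso = gamm.loso_cv(table, resp)
        diag = gamm.residual_diagnostics(fit)
        summaries[resp] = {
            "edf": round(fit.edf, 2),
            "adj_r2": round(fit.adj_r2, 3),
            "F": round(fit.f_stat, 1),
            "p_smooth": fit.f_pvalue,
            "rho": round(fit.rho, 3),
            "aic": round(fit.aic, 1),
            "extrema": ext,
            "significant_intervals": [
                [round(a, 1), round(b, 1)] for a, b in band.significant_intervals
            ],
            "loso_mean_r2": round(loso["mean"], 3),
            "loso_per_fold": {k: round(v, 3) for k, v in loso["per_fold"].items()},
            "whitened_lag1_autocorr": round(diag["whitened_lag1_autocorr"], 3),
        }
        pd.DataFrame(
            {"weeks": band.grid, "deriv": band.deriv,
             "lower": band.lower, "upper": band.upper}
        ).to_csv(OUT / f"derivative_{resp}.csv", index=False, float_format="%.4f")
        lab = "anterior" if "anterior" in resp else "posterior"
        print(f"{lab}: edf={fit.edf:.2f} adjR2={fit.adj_r2:.2f} "
              f"rho={fit.rho:.2f} p={fit.f_pvalue:.3g} extrema={ext}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, window in (("early", gamm.EARLY_WINDOW), ("late", gamm.LATE_WINDOW)):
            w = gamm.fit_window_lmm(table, *window)
            summaries[f"window_{name}"] = {
                "window": list(window),
                "slope_sd_per_week": round(w.slope, 3),
                "se": round(w.slope_se, 4),
                "p": w.pvalue,
            }
            print(f"{name} window {window}: slope {w.slope:+.3f} SD/week (p={w.pvalue:.3g})")

    (OUT / "trajectory_fits.json").write_text(json.dumps(summaries, indent=2))

    fig_dir = OUT / "figures"
    fig_dir.mkdir(exist_ok=True)
    cfg = pipeline.PipelineConfig()
    pipeline._plot_trajectories(cfg, fig_dir, table)
    print(f"wrote {OUT / 'trajectory_fits.json'} and {fig_dir / 'trajectories.png'}")


if __name__ == "__main__":
    main()
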