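"""Canned validation experiments on synthetic trials.

These functions run the pipeline end to end at desk scale and report the
quantities used to judge it: reaction-norm recovery against planted truth,
drought-response class recovery, and cross-validated per-day accuracy
profiles of the sequential models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomics import clip_negative
from .preprocess import DailyBiasModel, smooth_all_plots
from .soilmoisture import SoilMoistureInterpolator
from .spline_rn import SplineReactionNorm, extract_rn_curves
from .synthetic import SimConfig, simulate_trial
from .evaluate import run_scheme, score

__all__ = [
    "sp_training_table_from_truth",
    "reaction_norm_recovery",
    "directional_cv_experiment",
]


def sp_training_table_from_truth(design, truth, realized=True) -> pd.DataFrame:
    """Long (genotype, day, s_prev, dy) table straight from simulated truth."""
    days = truth.days.astype(float)
    moist = truth.extras["moisture_dense"]
    growth = truth.extras["growth_realized"] if realized else truth.true_growth
    n_plots, n_days = growth.shape
    geno = design["genotype"].to_numpy()
    return pd.DataFrame(
        {
            "genotype": np.repeat(geno, n_days - 1),
            "day": np.tile(days[1:], n_plots),
            "s_prev": moist[:, :-1].ravel(),
            "dy": growth[:, 1:].ravel(),
        }
    )


def reaction_norm_recovery(
    seed: int = 0,
    n_genotypes: int = 40,
    n_days: int = 50,
    Q: int = 3,
    lambda0: float = 10.0,
    probe: tuple[float, float] = (20.0, 2.5),
) -> dict:
    """Noise-free recovery experiment against planted reaction norms.

    Simulates a noise-free trial (four watering treatments) with three
    planted drought-response classes, fits the varying-coefficient spline
    model, and reports:

    - ``frac_high_corr``: on a trial with smooth polygenic reaction norms,
      fraction of (genotype, day) targets whose fitted curve correlates
      > 0.9 with the planted truth over the moisture range actually
      observed within ±5 days of the target day;
    - ``class_agreement``: on a companion trial with three planted
      (genetically determined) drought-response classes, agreement of the
      tercile grouping at the low-moisture probe with the planted classes.

    Two trials are used because the discrete class offsets deliberately
    flatten some true curves (a tolerant genotype grows as fast dry as
    wet), and a correlation is not a meaningful recovery measure for a
    flat curve.
    """
    common = dict(
        n_genotypes=n_genotypes,
        n_markers=400,
        day_start=15,
        day_end=15 + n_days - 1,
        noise_sd_growth=0.0,
        noise_sd_obs=0.0,
        bias_range=(1.0, 1.0),
        seed=seed,
    )

    def _fit(cfg):
        design, _, _, _, truth = simulate_trial(cfg)
        table = sp_training_table_from_truth(design, truth, realized=True)
        kern = clip_negative(truth.extras["kernel"])
        genos = sorted(design["genotype"].unique())
        kw = pd.DataFrame(kern.submatrix(genos, genos), index=genos, columns=genos)
        days = truth.days.astype(float)
        fit = SplineReactionNorm(Q=Q, lambda0=lambda0).fit(
            table, kw, target_genotypes=genos, target_days=days
        )
        return design, truth, fit, days

    # curve recovery on the smooth-polygenic trial
    _, truth, fit, days = _fit(SimConfig(**common))
    moist = truth.extras["moisture_dense"]
    gl = {g: i for i, g in enumerate(truth.extras["genotypes"].genotype_ids)}
    cors = []
    for (g, d), _ in fit.coefs_.items():
        k = int(d - days[0])
        lo_k, hi_k = max(0, k - 5), min(len(days), k + 6)
        window = moist[:, lo_k:hi_k]
        s_lo, s_hi = float(window.min()), float(window.max())
        if s_hi - s_lo < 0.5:
            continue
        sgrid = np.linspace(s_lo, s_hi, 25)
        tc = truth.basis.design(sgrid) @ truth.true_coefs[:, gl[g], k]
        est = fit.curve(g, d, sgrid)
        if tc.std() > 1e-9 and est.std() > 1e-9:
            cors.append(float(np.corrcoef(tc, est)[0, 1]))
    cors = np.asarray(cors)

    # class recovery on the planted-class trial
    _, truth_c, fit_c, _ = _fit(SimConfig(**common, n_response_classes=3))
    _, groups = extract_rn_curves(
        fit_c,
        [probe[0]],
        np.linspace(fit_c.basis_.lo, fit_c.basis_.hi, 30),
        probe=probe,
    )
    order = groups.set_index("genotype")["group"].map({"low": 0, "middle": 1, "high": 2})
    truth_lab = truth_c.class_labels
    agreement = float((order.reindex(truth_lab.index) == truth_lab).mean())
    return {
        "frac_high_corr": float((cors > 0.9).mean()),
        "median_corr": float(np.median(cors)),
        "n_targets": int(len(cors)),
        "class_agreement": agreement,
    }


def directional_cv_experiment(
    seed: int = 0,
    scheme: str = "CV-G",
    repeats: int = 2,
    n_trees: int = 500,
    models: tuple = ("SP", "RF"),
) -> dict:
    """CV accuracy profile of the sequential models under default conditions.

    Runs the full chain — bias correction, smoothing, moisture bandwidth
    selection by LOOCV, interpolation, CV — on a default trial with
    moderate noise, and summarises per-day accuracy (repeat-averaged, then
    averaged over environments): early-season mean (first 15 days),
    late-season mean (last 15 days) and the final day, per model.
    """
    cfg = SimConfig(n_genotypes=40, n_markers=400, seed=seed)
    design, phenotypes, moisture_obs, manual, truth = simulate_trial(cfg)
    bias = DailyBiasModel().fit(phenotypes[["plot_id", "day", "value"]], manual)
    smoothed = smooth_all_plots(bias.transform(phenotypes))
    interp = SoilMoistureInterpolator().fit(moisture_obs)
    dense = interp.densify(design, truth.days)
    preds = run_scheme(
        design,
        smoothed,
        dense,
        truth.extras["kernel"],
        scheme,
        models=models,
        repeats=repeats,
        seed=seed,
        n_trees=n_trees,
    )
    report = score(preds, smoothed[["plot_id", "day", "smoothed"]])
    out = {"lambda_s": interp.lambda_s_, "lambda_t": interp.lambda_t_}
    for model, g in report.groupby("model"):
        daily = g.groupby("day")["r"].mean()
        out[model] = {
            "early": float(daily.iloc[:15].mean()),
            "late": float(daily.iloc[-15:].mean()),
            "final": float(daily.iloc[-1]),
            "per_day": daily,
        }
    return out
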