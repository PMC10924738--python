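"""Cross-validation schemes, sequential trajectory prediction, and scoring.

Three CV schemes test different prediction problems: CV-G holds out
genotype folds (5-fold, 10 repeats) within every environment; CV-E holds
out one whole environment (treatment x year) at a time; CV-GE holds out
every (genotype fold, environment) cell, training only on other folds x
other environments, so neither the test genotype nor the test environment
is seen in training.

Whole-season prediction is sequential: starting from a mixed-model
first-day prediction, each day's predicted value feeds the next day's
prediction (ŷ_d = ŷ_{d-1} + SP_{i,d}(s_{i,d-1}) for the spline model,
ŷ_d = RF(ŷ_{d-1}, g_i, s_{i,d-1}, d) for the forest); no observed
phenotype of a test plot is ever consulted.  Accuracy is the Pearson
correlation between predicted and smoothed values per (environment, day),
averaged over repeats before model comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenomicKernel, clip_negative
from .rf_growth import RandomForestGrowth, assemble_table
from .spline_rn import SplineReactionNorm
from .baselines import predict_first_day, run_gp_gpg

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "sp_trajectory",
    "rf_trajectory",
    "score",
    "compare_models",
    "run_scheme",
]

SCHEMES = ("CV-G", "CV-E", "CV-GE")


@dataclass
class CVPlan:
    """Test cells of one scheme: list of (repeat, fold_genotypes, environment).

    For CV-G/CV-GE genotype folds partition the genotype set per repeat.
    CV-E has one cell per environment (fold = all genotypes, repeat 0).
    """

    scheme: str
    cells: list = field(default_factory=list)  # (repeat, tuple(genotypes), env | None)
    genotypes: list = field(default_factory=list)
    environments: list = field(default_factory=list)
    k_folds: int = 5
    repeats: int = 10
    seed: int = 0

    def training_mask(self, design: pd.DataFrame, cell) -> np.ndarray:
        """Boolean mask of design rows usable for training against `cell`."""
        _, fold, env = cell
        in_fold = design["genotype"].isin(fold).to_numpy()
        if self.scheme == "CV-G":
            return ~in_fold
        if self.scheme == "CV-E":
            return (design["environment"] != env).to_numpy()
        if self.scheme == "CV-GE":
            return ~in_fold & (design["environment"] != env).to_numpy()
        raise ValueError(self.scheme)

    def test_mask(self, design: pd.DataFrame, cell) -> np.ndarray:
        _, fold, env = cell
        in_fold = design["genotype"].isin(fold).to_numpy()
        if self.scheme == "CV-G":
            return in_fold
        in_env = (design["environment"] == env).to_numpy()
        if self.scheme == "CV-E":
            return in_env
        return in_fold & in_env


def make_cv_plan(
    genotypes: list[str],
    environments: list[str],
    scheme: str,
    k_folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Random genotype partitions per repeat; leave-one-environment for CV-E."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if scheme != "CV-E" and k_folds > len(genotypes):
        raise ValueError("k_folds exceeds number of genotypes")
    rng = np.random.default_rng(seed)
    plan = CVPlan(
        scheme=scheme,
        genotypes=list(genotypes),
        environments=list(environments),
        k_folds=k_folds,
        repeats=repeats,
        seed=seed,
    )
    if scheme == "CV-E":
        plan.cells = [(0, tuple(genotypes), env) for env in environments]
        return plan
    for rep in range(repeats):
        perm = rng.permutation(len(genotypes))
        folds = np.array_split(perm, k_folds)
        for fold in folds:
            geno_fold = tuple(genotypes[i] for i in fold)
            if scheme == "CV-G":
                plan.cells.append((rep, geno_fold, None))
            else:
                for env in environments:
                    plan.cells.append((rep, geno_fold, env))
    return plan


def sp_trajectory(
    fit: SplineReactionNorm,
    genotype,
    days: np.ndarray,
    s_series: np.ndarray,
    y0: float,
) -> np.ndarray:
    """Recursion ŷ_d = ŷ_{d-1} + SP_{i,d}(s_{i,d-1}) from the first day."""
    days = np.asarray(days, dtype=float)
    if len(s_series) != len(days):
        raise ValueError("moisture series must cover every day of the horizon")
    if np.any(~np.isfinite(np.asarray(s_series, float))):
        bad = days[~np.isfinite(np.asarray(s_series, float))]
        raise ValueError(f"missing moisture on days {bad.tolist()}")
    out = np.empty(len(days))
    out[0] = y0
    for k in range(1, len(days)):
        out[k] = out[k - 1] + fit.evaluate(genotype, days[k], s_series[k - 1])
    return out


def rf_trajectory(
    model: RandomForestGrowth,
    g_col: np.ndarray,
    days: np.ndarray,
    s_series: np.ndarray,
    y0: float,
) -> np.ndarray:
    """Recursion ŷ_d = RF(ŷ_{d-1}, g_i, s_{i,d-1}, d) for one plot."""
    return rf_trajectory_batch(
        model, np.atleast_2d(g_col), days, np.atleast_2d(s_series), np.atleast_1d(y0)
    )[0]


def rf_trajectory_batch(
    model: RandomForestGrowth,
    g_mat: np.ndarray,
    days: np.ndarray,
    s_mat: np.ndarray,
    y0: np.ndarray,
) -> np.ndarray:
    """Vectorised forest recursion over plots: one predict call per day."""
    days = np.asarray(days, dtype=float)
    s_mat = np.asarray(s_mat, dtype=float)
    if s_mat.shape[1] != len(days):
        raise ValueError("moisture series must cover every day of the horizon")
    if not np.all(np.isfinite(s_mat)):
        bad = days[~np.isfinite(s_mat).all(axis=0)]
        raise ValueError(f"missing moisture on days {bad.tolist()}")
    out = np.empty((len(y0), len(days)))
    out[:, 0] = y0
    for k in range(1, len(days)):
        out[:, k] = model.predict_next(out[:, k - 1], g_mat, s_mat[:, k - 1], days[k])
    return out


def score(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r per (model, scheme, environment, day), repeat-averaged.

    ``predictions``: (model, scheme, repeat, environment, day, plot_id,
    predicted); ``truth``: (plot_id, day, smoothed).  Cells with fewer than
    `min_pairs` pairs or zero variance are dropped (flagged in ``.attrs``).
    """
    merged = predictions.merge(truth, on=["plot_id", "day"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping (plot, day) keys between predictions and truth")
    rows, undefined = [], []
    for key, g in merged.groupby(["model", "scheme", "repeat", "environment", "day"]):
        a = g["predicted"].to_numpy(float)
        b = g["smoothed"].to_numpy(float)
        if len(a) < min_pairs or a.std() == 0 or b.std() == 0:
            undefined.append(key)
            continue
        rows.append(
            dict(
                zip(
                    ("model", "scheme", "repeat", "environment", "day"),
                    key,
                ),
                r=float(np.corrcoef(a, b)[0, 1]),
                n=len(a),
            )
        )
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise ValueError("no cell had enough paired values")
    report = (
        per_rep.groupby(["model", "scheme", "environment", "day"])
        .agg(r=("r", "mean"), n=("n", "sum"), repeats=("r", "size"))
        .reset_index()
    )
    report.attrs["undefined_cells"] = undefined
    return report


def compare_models(report_a: pd.DataFrame, report_b: pd.DataFrame) -> dict:
    """Count (environment, day) cells where model A's r strictly exceeds B's."""
    key = ["scheme", "environment", "day"]
    a = report_a.set_index(key)["r"]
    b = report_b.set_index(key)["r"]
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("accuracy reports cover different cell grids")
        b = b.reindex(a.index)
    wins = int((a > b).sum())
    losses = int((a < b).sum())
    ties = int((a == b).sum())
    per_env = (
        (a > b).groupby(level="environment").sum().astype(int).to_dict()
    )
    return {
        "wins": wins,
        "losses": losses,
        "ties": ties,
        "total": len(a),
        "wins_per_environment": per_env,
    }


def _check_cv_integrity(scheme, train_design, test_design) -> None:
    overlap = set(train_design["plot_id"]) & set(test_design["plot_id"])
    if overlap:
        raise AssertionError(f"training/test plots overlap: {sorted(overlap)[:5]}")
    if scheme in ("CV-G", "CV-GE"):
        shared_g = set(train_design["genotype"]) & set(test_design["genotype"])
        if shared_g:
            raise AssertionError(f"shared genotypes across split: {sorted(shared_g)[:5]}")
    if scheme in ("CV-E", "CV-GE"):
        shared_e = set(train_design["environment"]) & set(test_design["environment"])
        if shared_e:
            raise AssertionError(f"shared environments across split: {sorted(shared_e)}")


def run_scheme(
    design: pd.DataFrame,
    smoothed: pd.DataFrame,
    moisture: pd.DataFrame,
    kernel: GenomicKernel,
    scheme: str,
    models: tuple = ("SP", "RF", "GPG"),
    k_folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    Q: int = 3,
    lambda0: float = 10.0,
    mtry: int = 10,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Run one CV scheme end to end; returns the long prediction table.

    ``smoothed``: (plot_id, day, smoothed); ``moisture``: dense (plot_id,
    day, moisture).  Sequential models (SP, RF) start from the scheme's
    mixed-model first-day prediction and consult no test-plot phenotypes;
    CV integrity is asserted on every cell.
    """
    plan = make_cv_plan(
        sorted(design["genotype"].unique()),
        sorted(design["environment"].unique()),
        scheme,
        k_folds=k_folds,
        repeats=repeats,
        seed=seed,
    )
    days = np.asarray(sorted(smoothed["day"].unique()), dtype=float)
    sm_wide = smoothed.pivot_table(index="plot_id", columns="day", values="smoothed")
    mo_wide = moisture.pivot_table(index="plot_id", columns="day", values="moisture")
    meta = design.set_index("plot_id")
    kern_clip = clip_negative(kernel)

    out_rows = []
    for cell in plan.cells:
        rep, fold, env = cell
        tr_mask = plan.training_mask(design, cell)
        te_mask = plan.test_mask(design, cell)
        train_design = design[tr_mask]
        test_design = design[te_mask]
        if test_design.empty or train_design.empty:
            continue
        _check_cv_integrity(scheme, train_design, test_design)
        train_plots = train_design["plot_id"].tolist()
        test_plots = test_design["plot_id"].tolist()
        train_genos = sorted(train_design["genotype"].unique())

        # first-day prediction (mixed model of the scheme)
        first = days[0]
        tr_first = pd.DataFrame(
            {
                "genotype": train_design["genotype"].to_numpy(),
                "environment": train_design["environment"].to_numpy(),
                "value": sm_wide.loc[train_plots, first].to_numpy(),
            }
        )
        te_first = pd.DataFrame(
            {
                "genotype": test_design["genotype"].to_numpy(),
                "environment": test_design["environment"].to_numpy(),
            }
        ).reset_index(drop=True)
        kernel_cv = kernel if scheme != "CV-E" else None
        y0 = predict_first_day(tr_first, te_first, scheme, kernel_cv)

        def emit(model_name, plot, traj):
            for d, v in zip(days, traj):
                out_rows.append(
                    {
                        "model": model_name,
                        "scheme": scheme,
                        "repeat": rep,
                        "environment": meta.loc[plot, "environment"],
                        "day": d,
                        "plot_id": plot,
                        "predicted": v,
                    }
                )

        if "SP" in models:
            sp_train = _sp_table(train_plots, sm_wide, mo_wide, meta, days)
            target_genos = sorted(set(test_design["genotype"]) | set(train_genos))
            kw = pd.DataFrame(
                kern_clip.submatrix(target_genos, train_genos),
                index=target_genos,
                columns=train_genos,
            )
            sp = SplineReactionNorm(Q=Q, lambda0=lambda0).fit(
                sp_train, kw, target_genotypes=target_genos, target_days=days
            )
            for plot, y00 in zip(test_plots, y0):
                traj = sp_trajectory(
                    sp, meta.loc[plot, "genotype"], days,
                    mo_wide.loc[plot, days].to_numpy(float), y00,
                )
                emit("SP", plot, traj)

        if "RF" in models:
            table = assemble_table(
                smoothed[smoothed["plot_id"].isin(train_plots)],
                moisture,
                kernel,
                design,
                train_genos,
            )
            eff_mtry = min(mtry, 3 + len(train_genos))
            rf = RandomForestGrowth(mtry=eff_mtry, n_trees=n_trees, seed=seed).fit(table)
            gsub = kernel.submatrix(
                [meta.loc[p, "genotype"] for p in test_plots], train_genos
            )
            s_mat = mo_wide.loc[test_plots, days].to_numpy(float)
            trajs = rf_trajectory_batch(rf, gsub, days, s_mat, np.asarray(y0))
            for plot, traj in zip(test_plots, trajs):
                emit("RF", plot, traj)

        for name, kind in (("GP", "level"), ("GPG", "growth")):
            if name not in models:
                continue
            tr_long = _long_by_genotype(train_plots, sm_wide, meta, days)
            te_long = _long_by_genotype(test_plots, sm_wide, meta, days)
            pred = run_gp_gpg(tr_long, te_long, scheme, kernel_cv, response_kind=kind)
            pred_map = pred.set_index(["genotype", "environment", "day"])["predicted"].sort_index()
            for plot in test_plots:
                g, e = meta.loc[plot, "genotype"], meta.loc[plot, "environment"]
                emit(name, plot, pred_map.loc[g, e].reindex(days).to_numpy())

    return pd.DataFrame(out_rows)


def _sp_table(plots, sm_wide, mo_wide, meta, days) -> pd.DataFrame:
    rows = []
    for plot in plots:
        y = sm_wide.loc[plot, days].to_numpy(float)
        s = mo_wide.loc[plot, days].to_numpy(float)
        g = meta.loc[plot, "genotype"]
        for k in range(1, len(days)):
            rows.append(
                {
                    "genotype": g,
                    "day": days[k],
                    "s_prev": s[k - 1],
                    "dy": y[k] - y[k - 1],
                }
            )
    return pd.DataFrame(rows)


def _long_by_genotype(plots, sm_wide, meta, days) -> pd.DataFrame:
    rows = []
    for plot in plots:
        y = sm_wide.loc[plot, days].to_numpy(float)
        for d, v in zip(days, y):
            rows.append(
                {
                    "genotype": meta.loc[plot, "genotype"],
                    "environment": meta.loc[plot, "environment"],
                    "day": d,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)
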