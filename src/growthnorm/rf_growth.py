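"""Random-forest daily-growth model.

The forest predicts the phenotype level y_{i,d} (not its increment) from
the previous day's size, the genotype's genomic-kernel column against the
training genotypes, the previous day's soil moisture, and days after
sowing:

    y_{i,d} = RF(y_{i,d-1}, g_i, s_{i,d-1}, d) + e_{i,d}.

Kernel columns are restricted to training genotypes so rows for unseen
genotypes are well-defined in genotype-holdout cross-validation.  The mtry
candidate grid is {5, 10, 15, 20, 25, 30}; 500 trees by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .genomics import GenomicKernel

__all__ = ["RandomForestGrowth", "assemble_table", "MTRY_GRID"]

MTRY_GRID = (5, 10, 15, 20, 25, 30)


def assemble_table(
    growth: pd.DataFrame,
    moisture: pd.DataFrame,
    kernel: GenomicKernel,
    design: pd.DataFrame,
    training_genotypes: list[str],
) -> pd.DataFrame:
    """One predictor row per (plot, day > first observed day).

    ``growth``: long smoothed series (plot_id, day, smoothed); ``moisture``:
    dense (plot_id, day, moisture).  Kernel columns g_i are the genotype's
    similarities to ``training_genotypes`` in fixed order; rows with a
    missing size or moisture value are dropped (count in ``.attrs``).
    """
    meta = design.set_index("plot_id")
    g_cols = [f"g_{g}" for g in training_genotypes]
    gmat = pd.DataFrame(
        kernel.submatrix(list(meta["genotype"].unique()), training_genotypes),
        index=list(meta["genotype"].unique()),
        columns=g_cols,
    )
    moist = moisture.set_index(["plot_id", "day"])["moisture"]
    rows = []
    n_dropped = 0
    for plot, g in growth.sort_values("day").groupby("plot_id"):
        days = g["day"].to_numpy(float)
        vals = g["smoothed"].to_numpy(float)
        geno = meta.loc[plot, "genotype"]
        for k in range(1, len(days)):
            s_prev = moist.get((plot, days[k - 1]), np.nan)
            if not (np.isfinite(vals[k]) and np.isfinite(vals[k - 1]) and np.isfinite(s_prev)):
                n_dropped += 1
                continue
            rows.append(
                {
                    "plot_id": plot,
                    "genotype": geno,
                    "day": days[k],
                    "y_prev": vals[k - 1],
                    "s_prev": float(s_prev),
                    "y": vals[k],
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.join(gmat.loc[table["genotype"].to_numpy()].set_index(table.index))
    table.attrs["n_dropped"] = n_dropped
    table.attrs["g_columns"] = g_cols
    return table


class RandomForestGrowth(BaseEstimator, RegressorMixin):
    """Regression forest over (y_prev, kernel column, s_prev, DAS).

    Parameters
    ----------
    mtry : features considered per split; must not exceed the predictor
        width (N_train + 3).
    n_trees : forest size (default 500).
    seed : forest randomness.
    """

    def __init__(self, mtry: int = 10, n_trees: int = 500, seed: int = 0) -> None:
        self.mtry = mtry
        self.n_trees = n_trees
        self.seed = seed

    def _feature_frame(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = ["y_prev"] + list(self.g_columns_) + ["s_prev", "day"]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"schema mismatch, missing columns: {missing}")
        return table[cols]

    def fit(self, table: pd.DataFrame, y=None) -> "RandomForestGrowth":
        if table.empty:
            raise ValueError("empty training table")
        self.g_columns_ = list(table.attrs.get(
            "g_columns", [c for c in table.columns if c.startswith("g_")]
        ))
        width = 3 + len(self.g_columns_)
        if self.mtry > width:
            raise ValueError(f"mtry={self.mtry} exceeds predictor width {width}")
        X = self._feature_frame(table)
        resp = table["y"].to_numpy(float) if y is None else np.asarray(y, float)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X.to_numpy(float), resp)
        self.train_response_range_ = (float(resp.min()), float(resp.max()))
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict(self._feature_frame(table).to_numpy(float))

    def predict_next(
        self, y_prev: np.ndarray, g: np.ndarray, s_prev: np.ndarray, day: float
    ) -> np.ndarray:
        """One-step prediction ŷ_d for a batch of plots."""
        y_prev = np.atleast_1d(np.asarray(y_prev, float))
        g = np.atleast_2d(np.asarray(g, float))
        if g.shape[1] != len(self.g_columns_):
            raise ValueError(
                f"kernel column width {g.shape[1]} != training schema {len(self.g_columns_)}"
            )
        s_prev = np.broadcast_to(np.asarray(s_prev, float), y_prev.shape)
        X = np.column_stack(
            [y_prev, g, s_prev, np.full_like(y_prev, float(day))]
        )
        out = self.forest_.predict(X)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite forest prediction")
        return out
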