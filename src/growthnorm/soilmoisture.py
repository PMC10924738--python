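"""Spatio-temporal interpolation of sparse soil-moisture measurements.

Soil moisture is measured on a subset of plots on alternating days.  Each
watering tube serves one field row, so moisture is assumed independent
across rows: a target plot is interpolated from measurements *in the same
row only*, as a Gaussian-kernel weighted mean over plot position within the
row and day,

    w = exp(-(l - l')² / λ_s) · exp(-(d - d')² / λ_t),

normalised to a convex combination.  Bandwidths (λ_s, λ_t) are chosen
jointly by leave-one-out cross-validation over a log-spaced candidate grid
(default 17 values from 0.1 to 1000), minimising RMSE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SoilMoistureInterpolator",
    "default_bandwidth_grid",
    "interpolate",
    "select_bandwidths",
    "densify",
]

REQUIRED_COLS = ("row", "position", "day", "value")


def default_bandwidth_grid(n: int = 17, lo: float = 0.1, hi: float = 1000.0) -> np.ndarray:
    """Log-uniform candidate bandwidths, endpoints inclusive."""
    return np.geomspace(lo, hi, n)


def _check_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    return measurements


class SoilMoistureInterpolator(BaseEstimator):
    """Separable Gaussian-kernel smoother over (plot position, day) per row.

    Parameters
    ----------
    lambda_s, lambda_t:
        Spatial / temporal bandwidths (divide the squared distance).  If
        either is None, ``fit`` selects both jointly by LOOCV over
        ``candidates``.
    candidates:
        Bandwidth candidate grid used when selecting; default 17 log-spaced
        values on [0.1, 1000].
    allow_row_fill:
        When densifying, fill rows without any measurement with the mean of
        the adjacent rows' interpolations instead of raising.
    """

    def __init__(
        self,
        lambda_s: float | None = None,
        lambda_t: float | None = None,
        candidates: np.ndarray | None = None,
        allow_row_fill: bool = False,
    ) -> None:
        self.lambda_s = lambda_s
        self.lambda_t = lambda_t
        self.candidates = candidates
        self.allow_row_fill = allow_row_fill

    # -- fitting ---------------------------------------------------------
    def fit(self, measurements: pd.DataFrame, y=None) -> "SoilMoistureInterpolator":
        measurements = _check_measurements(measurements)
        if measurements.empty:
            raise ValueError("no measurements")
        self.measurements_ = measurements.reset_index(drop=True)
        if self.lambda_s is None or self.lambda_t is None:
            grid = self.candidates if self.candidates is not None else default_bandwidth_grid()
            ls, lt, table = select_bandwidths(self.measurements_, grid)
            self.lambda_s_, self.lambda_t_ = ls, lt
            self.cv_table_ = table
        else:
            if self.lambda_s <= 0 or self.lambda_t <= 0:
                raise ValueError("bandwidths must be positive")
            self.lambda_s_, self.lambda_t_ = float(self.lambda_s), float(self.lambda_t)
        return self

    # -- prediction ------------------------------------------------------
    def predict(self, targets: pd.DataFrame) -> np.ndarray:
        """Interpolated moisture for each (row, position, day) target row."""
        if not hasattr(self, "measurements_"):
            raise RuntimeError("interpolator not fitted")
        out = np.empty(len(targets))
        for k, (_, t) in enumerate(targets.iterrows()):
            out[k] = interpolate(
                self.measurements_,
                self.lambda_s_,
                self.lambda_t_,
                (t["row"], t["position"], t["day"]),
            )
        return out

    def densify(self, design: pd.DataFrame, days: np.ndarray) -> pd.DataFrame:
        return densify(
            self.measurements_,
            self.lambda_s_,
            self.lambda_t_,
            design,
            days,
            allow_row_fill=self.allow_row_fill,
        )


def interpolate(
    measurements: pd.DataFrame,
    lambda_s: float,
    lambda_t: float,
    target: tuple,
    exclude_self: bool = False,
) -> float:
    """Kernel-weighted mean of same-row measurements at one target."""
    row, pos, day = target
    m = _check_measurements(measurements)
    same = m[m["row"] == row]
    if exclude_self:
        same = same[~((same["position"] == pos) & (same["day"] == day))]
    if same.empty:
        raise ValueError(f"no measurements in row {row!r} for interpolation")
    w = np.exp(
        -((same["position"].to_numpy(float) - pos) ** 2) / lambda_s
        - ((same["day"].to_numpy(float) - day) ** 2) / lambda_t
    )
    c = w.sum()
    if c == 0:  # numerically all-zero weights: fall back to nearest point
        d2 = (same["position"].to_numpy(float) - pos) ** 2 + (
            same["day"].to_numpy(float) - day
        ) ** 2
        return float(same["value"].to_numpy(float)[np.argmin(d2)])
    return float(np.dot(w, same["value"].to_numpy(float)) / c)


def _loocv_rmse_tables(measurements: pd.DataFrame, grid: np.ndarray) -> pd.DataFrame:
    """RMSE of leave-one-out prediction for each (λ_s, λ_t) pair, vectorised.

    Per row: precompute squared position/day distance matrices once; each
    candidate pair reuses them.
    """
    m = _check_measurements(measurements)
    per_row = []
    for _, g in m.groupby("row"):
        pos = g["position"].to_numpy(float)
        day = g["day"].to_numpy(float)
        val = g["value"].to_numpy(float)
        ds = (pos[:, None] - pos[None, :]) ** 2
        dt = (day[:, None] - day[None, :]) ** 2
        per_row.append((ds, dt, val))
    records = []
    for ls in grid:
        for lt in grid:
            se_sum = 0.0
            n = 0
            for ds, dt, val in per_row:
                if len(val) < 2:
                    continue
                w = np.exp(-ds / ls - dt / lt)
                np.fill_diagonal(w, 0.0)
                c = w.sum(axis=1)
                ok = c > 0
                if not ok.any():
                    continue
                pred = (w[ok] @ val) / c[ok]
                se_sum += float(((pred - val[ok]) ** 2).sum())
                n += int(ok.sum())
            rmse = np.sqrt(se_sum / n) if n else np.inf
            records.append({"lambda_s": float(ls), "lambda_t": float(lt), "rmse": rmse, "n": n})
    return pd.DataFrame(records)


def select_bandwidths(
    measurements: pd.DataFrame, candidates: np.ndarray | None = None
) -> tuple[float, float, pd.DataFrame]:
    """Joint LOOCV bandwidth search; ties broken toward the smaller pair.

    Returns (λ_s, λ_t, full RMSE table).  The table rows are ordered by
    (λ_s, λ_t) ascending, so `idxmin` on RMSE realises the lexicographic
    smallest-pair tie-break.
    """
    grid = np.sort(np.asarray(candidates if candidates is not None else default_bandwidth_grid(), dtype=float))
    table = _loocv_rmse_tables(measurements, grid)
    if not np.isfinite(table["rmse"]).any():
        raise ValueError("LOOCV undefined: every row has fewer than 2 measurements")
    best = table.loc[table["rmse"].idxmin()]
    return float(best["lambda_s"]), float(best["lambda_t"]), table


def densify(
    measurements: pd.DataFrame,
    lambda_s: float,
    lambda_t: float,
    design: pd.DataFrame,
    days: np.ndarray,
    allow_row_fill: bool = False,
) -> pd.DataFrame:
    """Interpolate moisture for every design plot x day (exclude_self=False).

    Returns a long table (plot_id, row, position, day, moisture) with
    exactly n_plots x n_days rows.  Rows of the design without any
    measurement raise, unless `allow_row_fill`, in which case they receive
    the mean interpolation of the adjacent measured rows (row index +-1,
    widening until found).
    """
    m = _check_measurements(measurements)
    days = np.asarray(days)
    measured_rows = set(m["row"].unique())
    chunks = []
    bare_rows = []
    for row_id, g in design.groupby("row"):
        pos = g["position"].to_numpy(float)
        if row_id not in measured_rows:
            bare_rows.append((row_id, g))
            continue
        sm = m[m["row"] == row_id]
        mp = sm["position"].to_numpy(float)
        md = sm["day"].to_numpy(float)
        mv = sm["value"].to_numpy(float)
        ws = np.exp(-((pos[:, None] - mp[None, :]) ** 2) / lambda_s)
        wt = np.exp(-((days[:, None].astype(float) - md[None, :]) ** 2) / lambda_t)
        # weights factorise: value[plot, day] = Σ_m ws*wt*v / Σ_m ws*wt
        num = np.einsum("pm,dm,m->pd", ws, wt, mv)
        den = np.einsum("pm,dm->pd", ws, wt)
        vals = num / den
        chunks.append(
            pd.DataFrame(
                {
                    "plot_id": np.repeat(g["plot_id"].to_numpy(), len(days)),
                    "row": row_id,
                    "position": np.repeat(pos, len(days)),
                    "day": np.tile(days, len(g)),
                    "moisture": vals.ravel(),
                }
            )
        )
    if bare_rows and not allow_row_fill:
        ids = [r for r, _ in bare_rows]
        raise ValueError(f"rows with no soil-moisture measurements: {ids}")
    dense = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame()
    for row_id, g in bare_rows:
        # fill from nearest measured rows on either side
        row_ids = sorted(measured_rows)
        if not row_ids:
            raise ValueError("no measured rows at all")
        deltas = np.abs(np.asarray(row_ids, dtype=float) - float(row_id))
        near = [row_ids[k] for k in np.flatnonzero(deltas == deltas.min())]
        filler = (
            dense[dense["row"].isin(near)].groupby("day")["moisture"].mean()
        )
        chunk = pd.DataFrame(
            {
                "plot_id": np.repeat(g["plot_id"].to_numpy(), len(days)),
                "row": row_id,
                "position": np.repeat(g["position"].to_numpy(float), len(days)),
                "day": np.tile(days, len(g)),
            }
        )
        chunk["moisture"] = filler.reindex(chunk["day"]).to_numpy()
        dense = pd.concat([dense, chunk], ignore_index=True)
    return dense.reset_index(drop=True)
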