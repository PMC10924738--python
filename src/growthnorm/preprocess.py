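"""Height-bias correction and smoothing-spline growth curves.

Remote-sensed canopy height carries a day-specific multiplicative bias
relative to manually measured plant height: CH_{d,i} = b_d PH_{d,i} + e.
The bias b_d is estimated per day by through-origin least squares over the
ground-truth plots, linearly interpolated to days without manual data, and
divided out (CH / b_d).  Daily growth curves are then obtained by cubic
smoothing splines minimising Σ(obs - f)² + penalty ∫ f''², evaluated at
every integer day; default penalties are 1e-4 for canopy area and 1e-3 for
canopy height.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator

__all__ = [
    "DailyBiasModel",
    "estimate_daily_bias",
    "correct_heights",
    "smooth_growth_curve",
    "smooth_all_plots",
    "DEFAULT_PENALTY",
]

DEFAULT_PENALTY = {"canopy_area": 1e-4, "canopy_height": 1e-3}


class DailyBiasModel(BaseEstimator):
    """Per-day multiplicative bias of remote-sensed height vs ground truth.

    ``fit`` takes two long tables with columns (plot_id, day, value): the
    remote-sensed heights and the manual heights.  Fitted attributes:

    bias_ : pd.Series
        b_d indexed by day, for every day in the remote-sensed table
        (estimated on days with ground truth, linearly interpolated
        elsewhere, nearest value carried to the boundaries).
    residual_scale_ : pd.Series
        RMS residual of the through-origin fit per estimated day.
    """

    def fit(self, uav_heights: pd.DataFrame, manual_heights: pd.DataFrame) -> "DailyBiasModel":
        merged = uav_heights.merge(
            manual_heights, on=["plot_id", "day"], suffixes=("_uav", "_manual")
        )
        if merged.empty:
            raise ValueError("no (plot, day) pair has both remote-sensed and manual height")
        est_days, est_bias, resid = [], [], []
        for day, g in merged.groupby("day"):
            ph = g["value_manual"].to_numpy(float)
            ch = g["value_uav"].to_numpy(float)
            denom = float(np.sum(ph**2))
            if denom == 0:
                raise ValueError(f"degenerate regression on day {day}: all manual heights zero")
            b = float(np.sum(ph * ch) / denom)
            est_days.append(day)
            est_bias.append(b)
            resid.append(float(np.sqrt(np.mean((ch - b * ph) ** 2))))
        est_days = np.asarray(est_days, dtype=float)
        order = np.argsort(est_days)
        est_days, est_bias = est_days[order], np.asarray(est_bias)[order]
        if np.any(est_bias <= 0):
            bad = est_days[np.asarray(est_bias) <= 0]
            raise ValueError(f"non-positive bias estimated on days {bad.tolist()}")
        all_days = np.unique(uav_heights["day"].to_numpy(float))
        # np.interp holds boundary values flat, matching nearest-estimate policy
        interp = np.interp(all_days, est_days, est_bias)
        self.bias_ = pd.Series(interp, index=all_days, name="bias")
        self.estimated_days_ = est_days
        self.residual_scale_ = pd.Series(np.asarray(resid)[order], index=est_days)
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        """Divide out b_d from each observation (column `value`)."""
        b = self.bias_.reindex(series["day"].to_numpy(float))
        if b.isna().any():
            missing = sorted(set(series["day"][b.isna().to_numpy()]))
            raise ValueError(f"bias undefined on days {missing}")
        out = series.copy()
        out["value"] = series["value"].to_numpy(float) / b.to_numpy(float)
        return out


def estimate_daily_bias(
    uav_heights: pd.DataFrame, manual_heights: pd.DataFrame
) -> DailyBiasModel:
    return DailyBiasModel().fit(uav_heights, manual_heights)


def correct_heights(series: pd.DataFrame, bias: DailyBiasModel) -> pd.DataFrame:
    return bias.transform(series)


def smooth_growth_curve(
    days: np.ndarray, values: np.ndarray, penalty: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothing spline of one plot's series on the integer-day grid.

    Returns (dense_days, smoothed_values) on every integer day spanned by
    the observations.  Requires >= 4 observation days.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(days)
    days, values = days[order], values[order]
    if len(np.unique(days)) < 4:
        raise ValueError("need >= 4 distinct observation days; use a linear fit instead")
    spline = make_smoothing_spline(days, values, lam=penalty)
    dense = np.arange(int(np.ceil(days[0])), int(np.floor(days[-1])) + 1, dtype=float)
    return dense, spline(dense)


def smooth_all_plots(
    phenotypes: pd.DataFrame, penalty: float | None = None, trait: str | None = None
) -> pd.DataFrame:
    """Smooth every plot's series; long in, long out with a `smoothed` column.

    `phenotypes` columns: plot_id, day, trait, value.  Penalty defaults per
    trait (1e-4 canopy area, 1e-3 canopy height).
    """
    frames = []
    for (plot, tr), g in phenotypes.groupby(["plot_id", "trait"]):
        if trait is not None and tr != trait:
            continue
        lam = penalty if penalty is not None else DEFAULT_PENALTY.get(tr, 1e-3)
        dense, smoothed = smooth_growth_curve(
            g["day"].to_numpy(float), g["value"].to_numpy(float), lam
        )
        frames.append(
            pd.DataFrame(
                {"plot_id": plot, "day": dense, "trait": tr, "smoothed": smoothed}
            )
        )
    if not frames:
        raise ValueError("no series to smooth")
    return pd.concat(frames, ignore_index=True)
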