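"""Varying-coefficient B-spline reaction norms of daily growth.

Daily growth is modelled as a genotype- and stage-specific spline function
of the previous day's soil moisture,

    Δy_{i,d} = SP_{i,d}(s_{i,d-1}) + e_{i,d},
    SP_{i,d}(s) = Σ_q c_{q,i,d} φ_q(s),

with a B-spline basis φ over the observed moisture support.  The
coefficients are assumed to vary smoothly over genotypes and days: each
target (genotype i, day d) gets its own weighted-least-squares fit in which
record (i', d') is weighted by

    w = max(G_{i,i'}, 0) · exp(-(d - d')² / λ_0),

the product of genomic similarity and a Gaussian day kernel.  Data from
genetically close genotypes and nearby growth stages therefore dominate
each local fit.  λ_0 candidates are {10, 30, 50, 70}; Q candidates {3, 4, 5}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BSplineBasis",
    "build_basis",
    "SplineReactionNorm",
    "fit_target",
    "extract_rn_curves",
    "LAMBDA0_GRID",
    "Q_GRID",
]

LAMBDA0_GRID = (10.0, 30.0, 50.0, 70.0)
Q_GRID = (3, 4, 5)


@dataclass
class BSplineBasis:
    """Q B-spline basis functions on the observed soil-moisture support.

    Clamped knot vector; partition of unity on [lo, hi].  Evaluation
    outside the support clamps the argument to the boundary.
    """

    knots: np.ndarray
    degree: int
    lo: float
    hi: float

    @property
    def Q(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, s: np.ndarray) -> np.ndarray:
        """Evaluate all Q basis functions at each (clamped) moisture value."""
        s = np.clip(np.asarray(s, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(s, self.knots, self.degree).toarray()

    def in_support(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (s >= self.lo) & (s <= self.hi)


def build_basis(moisture_values: np.ndarray, Q: int, degree: int = 3) -> BSplineBasis:
    """B-spline basis with exactly Q functions over the moisture sample.

    Boundary knots at observed min/max; interior knots (Q - degree - 1 of
    them) at equally spaced quantiles; degree is reduced to Q - 1 when
    Q <= degree so the basis is well-defined.
    """
    s = np.asarray(moisture_values, dtype=float)
    s = s[np.isfinite(s)]
    if len(np.unique(s)) < Q:
        raise ValueError(f"need >= {Q} distinct moisture values")
    lo, hi = float(s.min()), float(s.max())
    if lo == hi:
        raise ValueError("degenerate moisture support (min == max)")
    deg = min(degree, Q - 1)
    n_interior = Q - deg - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(s, qs)
        interior = np.clip(interior, lo + 1e-12, hi - 1e-12)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (deg + 1), interior, [hi] * (deg + 1)])
    return BSplineBasis(knots=knots, degree=deg, lo=lo, hi=hi)


def fit_target(
    phi: np.ndarray,
    dy: np.ndarray,
    weights: np.ndarray,
    ridge: float = 0.0,
) -> np.ndarray:
    """Closed-form weighted ridge solve for one (genotype, day) target.

    Minimises Σ w (Δy - Φc)² + ridge ||c||²; raises on a rank-deficient
    system, reporting the effective sample size Σw.
    """
    w = np.asarray(weights, dtype=float)
    a = phi.T @ (phi * w[:, None])
    if ridge > 0:
        a = a + ridge * np.eye(phi.shape[1])
    b = phi.T @ (w * dy)
    try:
        c = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular normal equations (effective sample size {w.sum():.3g}); "
            "increase ridge or lambda0"
        ) from err
    if not np.all(np.isfinite(c)):
        raise np.linalg.LinAlgError(
            f"non-finite coefficients (effective sample size {w.sum():.3g})"
        )
    return c


class SplineReactionNorm(BaseEstimator, RegressorMixin):
    """Varying-coefficient B-spline model of daily growth vs soil moisture.

    Parameters
    ----------
    Q : number of B-spline basis functions (paper grid 3, 4, 5).
    lambda0 : day-kernel bandwidth (grid 10, 30, 50, 70).
    ridge : ridge multiplier; the per-target penalty is
        ridge · (Σw) · var(Δy).  Set 0 for the plain WLS estimator.
    degree : B-spline degree before reduction (default cubic).

    ``fit`` consumes a long training table with columns
    (genotype, day, s_prev, dy) and a clipped genomic kernel giving
    similarities of target genotypes to training genotypes.  One coefficient
    vector is estimated per (genotype, day) target; plots of the same
    genotype share a target because the weights depend only on genotype and
    day.

    Fitted attributes: ``basis_``, ``coefs_`` (dict (genotype, day) ->
    coefficient vector), ``target_index_``.
    """

    def __init__(
        self,
        Q: int = 3,
        lambda0: float = 10.0,
        ridge: float = 1e-6,
        degree: int = 3,
    ) -> None:
        self.Q = Q
        self.lambda0 = lambda0
        self.ridge = ridge
        self.degree = degree

    def fit(
        self,
        training: pd.DataFrame,
        kernel_weights: pd.DataFrame | np.ndarray,
        target_genotypes: list | None = None,
        target_days: np.ndarray | None = None,
        basis: BSplineBasis | None = None,
    ) -> "SplineReactionNorm":
        """Estimate c_{q,i,d} for every requested (genotype, day) target.

        Parameters
        ----------
        training : table with columns genotype, day, s_prev, dy.
        kernel_weights : DataFrame indexed by target genotype with one
            column per training genotype (already clipped at zero), or a
            square array over the union when targets == training genotypes.
        target_genotypes, target_days : targets to fit; default all
            training genotypes / observed days.
        """
        req = {"genotype", "day", "s_prev", "dy"}
        if not req.issubset(training.columns):
            raise ValueError(f"training table needs columns {sorted(req)}")
        training = training.dropna(subset=["s_prev", "dy"]).reset_index(drop=True)
        train_genos = sorted(training["genotype"].unique())
        if isinstance(kernel_weights, pd.DataFrame):
            kw = kernel_weights
        else:
            kw = pd.DataFrame(
                np.asarray(kernel_weights), index=train_genos, columns=train_genos
            )
        kw = kw.clip(lower=0.0)
        if target_genotypes is None:
            target_genotypes = [g for g in kw.index]
        if target_days is None:
            target_days = np.unique(training["day"].to_numpy(float))
        target_days = np.asarray(target_days, dtype=float)

        self.basis_ = basis if basis is not None else build_basis(
            training["s_prev"].to_numpy(float), self.Q, self.degree
        )
        Qb = self.basis_.Q
        phi = self.basis_.design(training["s_prev"].to_numpy(float))
        dy = training["dy"].to_numpy(float)
        rec_days = training["day"].to_numpy(float)
        day_levels, rec_day_idx = np.unique(rec_days, return_inverse=True)
        geno_lookup = {g: k for k, g in enumerate(train_genos)}
        rec_geno_idx = training["genotype"].map(geno_lookup).to_numpy()

        # Per-record outer products pooled by (training genotype, record day):
        # the target weight factorises as G[gi, g'] * k0(d, d'), so the normal
        # equations contract a (G', D', Q, Q) tensor with the two kernels.
        nG, nD = len(train_genos), len(day_levels)
        M = np.zeros((nG, nD, Qb, Qb))
        v = np.zeros((nG, nD, Qb))
        n_rec = np.zeros((nG, nD))
        outer = phi[:, :, None] * phi[:, None, :]
        np.add.at(M, (rec_geno_idx, rec_day_idx), outer)
        np.add.at(v, (rec_geno_idx, rec_day_idx), phi * dy[:, None])
        np.add.at(n_rec, (rec_geno_idx, rec_day_idx), 1.0)

        k0 = np.exp(
            -((target_days[:, None] - day_levels[None, :]) ** 2) / self.lambda0
        )  # (Dt, D')
        gk = kw.reindex(index=target_genotypes, columns=train_genos).to_numpy(float)
        if np.isnan(gk).any():
            raise ValueError("kernel_weights missing entries for some genotype pair")
        # a target genotype with no positive similarity to any training
        # genotype would get zero total weight; fall back to uniform weights
        # (population-average reaction norm) and record it
        zero_rows = gk.sum(axis=1) <= 1e-12
        self.uniform_fallback_ = [
            g for g, z in zip(target_genotypes, zero_rows) if z
        ]
        if zero_rows.any():
            gk = gk.copy()
            gk[zero_rows] = 1.0
        # contract day kernel then genotype kernel
        Mt = np.einsum("td,gdab->gtab", k0, M)
        vt = np.einsum("td,gda->gta", k0, v)
        wsum_gd = np.einsum("td,gd->gt", k0, n_rec)  # Σ k0 per train-genotype
        A = np.einsum("ig,gtab->itab", gk, Mt)
        Bv = np.einsum("ig,gta->ita", gk, vt)
        wsum = gk @ wsum_gd  # (targets, Dt) total weight Σ w

        var_dy = float(np.var(dy)) if len(dy) > 1 else 1.0
        self.coefs_ = {}
        self.effective_n_ = {}
        self.failures_ = []
        for ti, g in enumerate(target_genotypes):
            for di, d in enumerate(target_days):
                eps = self.ridge * wsum[ti, di] * var_dy
                try:
                    c = self._solve(A[ti, di], Bv[ti, di], eps)
                except np.linalg.LinAlgError as err:
                    self.failures_.append(((g, float(d)), str(err)))
                    continue
                self.coefs_[(g, float(d))] = c
                self.effective_n_[(g, float(d))] = float(wsum[ti, di])
        self.train_genotypes_ = train_genos
        self.target_days_ = target_days
        return self

    @staticmethod
    def _solve(a: np.ndarray, b: np.ndarray, eps: float) -> np.ndarray:
        q = a.shape[0]
        try:
            c = np.linalg.solve(a + eps * np.eye(q), b)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular normal equations: {err}") from err
        if not np.all(np.isfinite(c)):
            raise np.linalg.LinAlgError("non-finite coefficients")
        return c

    def evaluate(self, genotype, day: float, s) -> np.ndarray | float:
        """Predicted daily growth SP_{i,d}(s); s clamped to basis support."""
        key = (genotype, float(day))
        if key not in self.coefs_:
            raise KeyError(f"no fitted target {key}")
        scalar = np.isscalar(s)
        phi = self.basis_.design(np.atleast_1d(s))
        out = phi @ self.coefs_[key]
        return float(out[0]) if scalar else out

    def curve(self, genotype, day: float, s_grid: np.ndarray) -> np.ndarray:
        return self.evaluate(genotype, day, np.asarray(s_grid, dtype=float))


def extract_rn_curves(
    fit: SplineReactionNorm,
    days: list[float],
    s_grid: np.ndarray,
    moisture: pd.DataFrame | None = None,
    probe: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Tabulate per-genotype reaction-norm curves at selected days.

    Returns (curves, groups).  ``curves`` is long: (genotype, day, s, dy,
    in_support).  When ``moisture`` (columns genotype?, day, value — any
    long table with 'day' and 'value') is given, in_support marks moisture
    values observed within ±5 days of the probe day.  When ``probe`` =
    (day, s) is given, genotypes are split into terciles (low / middle /
    high) by curve value at the probe; ties broken by genotype order.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    genos = sorted({g for (g, _) in fit.coefs_})
    rows = []
    for d in days:
        if moisture is not None:
            nearby = moisture[(moisture["day"] >= d - 5) & (moisture["day"] <= d + 5)]
            if len(nearby):
                lo, hi = nearby["value"].min(), nearby["value"].max()
            else:
                lo, hi = np.inf, -np.inf
        else:
            lo, hi = fit.basis_.lo, fit.basis_.hi
        for g in genos:
            if (g, float(d)) not in fit.coefs_:
                continue
            vals = fit.curve(g, d, s_grid)
            for s, v in zip(s_grid, vals):
                rows.append(
                    {
                        "genotype": g,
                        "day": float(d),
                        "s": float(s),
                        "dy": float(v),
                        "in_support": bool(lo <= s <= hi),
                    }
                )
    curves = pd.DataFrame(rows)
    groups = None
    if probe is not None:
        pd_, ps = probe
        if not (fit.basis_.lo <= ps <= fit.basis_.hi):
            raise ValueError(
                f"probe moisture {ps} outside basis support "
                f"[{fit.basis_.lo}, {fit.basis_.hi}] (extrapolation)"
            )
        vals = {g: fit.evaluate(g, pd_, ps) for g in genos if (g, float(pd_)) in fit.coefs_}
        ordered = sorted(vals, key=lambda g: (vals[g], str(g)))
        n = len(ordered)
        labels = {}
        for k, g in enumerate(ordered):
            tier = min(2, 3 * k // n) if n else 0
            labels[g] = ("low", "middle", "high")[tier]
        groups = pd.DataFrame(
            {
                "genotype": list(vals),
                "value": [vals[g] for g in vals],
                "group": [labels[g] for g in vals],
            }
        )
    return curves, groups
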