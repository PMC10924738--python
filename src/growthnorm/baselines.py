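"""Mixed-model genomic-prediction baselines (first-day, GP, GPG).

The benchmark models are single-trait GBLUPs: y = Xβ + Zu + e with
u ~ N(0, σ_g² K) for a genomic kernel K (or the identity), e ~ N(0, σ_e² I).
Variance components are estimated by REML, profiling the likelihood over
the ratio λ = σ_g²/σ_e² with bounded scalar optimisation; BLUPs and
predictions for unobserved genotypes come from the kernel cross-covariance.

Three cross-validation schemes pick the model structure: genotype holdout
(CV-G) fits one kernel model per environment; environment holdout (CV-E)
fits a single all-environment model with fixed environment effects and an
identity genotype covariance (test genotypes are observed elsewhere);
joint holdout (CV-GE) fits the all-environment model with the genomic
kernel.  GP applies the scheme's model to each day's phenotype level; GPG
applies it to each day's growth increment and accumulates the increments
from the first-day prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .genomics import GenomicKernel

__all__ = ["GBLUP", "fit_gblup", "predict_first_day", "run_gp_gpg"]


class GBLUP(BaseEstimator, RegressorMixin):
    """Single-random-effect mixed model with REML variance components.

    Parameters
    ----------
    kernel : GenomicKernel or None.  None uses an identity genotype
        covariance (u ~ N(0, σ_g² I)).
    fixed : "mean" (single intercept) or "environment" (one fixed effect
        per environment label in the data).
    ratio : optional fixed value of σ_g²/σ_e²; skips REML when given.

    ``fit`` consumes a long table with columns (genotype, value) and
    optionally (environment).  Fitted attributes: ``beta_`` (fixed
    effects), ``u_`` (genotype BLUPs over all kernel genotypes, or the
    observed genotypes in identity mode), ``sigma_g2_``, ``sigma_e2_``.
    """

    def __init__(
        self,
        kernel: GenomicKernel | None = None,
        fixed: str = "mean",
        ratio: float | None = None,
    ) -> None:
        self.kernel = kernel
        self.fixed = fixed
        self.ratio = ratio

    # -- internals -------------------------------------------------------
    def _design(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        if self.fixed == "mean":
            return np.ones((len(data), 1)), ["(intercept)"]
        if self.fixed == "environment":
            envs = sorted(data["environment"].unique())
            X = np.zeros((len(data), len(envs)))
            for j, e in enumerate(envs):
                X[(data["environment"] == e).to_numpy(), j] = 1.0
            return X, envs
        raise ValueError(f"unknown fixed spec {self.fixed!r}")

    def fit(self, data: pd.DataFrame, y=None) -> "GBLUP":
        data = data.dropna(subset=["value"]).reset_index(drop=True)
        if data["genotype"].nunique() < 2:
            raise ValueError("need >= 2 genotypes")
        yv = data["value"].to_numpy(float)
        X, fixed_names = self._design(data)
        obs_genos = sorted(data["genotype"].unique())
        if self.kernel is not None:
            all_genos = list(self.kernel.genotype_ids)
            K = self.kernel.matrix
            w = np.linalg.eigvalsh(K)
            if w.min() < -1e-8 * max(np.trace(K) / K.shape[0], 1.0):
                raise ValueError(
                    f"kernel not PSD (min eigenvalue {w.min():.3g}); add jitter"
                )
        else:
            all_genos = obs_genos
            K = np.eye(len(obs_genos))
        gidx = {g: k for k, g in enumerate(all_genos)}
        Z = np.zeros((len(data), len(all_genos)))
        for r, g in enumerate(data["genotype"]):
            Z[r, gidx[g]] = 1.0

        ZKZ = Z @ K @ Z.T
        n, p = len(yv), X.shape[1]

        def neg_reml(log_ratio: float) -> float:
            lam = np.exp(log_ratio)
            V = lam * ZKZ + np.eye(n)
            try:
                cV = np.linalg.cholesky(V + 1e-10 * np.eye(n))
            except np.linalg.LinAlgError:
                return np.inf
            logdetV = 2.0 * np.log(np.diag(cV)).sum()
            Vi_y = np.linalg.solve(V, yv)
            Vi_X = np.linalg.solve(V, X)
            XtViX = X.T @ Vi_X
            sign, logdetX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf
            beta = np.linalg.solve(XtViX, X.T @ Vi_y)
            r = yv - X @ beta
            Vi_r = np.linalg.solve(V, r)
            ss = float(r @ Vi_r)
            if ss <= 0:
                return np.inf
            sigma_e2 = ss / (n - p)
            return 0.5 * ((n - p) * np.log(sigma_e2) + logdetV + logdetX)

        if self.ratio is not None:
            lam = float(self.ratio)
        else:
            res = minimize_scalar(
                neg_reml, bounds=(np.log(1e-6), np.log(1e6)), method="bounded",
                options={"xatol": 1e-6},
            )
            if not res.success:
                raise RuntimeError(f"REML did not converge: {res}")
            lam = float(np.exp(res.x))

        V = lam * ZKZ + np.eye(n)
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, yv)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = yv - X @ beta
        Vi_r = np.linalg.solve(V, r)
        sigma_e2 = float(r @ Vi_r) / (n - p)
        # û = σg² K Z' V_full⁻¹ (y - Xβ); with V scaled by σe², σg² = λ σe²
        u = lam * (K @ (Z.T @ Vi_r))

        self.beta_ = pd.Series(beta, index=fixed_names)
        self.u_ = pd.Series(u, index=all_genos)
        self.ratio_ = lam
        self.sigma_e2_ = sigma_e2
        self.sigma_g2_ = lam * sigma_e2
        self.fitted_ = X @ beta + Z @ u
        self.observed_genotypes_ = obs_genos
        return self

    # -- prediction ------------------------------------------------------
    def predict_genotypes(self, genotypes: list[str]) -> np.ndarray:
        """Genotype BLUPs û (zero for genotypes unknown to the model)."""
        return self.u_.reindex(genotypes).fillna(0.0).to_numpy()

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fixed part + BLUP for (genotype[, environment]) query rows.

        An environment absent from training falls back to the mean of the
        training environment effects.
        """
        u = self.predict_genotypes(list(data["genotype"]))
        if self.fixed == "mean":
            fx = np.full(len(data), float(self.beta_.iloc[0]))
        else:
            fx = self.beta_.reindex(data["environment"]).to_numpy()
            fx = np.where(np.isfinite(fx), fx, float(self.beta_.mean()))
        return fx + u


def fit_gblup(
    data: pd.DataFrame,
    kernel: GenomicKernel | None = None,
    fixed: str = "mean",
    ratio: float | None = None,
) -> GBLUP:
    return GBLUP(kernel=kernel, fixed=fixed, ratio=ratio).fit(data)


def _scheme_model(scheme: str, kernel: GenomicKernel | None) -> GBLUP:
    if scheme == "CV-G":
        return GBLUP(kernel=kernel, fixed="mean")
    if scheme == "CV-E":
        return GBLUP(kernel=None, fixed="environment")
    if scheme == "CV-GE":
        return GBLUP(kernel=kernel, fixed="environment")
    raise ValueError(f"unknown scheme {scheme!r}")


def predict_first_day(
    training: pd.DataFrame,
    test: pd.DataFrame,
    scheme: str,
    kernel: GenomicKernel | None,
) -> np.ndarray:
    """First-observation-day prediction per test (genotype, environment).

    ``training``/``test``: long tables (genotype, environment, value);
    test values are ignored.  CV-G fits one per-environment kernel model
    (test rows are predicted within their environment); CV-E and CV-GE fit
    the all-environment model of the scheme.
    """
    if scheme == "CV-G":
        out = np.full(len(test), np.nan)
        for env, sub in test.groupby("environment"):
            tr = training[training["environment"] == env]
            model = _scheme_model(scheme, kernel).fit(tr)
            out[sub.index.to_numpy()] = model.predict(sub)
        return out
    model = _scheme_model(scheme, kernel).fit(training)
    return model.predict(test)


def run_gp_gpg(
    training: pd.DataFrame,
    test: pd.DataFrame,
    scheme: str,
    kernel: GenomicKernel | None,
    response_kind: str = "level",
) -> pd.DataFrame:
    """Per-day genomic prediction over the season.

    ``training``/``test``: long tables (genotype, environment, day, value)
    of smoothed series.  response_kind "level" (GP) fits y_d per day;
    "growth" (GPG) fits Δy_d per day and accumulates the predicted
    increments from the first-day prediction.  Returns the test table with
    a ``predicted`` column on the common day grid.
    """
    if response_kind not in ("level", "growth"):
        raise ValueError("response_kind must be 'level' or 'growth'")

    def fit_predict(tr: pd.DataFrame, te: pd.DataFrame) -> np.ndarray:
        # CV-G fits the per-environment model; CV-E/CV-GE the pooled one
        return predict_first_day(tr.reset_index(drop=True), te.reset_index(drop=True), scheme, kernel)

    days = np.asarray(sorted(set(training["day"]) & set(test["day"])), dtype=float)
    if days.size == 0:
        raise ValueError("no common days between training and test")
    test = test[test["day"].isin(days)].reset_index(drop=True)
    preds = pd.Series(np.nan, index=test.index)

    first = days[0]
    tr_first = training[training["day"] == first].reset_index(drop=True)
    te_first = test[test["day"] == first].reset_index(drop=True)
    first_pred = predict_first_day(tr_first, te_first, scheme, kernel)
    first_map = dict(
        zip(zip(te_first["genotype"], te_first["environment"]), first_pred)
    )
    preds[test["day"] == first] = first_pred

    if response_kind == "level":
        for d in days[1:]:
            tr = training[training["day"] == d]
            mask = (test["day"] == d).to_numpy()
            preds[mask] = fit_predict(tr, test[mask])
    else:
        tr_wide = training.pivot_table(
            index=["genotype", "environment"], columns="day", values="value"
        )
        cum = {k: v for k, v in first_map.items()}
        for j in range(1, len(days)):
            d, d_prev = days[j], days[j - 1]
            dy = (tr_wide[d] - tr_wide[d_prev]).dropna().rename("value").reset_index()
            mask = (test["day"] == d).to_numpy()
            sub = test[mask]
            inc = fit_predict(dy, sub)
            vals = np.empty(len(sub))
            for r, (g, e, v) in enumerate(zip(sub["genotype"], sub["environment"], inc)):
                cum[(g, e)] = cum[(g, e)] + v
                vals[r] = cum[(g, e)]
            preds[mask] = vals
    out = test.copy()
    out["predicted"] = preds.to_numpy()
    return out
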