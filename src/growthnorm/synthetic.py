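"""Synthetic field trials with known ground-truth reaction norms.

Emulates a drought-phenotyping trial: a diversity panel of biallelic SNP
genotypes, four watering treatments (well-watered WW, non-watered W0, and
5-/10-day on-off cycles W5/W10) driving treatment-specific soil-moisture
trajectories, and daily growth generated from genotype- and stage-specific
reaction norms to the previous day's soil moisture.  Observations carry a
per-day multiplicative height bias and alternating-subset soil-moisture
missingness, mirroring how such trials are actually measured.

Every stochastic quantity flows from ``SimConfig.seed`` through one
generator, so identical configs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, GenomicKernel, build_linear_kernel
from .spline_rn import BSplineBasis, build_basis

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_soil_moisture",
    "simulate_true_reaction_norms",
    "simulate_trial",
]

TREATMENTS = ("WW", "W0", "W5", "W10")


@dataclass
class SimConfig:
    """Study conditions of a synthetic trial.

    Scales mimic soybean canopy height in cm: initial plot size ~5 cm,
    peak daily growth ~1.5 cm/day, season from 15 to 64 days after sowing.
    Soil moisture is %v/v in sandy soil: watered set-point 6%, dry floor
    2% (the observed range in such fields is narrow).
    """

    n_genotypes: int = 40
    n_markers: int = 400
    n_years: int = 1
    treatments: tuple = TREATMENTS
    day_start: int = 15
    day_end: int = 64
    Q_true: int = 3
    h2_coef: float = 0.8
    coef_sd: float = 0.25          # total SD of coefficient deviations (cm/day)
    base_growth: float = 1.5       # peak of the mean reaction norm (cm/day)
    noise_sd_growth: float = 0.1   # additive SD on daily growth (cm/day)
    noise_sd_obs: float = 0.3      # measurement noise on observed size (cm)
    bias_range: tuple = (0.8, 1.2)  # daily multiplicative height bias
    maf_range: tuple = (0.025, 0.5)
    # soil moisture (% v/v)
    ww_setpoint: float = 6.0
    dry_floor: float = 2.0
    rise_rate: float = 0.8
    decay_rate: float = 0.25
    moisture_noise_sd: float = 0.15
    moisture_corr_length: float = 2.0  # plots, along-row noise correlation
    # layout & measurement scheme
    plots_per_row: int = 10
    moisture_measured_every: int = 3   # measure every k-th plot position
    manual_plots_per_env: int = 4      # plots with manual height ground truth
    n_missing_groups: int = 2          # alternating-day measurement groups
    initial_size: float = 5.0
    initial_size_cv: float = 0.3   # diversity panels vary widely in early vigour
    h2_initial: float = 0.7        # heritability of log initial size
    n_response_classes: int | None = None  # plant discrete drought-response classes
    class_sep: float = 1.0             # low-moisture growth offset between classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        if self.day_end - self.day_start < 10:
            raise ValueError("day span must be >= 10")
        for name in ("coef_sd", "noise_sd_growth", "noise_sd_obs", "moisture_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.h2_coef <= 1.0:
            raise ValueError("h2_coef must be in [0, 1]")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments {sorted(unknown)}")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1)

    @property
    def environments(self) -> list[str]:
        if self.n_years == 1:
            return list(self.treatments)
        return [f"Y{y+1}-{t}" for y in range(self.n_years) for t in self.treatments]


@dataclass
class GroundTruth:
    """Noise-free generative state of a simulated trial."""

    true_coefs: np.ndarray            # [Q_true, n_genotypes, n_days]
    basis: BSplineBasis
    marker_effects: np.ndarray        # [Q_true, n_markers, n_days]
    true_growth: np.ndarray           # [n_plots, n_days] (first column 0)
    true_trajectory: np.ndarray       # [n_plots, n_days]
    true_bias: pd.Series              # b_d per day
    days: np.ndarray
    plot_ids: list
    class_labels: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Biallelic score matrix with per-marker MAF uniform on cfg.maf_range.

    Genotypes are drawn under Hardy-Weinberg proportions; a marker whose
    *empirical* MAF falls below the lower bound is redrawn so every
    simulated marker would survive the standard MAF filter.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.maf_range
    n, m = cfg.n_genotypes, cfg.n_markers
    scores = np.empty((n, m))
    for j in range(m):
        for _ in range(200):
            maf = rng.uniform(lo, hi)
            p_alt = maf if rng.random() < 0.5 else 1.0 - maf
            col = rng.binomial(2, p_alt, size=n) - 1.0
            emp = (col.mean() + 1.0) / 2.0
            if min(emp, 1.0 - emp) >= lo:
                break
        scores[:, j] = col
    ids = [f"G{i:03d}" for i in range(n)]
    return GenotypeMatrix(scores, ids, [f"M{j:05d}" for j in range(m)])


def _watering_schedule(treatment: str, n_days: int) -> np.ndarray:
    d = np.arange(n_days)
    if treatment == "WW":
        return np.ones(n_days, bool)
    if treatment == "W0":
        return np.zeros(n_days, bool)
    if treatment == "W5":
        return (d % 10) < 5
    if treatment == "W10":
        return (d % 20) < 10
    raise ValueError(f"unknown treatment {treatment!r}")


def moisture_mean_series(cfg: SimConfig, treatment: str) -> np.ndarray:
    """Deterministic treatment mean trajectory (first-order relaxation)."""
    on = _watering_schedule(treatment, len(cfg.days))
    m = np.empty(len(cfg.days))
    state = cfg.ww_setpoint
    for k in range(len(cfg.days)):
        if on[k]:
            state = state + cfg.rise_rate * (cfg.ww_setpoint - state)
        else:
            state = state + cfg.decay_rate * (cfg.dry_floor - state)
        m[k] = state
    return m


def simulate_soil_moisture(
    cfg: SimConfig,
    treatment: str,
    n_plots: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Moisture series [n_plots x n_days] for one row under one treatment.

    Deterministic treatment mean plus along-row correlated Gaussian noise
    (squared-exponential over plot position, independent across days).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_plots = cfg.plots_per_row if n_plots is None else n_plots
    mean = moisture_mean_series(cfg, treatment)
    out = np.tile(mean, (n_plots, 1))
    if cfg.moisture_noise_sd > 0:
        pos = np.arange(n_plots, dtype=float)
        cov = np.exp(-((pos[:, None] - pos[None, :]) ** 2) / (2 * cfg.moisture_corr_length**2))
        w, v = np.linalg.eigh(cov)
        L = v * np.sqrt(np.clip(w, 0, None))
        z = rng.standard_normal((n_plots, len(cfg.days)))
        out = out + cfg.moisture_noise_sd * (L @ z)
    return np.clip(out, 0.2, 99.0)


def _day_kernel_factor(days: np.ndarray, length: float = 10.0) -> np.ndarray:
    d = days.astype(float)
    k = np.exp(-((d[:, None] - d[None, :]) ** 2) / (2 * length**2))
    w, v = np.linalg.eigh(k)
    return v * np.sqrt(np.clip(w, 0, None))


def simulate_true_reaction_norms(
    cfg: SimConfig,
    genotypes: GenotypeMatrix,
    kernel: GenomicKernel,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.Series | None]:
    """Ground-truth coefficients c_{q,i,d}: smooth mean + structured deviations.

    c = μ_q(d) + genetic deviation + shared environmental day-curve.  The
    genetic part is built from random marker effects (smooth over days), so
    its covariance over genotypes is proportional to the linear genomic
    kernel and identical marker rows (clones) get identical coefficients;
    the non-genetic part is one smooth day curve shared by all genotypes.
    The split is h2_coef : (1 - h2_coef) of ``coef_sd``².

    Returns (coefs [Q, n_geno, n_days], marker_effects [Q, m, n_days],
    class_labels or None).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if kernel.matrix.shape[0] != cfg.n_genotypes:
        raise ValueError("kernel dimension does not match n_genotypes")
    days = cfg.days
    nD, nG, Q = len(days), cfg.n_genotypes, cfg.Q_true

    # Mean curves: amplitude increases with basis index (growth increases
    # with moisture) and follows a mid-season bump over days.
    span = cfg.day_end - cfg.day_start
    peak = cfg.day_start + span / 2.0
    bump = np.exp(-((days - peak) ** 2) / (2 * (span / 3.0) ** 2))
    amps = cfg.base_growth * (np.arange(1, Q + 1) / Q)
    mu = amps[:, None, None] * bump[None, None, :]          # [Q, 1, nD]

    LK = _day_kernel_factor(days)
    xc = genotypes.scores - genotypes.scores.mean(axis=0)
    p = (genotypes.scores.mean(axis=0) + 1.0) / 2.0
    denom = np.sqrt(max(2.0 * np.sum(p * (1.0 - p)), 1e-12))

    sd_g = np.sqrt(cfg.h2_coef) * cfg.coef_sd
    sd_e = np.sqrt(1.0 - cfg.h2_coef) * cfg.coef_sd
    coefs = np.empty((Q, nG, nD))
    alphas = np.empty((Q, cfg.n_markers, nD))
    for q in range(Q):
        z = rng.standard_normal((cfg.n_markers, nD))
        alpha = (z @ LK.T) / denom * sd_g                    # marker effects over days
        genetic = xc @ alpha                                 # cov ∝ G_L over genotypes
        env = sd_e * (LK @ rng.standard_normal(nD))          # shared day curve
        coefs[q] = mu[q] + genetic + env[None, :]
        alphas[q] = alpha

    labels = None
    if cfg.n_response_classes:
        # classes are genetically determined: terciles (k-tiles) of a
        # marker-based latent drought-tolerance score, so class differences
        # carry the same genomic structure the estimators exploit
        k = cfg.n_response_classes
        latent = xc @ rng.standard_normal(cfg.n_markers) / denom
        order = np.argsort(np.argsort(latent, kind="stable"), kind="stable")
        assign = np.minimum(k - 1, order * k // nG)
        offsets = (assign - (k - 1) / 2.0) * cfg.class_sep
        # class offset acts on the lowest-moisture basis coefficient
        coefs[0] += offsets[:, None]
        labels = pd.Series(assign, index=genotypes.genotype_ids, name="class")
    return coefs, alphas, labels


def _make_design(cfg: SimConfig, genotypes: GenotypeMatrix, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    row_counter = 0
    for env in cfg.environments:
        order = rng.permutation(cfg.n_genotypes)
        for k, gi in enumerate(order):
            if k % cfg.plots_per_row == 0:
                row_counter += 1
            rows.append(
                {
                    "plot_id": f"{env}-P{k:03d}",
                    "genotype": genotypes.genotype_ids[gi],
                    "environment": env,
                    "treatment": env.split("-")[-1],
                    "row": row_counter,
                    "position": k % cfg.plots_per_row,
                }
            )
    return pd.DataFrame(rows)


def simulate_trial(cfg: SimConfig):
    """Full synthetic trial.

    Returns (design, phenotypes, moisture_obs, manual_heights, truth):

    - design: plot_id, genotype, environment, treatment, row, position
    - phenotypes: observed canopy height, long (plot_id, day, trait, value)
    - moisture_obs: sparse measurements (row, position, day, value) on the
      measured plot subset, two groups measured on alternating days
    - manual_heights: unbiased ground-truth heights on reference plots
    - truth: :class:`GroundTruth`
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes = simulate_genotypes(cfg, rng)
    kernel = build_linear_kernel(genotypes)
    design = _make_design(cfg, genotypes, rng)
    days = cfg.days
    nD = len(days)

    # dense moisture truth per plot (row by row, same watering tube)
    moisture = np.empty((len(design), nD))
    for (env, row_id), g in design.groupby(["environment", "row"]):
        treatment = env.split("-")[-1]
        block = simulate_soil_moisture(cfg, treatment, n_plots=len(g), rng=rng)
        moisture[g.index.to_numpy(), :] = block

    # ground-truth reaction norms on the realised moisture support
    basis = build_basis(moisture.ravel(), cfg.Q_true)
    coefs, alphas, labels = simulate_true_reaction_norms(cfg, genotypes, kernel, rng)

    geno_idx = design["genotype"].map(
        {g: k for k, g in enumerate(genotypes.genotype_ids)}
    ).to_numpy()
    # initial size: log-normal with a heritable early-vigour component
    xc0 = genotypes.scores - genotypes.scores.mean(axis=0)
    p0 = (genotypes.scores.mean(axis=0) + 1.0) / 2.0
    den0 = np.sqrt(max(2.0 * np.sum(p0 * (1.0 - p0)), 1e-12))
    gv = xc0 @ rng.standard_normal(cfg.n_markers) / den0
    gv = gv * np.sqrt(cfg.h2_initial) * cfg.initial_size_cv
    log_init = (
        gv[geno_idx]
        + rng.normal(0.0, np.sqrt(1.0 - cfg.h2_initial) * cfg.initial_size_cv, size=len(design))
    )
    init = cfg.initial_size * np.exp(log_init)

    # realized growth floors at 0 (plants do not shrink); the unclipped
    # spline values are also kept — they are what the growth recursion
    # ŷ_d = ŷ_{d-1} + SP(s) reproduces exactly
    growth_true = np.zeros((len(design), nD))
    growth_real = np.zeros((len(design), nD))
    growth_spline = np.zeros((len(design), nD))
    for k in range(1, nD):
        phi = basis.design(moisture[:, k - 1])               # [n_plots, Q]
        c = coefs[:, geno_idx, k].T                          # [n_plots, Q]
        sp = np.sum(phi * c, axis=1)
        growth_spline[:, k] = sp
        growth_true[:, k] = np.maximum(sp, 0.0)
        noise = (
            rng.normal(0.0, cfg.noise_sd_growth, size=len(design))
            if cfg.noise_sd_growth > 0
            else 0.0
        )
        growth_real[:, k] = np.maximum(sp + noise, 0.0)
    traj_true = init[:, None] + np.cumsum(growth_true, axis=1)
    traj_real = init[:, None] + np.cumsum(growth_real, axis=1)
    traj_spline = init[:, None] + np.cumsum(growth_spline, axis=1)

    bias = rng.uniform(cfg.bias_range[0], cfg.bias_range[1], size=nD)
    obs_noise = (
        rng.normal(0.0, cfg.noise_sd_obs, size=traj_real.shape)
        if cfg.noise_sd_obs > 0
        else np.zeros_like(traj_real)
    )
    observed = bias[None, :] * traj_real + obs_noise

    phenotypes = pd.DataFrame(
        {
            "plot_id": np.repeat(design["plot_id"].to_numpy(), nD),
            "day": np.tile(days, len(design)),
            "trait": "canopy_height",
            "value": observed.ravel(),
        }
    )

    # manual heights: first plots of each environment, measured daily, no bias
    manual_rows = []
    for env, g in design.groupby("environment"):
        chosen = g.index.to_numpy()[: cfg.manual_plots_per_env]
        for idx in chosen:
            for k, d in enumerate(days):
                manual_rows.append(
                    {
                        "plot_id": design.loc[idx, "plot_id"],
                        "day": int(d),
                        "value": traj_real[idx, k],
                    }
                )
    manual_heights = pd.DataFrame(manual_rows)

    # sparse moisture observations: every k-th position, alternating days
    obs_rows = []
    for (env, row_id), g in design.groupby(["environment", "row"]):
        g = g.sort_values("position")
        measured = g[g["position"] % cfg.moisture_measured_every == 0]
        for gi, (idx, plot) in enumerate(measured.iterrows()):
            group = gi % cfg.n_missing_groups
            for k, d in enumerate(days):
                if k % cfg.n_missing_groups != group:
                    continue
                obs_rows.append(
                    {
                        "row": row_id,
                        "position": plot["position"],
                        "day": int(d),
                        "value": moisture[idx, k],
                    }
                )
    moisture_obs = pd.DataFrame(obs_rows)

    truth = GroundTruth(
        true_coefs=coefs,
        basis=basis,
        marker_effects=alphas,
        true_growth=growth_true,
        true_trajectory=traj_true,
        true_bias=pd.Series(bias, index=days.astype(float)),
        days=days,
        plot_ids=design["plot_id"].tolist(),
        class_labels=labels,
        extras={
            "moisture_dense": moisture,
            "genotypes": genotypes,
            "kernel": kernel,
            "growth_realized": growth_real,
            "trajectory_realized": traj_real,
            "growth_unclipped": growth_spline,
            "trajectory_unclipped": traj_spline,
            "initial_size": init,
        },
    )
    return design, phenotypes, moisture_obs, manual_heights, truth
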