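import numpy as np
import pandas as pd
import pytest

from growthnorm.synthetic import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A small complete trial shared by read-only tests."""
    cfg = SimConfig(n_genotypes=12, n_markers=120, day_start=15, day_end=40, seed=11)
    design, phenotypes, moisture_obs, manual, truth = simulate_trial(cfg)
    return dict(
        cfg=cfg,
        design=design,
        phenotypes=phenotypes,
        moisture_obs=moisture_obs,
        manual=manual,
        truth=truth,
    )


@pytest.fixture(scope="session")
def noise_free_trial():
    """Noise-free, unit-bias trial: observed equals truth exactly."""
    cfg = SimConfig(
        n_genotypes=10,
        n_markers=100,
        day_start=15,
        day_end=40,
        noise_sd_growth=0.0,
        noise_sd_obs=0.0,
        moisture_noise_sd=0.0,
        bias_range=(1.0, 1.0),
        initial_size_cv=0.0,
        seed=21,
    )
    design, phenotypes, moisture_obs, manual, truth = simulate_trial(cfg)
    return dict(
        cfg=cfg,
        design=design,
        phenotypes=phenotypes,
        moisture_obs=moisture_obs,
        manual=manual,
        truth=truth,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sp_training_table(design, truth, realized=False):
    """Long (genotype, day, s_prev, dy) table straight from simulation truth."""
    days = truth.days.astype(float)
    moist = truth.extras["moisture_dense"]
    growth = truth.extras["growth_realized"] if realized else truth.true_growth
    meta = design.reset_index(drop=True)
    rows = []
    for pi in range(len(meta)):
        g = meta.loc[pi, "genotype"]
        for k in range(1, len(days)):
            rows.append(
                {
                    "genotype": g,
                    "day": days[k],
                    "s_prev": moist[pi, k - 1],
                    "dy": growth[pi, k],
                }
            )
    return pd.DataFrame(rows)
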