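"""Shared fixtures: small synthetic cohorts with known truth."""
import dataclasses

import pytest

from twingem.datatypes import ACEParams
from twingem.simulate import (
    SimulationConfig,
    apply_censoring,
    default_config,
    make_incomplete,
    simulate_dataset,
)

SEED = 1234


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=SEED)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    """Default cohort after censoring and missingness (observed scale)."""
    df = simulate_dataset(default_cfg)
    df = apply_censoring(
        df, default_cfg.censoring_threshold, default_cfg.floor_value
    )
    return make_incomplete(
        df, default_cfg.incomplete_fraction, seed=SEED + 1
    )


def single_group_config(
    mean=535.0,
    sex_effect=0.0,
    ace=ACEParams(58.32, 6.48, 16.2),
    n_mz=1000,
    n_dz=1000,
    beta_pgs=0.0,
    pgs_dz_correlation=0.5,
    seed=SEED,
):
    """One-stratum cohort; defaults give the total-sample decomposition
    h2=0.72, c2=0.08 on the national 535/9 scale."""
    return SimulationConfig(
        group_means_girls=(mean,),
        sex_effect=(sex_effect,),
        ace_variances=(ace,),
        pgs_group_means=(0.0,),
        beta_pgs=beta_pgs,
        pgs_dz_correlation=pgs_dz_correlation,
        n_pairs_per_cell={"MZ": (n_mz,), "DZ": (n_dz,)},
        seed=seed,
    )


@pytest.fixture()
def small_censored_cohort():
    cfg = single_group_config(n_mz=800, n_dz=800)
    return cfg, apply_censoring(simulate_dataset(cfg))


def reseed(cfg, seed):
    return dataclasses.replace(cfg, seed=seed)
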