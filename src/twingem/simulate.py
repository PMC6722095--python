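"""Synthetic twin-cohort generator with known true parameters.

The generator emulates a large Dutch 12-year-old twin cohort scored on
a national achievement test (501-550 scale, hard ceiling at 550):

* four ordinal parental-SES strata with SES-increasing mean EA and
  SES-decreasing additive-genetic (A), common-environmental (C) and
  unique-environmental (E) variances;
* a small male advantage in mean EA that shrinks in the highest
  stratum;
* a standardized polygenic score (PGS) for educational attainment whose
  stratum means rise with SES (genotype-SES correlation), identical
  within MZ pairs and correlated ~0.5 within DZ pairs, with a positive
  effect on EA;
* right-censoring at the test ceiling, stronger in higher strata;
* ~14% of pairs with one twin's EA missing.

``ace_variances`` are *total* variance components: the part of the
additive-genetic variance tagged by the measured PGS (``beta_pgs**2 *
pgs_variance``) is carved out of A internally, so an ACE fit that
ignores the PGS recovers exactly the configured components, and with
the default DZ PGS correlation of 0.5 the MZ/DZ covariance structure is
unchanged.

Sampling uses one seed with named substreams (pgs, genetics, sexes) so
that toggling a downstream feature (e.g. missingness) does not perturb
the drawn cohort.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_FLOOR,
    DEFAULT_THRESHOLD,
    GROUP_LABELS,
    ACEParams,
)
from .exceptions import ConfigurationError

#: Published marginal moments of the national test score distribution.
NATIONAL_MEAN = 535.0
NATIONAL_SD = 9.0

# Default generating values: point estimates from censoring-corrected
# SES-stratified twin modelling of a large national twin register
# (lowest -> highest SES).
DEFAULT_GROUP_MEANS_GIRLS = (533.2, 535.8, 538.9, 542.0)
DEFAULT_SEX_EFFECT = (1.3, 1.2, 1.2, 0.3)
DEFAULT_ACE = (
    ACEParams(65.9, 2.7, 17.9),
    ACEParams(60.8, 1.8, 16.5),
    ACEParams(52.3, 0.0, 14.7),
    ACEParams(47.8, 0.0, 11.2),
)
#: Observed register cell counts (pairs) per SES stratum.
DEFAULT_CELLS = {"MZ": (320, 1030, 766, 363), "DZ": (571, 1859, 1378, 642)}

# PGS structure: stratum means rise with SES; the slope is a calibration
# constant set so the PGS accounts for ~10% of EA variance.
DEFAULT_PGS_GROUP_MEANS = (-0.3, -0.1, 0.1, 0.3)
DEFAULT_BETA_PGS = 2.85

DEFAULT_SEED = 1729


def _per_group(value, n_groups: int, name: str) -> tuple:
    """Broadcast a scalar to all groups, or validate a length-G tuple."""
    if np.isscalar(value):
        return tuple(float(value) for _ in range(n_groups))
    value = tuple(float(v) for v in value)
    if len(value) != n_groups:
        raise ConfigurationError(
            f"{name} must be scalar or length {n_groups}, got {len(value)}"
        )
    return value


@dataclass(frozen=True)
class SimulationConfig:
    """Full generating model for a synthetic twin cohort.

    ``n_pairs_per_cell`` maps zygosity to a per-SES-stratum tuple of
    pair counts.  ``group_means_girls`` are the realized latent girls'
    means per stratum (the generator folds the PGS stratum means into
    the intercepts so these are the recoverable quantities).
    """

    group_means_girls: tuple = DEFAULT_GROUP_MEANS_GIRLS
    sex_effect: Union[float, tuple] = DEFAULT_SEX_EFFECT
    ace_variances: tuple = DEFAULT_ACE
    pgs_group_means: Union[float, tuple] = DEFAULT_PGS_GROUP_MEANS
    pgs_variance: float = 1.0
    pgs_dz_correlation: float = 0.5
    beta_pgs: float = DEFAULT_BETA_PGS
    censoring_threshold: float = DEFAULT_THRESHOLD
    floor_value: float = DEFAULT_FLOOR
    incomplete_fraction: float = 0.14
    n_pairs_per_cell: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CELLS.items()}
    )
    seed: int = DEFAULT_SEED

    @property
    def n_groups(self) -> int:
        return len(self.group_means_girls)

    @property
    def group_labels(self) -> tuple:
        if self.n_groups == len(GROUP_LABELS):
            return GROUP_LABELS
        return tuple(f"g{i + 1}" for i in range(self.n_groups))

    def validate(self) -> None:
        g = self.n_groups
        if g < 1:
            raise ConfigurationError("at least one SES group is required")
        _per_group(self.sex_effect, g, "sex_effect")
        _per_group(self.pgs_group_means, g, "pgs_group_means")
        if len(self.ace_variances) != g:
            raise ConfigurationError("ace_variances must have one entry per group")
        pgs_var_share = self.beta_pgs**2 * self.pgs_variance
        for label, ace in zip(self.group_labels, self.ace_variances):
            if not isinstance(ace, ACEParams):
                raise ConfigurationError("ace_variances entries must be ACEParams")
            if self.beta_pgs != 0 and ace.a2 < pgs_var_share:
                raise ConfigurationError(
                    f"group {label}: PGS-tagged variance {pgs_var_share:.2f} "
                    f"exceeds total additive-genetic variance {ace.a2:.2f}"
                )
        if not (math.isfinite(self.pgs_variance) and self.pgs_variance >= 0):
            raise ConfigurationError("pgs_variance must be finite and >= 0")
        if not -1.0 <= self.pgs_dz_correlation <= 1.0:
            raise ConfigurationError("pgs_dz_correlation outside [-1, 1]")
        if not self.censoring_threshold > self.floor_value:
            raise ConfigurationError("censoring_threshold must exceed floor_value")
        if not 0.0 <= self.incomplete_fraction < 1.0:
            raise ConfigurationError("incomplete_fraction outside [0, 1)")
        for zyg in ("MZ", "DZ"):
            counts = self.n_pairs_per_cell.get(zyg, ())
            if len(counts) != g or any(int(n) < 0 for n in counts):
                raise ConfigurationError(
                    f"n_pairs_per_cell[{zyg!r}] must give a count per group"
                )
        if not all(
            a < b for a, b in zip(self.group_means_girls, self.group_means_girls[1:])
        ) and g > 1:
            raise ConfigurationError("group means must increase strictly with SES")

    def sex_effects(self) -> tuple:
        return _per_group(self.sex_effect, self.n_groups, "sex_effect")

    def pgs_means(self) -> tuple:
        return _per_group(self.pgs_group_means, self.n_groups, "pgs_group_means")

    def group_weights(self) -> np.ndarray:
        """Twin-pair proportion per SES stratum implied by the cell counts."""
        totals = np.array(
            [
                self.n_pairs_per_cell["MZ"][g] + self.n_pairs_per_cell["DZ"][g]
                for g in range(self.n_groups)
            ],
            dtype=float,
        )
        return totals / totals.sum()

    def expected_marginal_moments(self) -> tuple:
        """Expected mean and SD of latent EA across the whole cohort."""
        w = self.group_weights()
        means = np.array(self.group_means_girls) + 0.5 * np.array(self.sex_effects())
        sexvar = 0.25 * np.array(self.sex_effects()) ** 2
        totals = np.array([ace.total for ace in self.ace_variances])
        mean = float(w @ means)
        var = float(w @ (totals + sexvar) + w @ (means - mean) ** 2)
        return mean, math.sqrt(var)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ace_variances"] = [ace.as_tuple() for ace in self.ace_variances]
        d["n_pairs_per_cell"] = {k: list(v) for k, v in self.n_pairs_per_cell.items()}
        return d


def default_config(seed: int = DEFAULT_SEED, n_scale: float = 1.0) -> SimulationConfig:
    """Default cohort configuration.

    Stratum contrasts (means, sex effects, A/C/E components) are the
    reference point estimates above; the overall level is anchored so
    that the cohort-weighted latent EA mean equals the national test
    mean of 535 (the stratum estimates come from a register sample that
    over-represents high-SES families, so their weighted mean sits a few
    points above the national norm).  With the default cell counts the
    implied marginal SD is ~9, matching the published national SD.

    ``n_scale`` multiplies every cell count (rounded), preserving the
    SES composition.
    """
    means = np.array(DEFAULT_GROUP_MEANS_GIRLS)
    cells = {
        zyg: tuple(int(round(n * n_scale)) for n in DEFAULT_CELLS[zyg])
        for zyg in ("MZ", "DZ")
    }
    base = SimulationConfig(seed=seed, n_pairs_per_cell=cells)
    shift = base.expected_marginal_moments()[0] - NATIONAL_MEAN
    cfg = dataclasses.replace(
        base, group_means_girls=tuple(float(m) for m in np.round(means - shift, 6))
    )
    cfg.validate()
    return cfg


def _simulate_cell(
    cfg: SimulationConfig,
    g: int,
    zygosity: str,
    n: int,
    rng_pgs: np.random.Generator,
    rng_gen: np.random.Generator,
    rng_sex: np.random.Generator,
) -> pd.DataFrame:
    ace = cfg.ace_variances[g]
    beta = cfg.beta_pgs
    pgs_sd = math.sqrt(cfg.pgs_variance)
    a2_resid = ace.a2 - beta**2 * cfg.pgs_variance
    intercept = cfg.group_means_girls[g] - beta * cfg.pgs_means()[g]

    if zygosity == "MZ":
        z = rng_pgs.standard_normal(n)
        pgs1 = pgs2 = cfg.pgs_means()[g] + pgs_sd * z
        a_shared = rng_gen.standard_normal(n)
        a1 = a2_ = math.sqrt(a2_resid) * a_shared
        sex1 = sex2 = rng_sex.integers(0, 2, size=n)
    else:
        r = cfg.pgs_dz_correlation
        z1 = rng_pgs.standard_normal(n)
        z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng_pgs.standard_normal(n)
        pgs1 = cfg.pgs_means()[g] + pgs_sd * z1
        pgs2 = cfg.pgs_means()[g] + pgs_sd * z2
        ac = rng_gen.standard_normal(n)
        s_half = math.sqrt(0.5)
        a1 = math.sqrt(a2_resid) * (s_half * ac + s_half * rng_gen.standard_normal(n))
        a2_ = math.sqrt(a2_resid) * (s_half * ac + s_half * rng_gen.standard_normal(n))
        sex1 = rng_sex.integers(0, 2, size=n)
        sex2 = rng_sex.integers(0, 2, size=n)

    c_shared = math.sqrt(ace.c2) * rng_gen.standard_normal(n)
    e1 = math.sqrt(ace.e2) * rng_gen.standard_normal(n)
    e2 = math.sqrt(ace.e2) * rng_gen.standard_normal(n)
    d = cfg.sex_effects()[g]
    ea1 = intercept + d * sex1 + beta * pgs1 + a1 + c_shared + e1
    ea2 = intercept + d * sex2 + beta * pgs2 + a2_ + c_shared + e2
    return pd.DataFrame(
        {
            "zygosity": zygosity,
            "ses": g + 1,
            "sex1": np.where(sex1 == 1, "M", "F"),
            "sex2": np.where(sex2 == 1, "M", "F"),
            "ea1": ea1,
            "ea2": ea2,
            "cens1": False,
            "cens2": False,
            "pgs1": pgs1,
            "pgs2": pgs2,
        }
    )


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw a latent twin cohort (no censoring or missingness applied).

    Latent EA of twin *i* is ``intercept_g + sex_effect_g * I(male) +
    beta_pgs * PGS_i + A_i + C_pair + E_i`` with the additive-genetic
    deviations correlated 1 (MZ) / 0.5 (DZ) within pairs and PGS pairs
    correlated 1 (MZ) / ``pgs_dz_correlation`` (DZ).  Deterministic
    given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    rng_pgs = np.random.default_rng(kids[0])
    rng_gen = np.random.default_rng(kids[1])
    rng_sex = np.random.default_rng(kids[2])
    frames = []
    for g in range(config.n_groups):
        for zyg in ("MZ", "DZ"):
            n = int(config.n_pairs_per_cell[zyg][g])
            if n:
                frames.append(
                    _simulate_cell(config, g, zyg, n, rng_pgs, rng_gen, rng_sex)
                )
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "family_id", [f"fam{i:06d}" for i in range(len(df))])
    return df


def apply_censoring(
    data: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    floor_value: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Right-censor latent EA at ``threshold`` and clip at the floor.

    Latent values at or above the threshold are stored at the threshold
    with the censoring flag set.  Values below ``floor_value`` are
    clipped to it *without* a flag: the instrument's floor carries
    negligible mass under realistic parameters and is not modelled in
    the likelihood.  ``threshold = +inf`` is a no-op.
    """
    if not threshold > floor_value:
        raise ConfigurationError("threshold must exceed floor_value")
    out = data.copy()
    for side in ("1", "2"):
        y = out[f"ea{side}"].to_numpy(dtype=float)
        cens = np.nan_to_num(y, nan=-np.inf) >= threshold
        y = np.where(cens, threshold, y)
        y = np.where(np.nan_to_num(y, nan=np.inf) < floor_value, floor_value, y)
        out[f"ea{side}"] = y
        out[f"cens{side}"] = cens
    return out


def make_incomplete(
    data: pd.DataFrame,
    fraction: float,
    seed: int,
    pgs_fraction: float = 0.0,
) -> pd.DataFrame:
    """Remove one twin's EA in a random ``fraction`` of pairs.

    Each pair is selected independently with probability ``fraction``;
    in a selected pair one random side loses its EA value (and its
    censoring flag), so no pair ever has both EA values missing.  PGS
    values are removed independently per twin with ``pgs_fraction``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("fraction outside [0, 1)")
    if not 0.0 <= pgs_fraction < 1.0:
        raise ConfigurationError("pgs_fraction outside [0, 1)")
    out = data.copy()
    rng = np.random.default_rng(seed)
    hit = rng.random(len(out)) < fraction
    side = rng.integers(1, 3, size=len(out))
    for s in (1, 2):
        drop = hit & (side == s)
        out.loc[drop, f"ea{s}"] = np.nan
        out.loc[drop, f"cens{s}"] = False
        if pgs_fraction > 0:
            out.loc[rng.random(len(out)) < pgs_fraction, f"pgs{s}"] = np.nan
    return out


def write_truth_manifest(config: SimulationConfig, path) -> None:
    """Persist the generating parameters for parameter-recovery tests."""
    manifest = {
        "config": config.to_dict(),
        "group_labels": list(config.group_labels),
        "expected_marginal_mean": config.expected_marginal_moments()[0],
        "expected_marginal_sd": config.expected_marginal_moments()[1],
        "phenotypic_variances": [ace.total for ace in config.ace_variances],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
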