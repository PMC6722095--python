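"""Core domain types for twin-pair ACE modelling with censoring.

The unit of analysis is a twin pair: two children with the same family
identifier, a zygosity (MZ or DZ), a four-level parental socioeconomic
status (SES), per-twin sex, per-twin score on a national educational
achievement (EA) test bounded at 501-550 and right-censored at the
ceiling of 550, and an optional standardized polygenic score (PGS) for
educational attainment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

from .exceptions import ConfigurationError, DataValidationError

#: Ordinal labels for the four SES strata, lowest to highest.
GROUP_LABELS = ("lowest", "low", "high", "highest")

#: Hard maximum of the EA test; a stored score equal to this value is
#: always treated as right-censored.
DEFAULT_THRESHOLD = 550.0

#: Hard minimum of the EA test (not modelled as censoring, see docs).
DEFAULT_FLOOR = 501.0


def group_label(ses: int) -> str:
    """Map an SES code (1..4, 1 = lowest) to its ordinal label."""
    if not 1 <= int(ses) <= len(GROUP_LABELS):
        raise DataValidationError(f"SES code must be in 1..4, got {ses!r}")
    return GROUP_LABELS[int(ses) - 1]


@dataclass(frozen=True)
class ACEParams:
    """Unstandardized variance components of the classical twin model.

    Attributes
    ----------
    a2 : float
        Additive-genetic variance (score units squared).
    c2 : float
        Common (shared) environmental variance.
    e2 : float
        Unique (non-shared) environmental variance, which also absorbs
        measurement error.
    """

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        """Phenotypic variance implied by the decomposition."""
        return self.a2 + self.c2 + self.e2

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a2, self.c2, self.e2)


@dataclass(frozen=True)
class PairMoments:
    """First and second moments of the latent bivariate-normal pair."""

    mu1: float
    mu2: float
    v1: float
    v2: float
    cov: float

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.v2 <= 0:
            raise ConfigurationError("variances must be positive")
        if abs(self.cov) > math.sqrt(self.v1 * self.v2) + 1e-12:
            raise ConfigurationError("covariance exceeds Cauchy-Schwarz bound")

    @property
    def corr(self) -> float:
        return self.cov / math.sqrt(self.v1 * self.v2)


@dataclass(frozen=True)
class TwinPairRecord:
    """One twin pair.

    EA values of ``None`` denote missingness (at most one per pair).  A
    censored EA value is stored at the threshold with its flag set.
    """

    family_id: str
    zygosity: str  # "MZ" | "DZ"
    ses: int  # 1..4, 1 = lowest
    sex1: str  # "F" | "M"
    sex2: str
    ea1: Optional[float] = None
    ea2: Optional[float] = None
    cens1: bool = False
    cens2: bool = False
    pgs1: Optional[float] = None
    pgs2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise DataValidationError(f"unknown zygosity {self.zygosity!r}")
        group_label(self.ses)
        for s in (self.sex1, self.sex2):
            if s not in ("F", "M"):
                raise DataValidationError(f"unknown sex code {s!r}")
        if self.zygosity == "MZ" and self.sex1 != self.sex2:
            raise DataValidationError("MZ pair with discordant sexes")
        if self.ea1 is None and self.ea2 is None:
            raise DataValidationError("both EA values missing in one pair")

    @property
    def ses_label(self) -> str:
        return group_label(self.ses)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a twin-model parameterization.

    The free-parameter count is a pure function of the spec (given the
    number of SES groups in the data):

    * intercepts: one per group if ``stratify_means_by_ses`` else one;
    * sex effect: one if ``equate_sex_effect``, else per group when
      means are stratified;
    * PGS slope (only if ``include_pgs``): one if ``equate_pgs_slopes``
      else one per group;
    * variance components: (A, C, E) or (A, E) per group if
      ``stratify_variances_by_ses`` else shared.
    """

    stratify_means_by_ses: bool = False
    stratify_variances_by_ses: bool = False
    include_c: bool = True
    include_pgs: bool = False
    equate_pgs_slopes: bool = True
    equate_sex_effect: bool = True
    censoring: bool = True
    threshold: float = DEFAULT_THRESHOLD

    def n_free_params(self, n_groups: int) -> int:
        g = n_groups
        n = g if self.stratify_means_by_ses else 1
        n += 1 if self.equate_sex_effect else (g if self.stratify_means_by_ses else 1)
        if self.include_pgs:
            n += 1 if self.equate_pgs_slopes else g
        per_group = 3 if self.include_c else 2
        n += per_group * (g if self.stratify_variances_by_ses else 1)
        return n

    def is_restriction_of(self, parent: "ModelSpec") -> bool:
        """True when every freedom of this spec is also free in ``parent``.

        Conservative structural check used by the likelihood-ratio test;
        parameter fixing applied at fit time is checked separately.
        """
        if (self.censoring, self.threshold, self.include_pgs) != (
            parent.censoring,
            parent.threshold,
            parent.include_pgs,
        ):
            return False
        freedoms = (
            ("stratify_means_by_ses", True),
            ("stratify_variances_by_ses", True),
            ("include_c", True),
            ("equate_pgs_slopes", False),
            ("equate_sex_effect", False),
        )
        for name, free_value in freedoms:
            child_free = getattr(self, name) == free_value
            parent_free = getattr(parent, name) == free_value
            if child_free and not parent_free:
                return False
        return True

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown ModelSpec fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``estimates`` maps public parameter names (``mu[low]``, ``bsex``,
    ``bpgs[highest]``, ``a2[lowest]``, ...) to values on their natural
    scale (variances, not standard deviations).
    """

    spec: ModelSpec
    estimates: dict
    minus2ll: float
    n_free_params: int
    converged: bool
    n_pairs: int
    groups: tuple
    fixed: dict = field(default_factory=dict)
    ci: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def _g(self, name: str, group: Optional[str]) -> float:
        if name in self.estimates:
            return self.estimates[name]
        if group is None and len(self.groups) == 1:
            group = self.groups[0]
        key = f"{name}[{group}]"
        if key not in self.estimates:
            raise KeyError(f"no parameter {name!r} for group {group!r}")
        return self.estimates[key]

    def ace(self, group: Optional[str] = None) -> ACEParams:
        """Variance components, for ``group`` or shared."""
        c2 = self._g("c2", group) if self.spec.include_c else 0.0
        return ACEParams(self._g("a2", group), c2, self._g("e2", group))

    def mean(self, group: Optional[str] = None, sex: str = "F") -> float:
        """Model-implied latent mean for a twin of given sex (PGS at 0)."""
        mu = self._g("mu", group)
        if sex == "M":
            mu += self._g("bsex", group)
        return mu

    def pgs_slope(self, group: Optional[str] = None) -> float:
        return self._g("bpgs", group)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested models."""

    delta_minus2ll: float
    delta_df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.delta_df <= 0:
            raise ConfigurationError("delta_df must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ConfigurationError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    """ML estimate of a within-pair correlation with optional CI."""

    rho: float
    ci: Optional[tuple] = None
    n_pairs: int = 0
    minus2ll: float = float("nan")
    converged: bool = True


@dataclass
class WithinFamilyResult:
    """DZ higher-vs-lower-PGS co-twin contrast.

    ``mean_ea_gap`` is the FIML estimate of the EA advantage of the
    higher-PGS twin under the censored pair likelihood; ``lrt`` tests it
    against the zero-gap model with one degree of freedom.
    """

    mean_pgs_gap: float
    mean_ea_gap: float
    lrt: LRTResult
    n_pairs: int
    n_ties_dropped: int = 0
    regression_slope: Optional[float] = None
    sex_gap_coef: Optional[float] = None
    minus2ll: float = float("nan")
    ci: Optional[tuple] = None
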