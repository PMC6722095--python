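"""Exact log-likelihood kernel for twin pairs under right-censoring.

A pair's latent EA scores are modelled as bivariate normal.  The test
ceiling induces right-censoring: a recorded score equal to the threshold
only tells us that the latent score was at or above it.  Full-information
maximum likelihood then requires one of eight observation patterns per
pair, combining per-twin states observed (O), censored (C) and missing:

======== =============================================================
pattern  contribution to the likelihood
======== =============================================================
OO       bivariate normal density
OC / CO  density(observed) x P(co-twin latent > threshold | observed)
CC       rectangle probability P(both latents > threshold)
O_ / _O  univariate normal density (FIML for incomplete pairs)
C_ / _C  univariate survival probability
======== =============================================================

The rectangle probability is evaluated by reducing to the conditional
form  P(Z1>h, Z2>k) = int_h^inf phi(z) PhiBar((k - rho z)/sqrt(1-rho^2)) dz
and applying fixed-panel Gauss-Legendre quadrature, which is accurate to
well below 1e-10 over the whole parameter range (verified against closed
forms and Monte Carlo in the test suite) and vectorizes over pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import log_ndtr, ndtr

from .datatypes import DEFAULT_THRESHOLD, PairMoments, TwinPairRecord
from .exceptions import DataValidationError, LikelihoodError

_LOG_2PI = float(np.log(2.0 * np.pi))
_SQRT_2PI = float(np.sqrt(2.0 * np.pi))

# Quadrature layout: the integrand is a Gaussian density times a smooth
# sigmoid, supported on (h, ~10); 8 panels of 24-point Gauss-Legendre
# resolve it to ~1e-14 absolute.
_ZMAX = 10.0
_N_PANELS = 8
_GL_X, _GL_W = leggauss(24)
_GL_OFFSET = (np.arange(_N_PANELS)[:, None] + 0.5 * (_GL_X[None, :] + 1.0)).ravel()
_GL_WEIGHT = np.tile(0.5 * _GL_W, _N_PANELS)

_RHO_EDGE = 1.0 - 1e-9

_PATTERNS = ("OO", "OC", "CO", "CC", "O_", "C_", "_O", "_C")


def classify_pattern(
    y1: Optional[float], y2: Optional[float], c1: bool, c2: bool
) -> str:
    """Derive the observation pattern of a pair.

    A missing value with its censoring flag set is inconsistent and
    rejected.
    """
    if y1 is None and c1:
        raise DataValidationError("twin 1 marked censored but has no value")
    if y2 is None and c2:
        raise DataValidationError("twin 2 marked censored but has no value")
    s1 = "_" if y1 is None else ("C" if c1 else "O")
    s2 = "_" if y2 is None else ("C" if c2 else "O")
    if s1 == "_" and s2 == "_":
        raise DataValidationError("both EA values missing in one pair")
    return s1 + s2


@dataclass(frozen=True)
class PairObservation:
    """A single pair's (possibly censored, possibly incomplete) scores."""

    y1: Optional[float]
    y2: Optional[float]
    c1: bool = False
    c2: bool = False

    @property
    def pattern(self) -> str:
        return classify_pattern(self.y1, self.y2, self.c1, self.c2)


def _bvn_upper_vec(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Vectorized P(Z1 > h, Z2 > k); requires |rho| < 1.

    Infinite lower limits are handled by the integration window itself:
    mass outside (-10, 10) is below 8e-24.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    s = np.sqrt(1.0 - rho * rho)
    lo = np.clip(h, -_ZMAX, _ZMAX)
    width = (_ZMAX - lo) / _N_PANELS
    z = lo[..., None] + width[..., None] * _GL_OFFSET
    w = width[..., None] * _GL_WEIGHT
    phi = np.exp(-0.5 * z * z) / _SQRT_2PI
    # PhiBar((k - rho z)/s) written as Phi((rho z - k)/s)
    tail = ndtr((rho[..., None] * z - k[..., None]) / s[..., None])
    out = np.sum(w * phi * tail, axis=-1)
    return np.clip(out, 0.0, 1.0)


def bvn_upper_rect(h: float, k: float, rho: float) -> float:
    """Upper-rectangle probability P(Z1 > h, Z2 > k) of a standard
    bivariate normal with correlation ``rho``.

    ``h`` and ``k`` may be ``-inf`` (or ``+inf``, giving 0).  The
    degenerate cases ``rho = +/-1`` use closed forms: for ``rho = 1``
    the pair is comonotone so the probability is ``PhiBar(max(h, k))``;
    for ``rho = -1`` it is ``max(0, Phi(-k) - Phi(h))``.
    """
    h, k, rho = float(h), float(k), float(rho)
    if np.isnan(h) or np.isnan(k) or np.isnan(rho) or abs(rho) > 1.0:
        raise LikelihoodError(f"invalid arguments h={h}, k={k}, rho={rho}")
    if h == np.inf or k == np.inf:
        return 0.0
    if rho >= _RHO_EDGE:
        return float(ndtr(-max(h, k)))
    if rho <= -_RHO_EDGE:
        return float(max(0.0, ndtr(-k) - ndtr(h)))
    return float(_bvn_upper_vec(np.array([h]), np.array([k]), np.array([rho]))[0])


class PairArrays:
    """Pattern-indexed arrays for fast repeated likelihood evaluation.

    Censored entries hold the threshold as their stored value.  The
    constructor derives the eight observation patterns once; evaluation
    then only slices.
    """

    def __init__(
        self,
        y1: np.ndarray,
        y2: np.ndarray,
        c1: np.ndarray,
        c2: np.ndarray,
        threshold: float,
    ):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        c1 = np.asarray(c1, dtype=bool)
        c2 = np.asarray(c2, dtype=bool)
        if not (y1.shape == y2.shape == c1.shape == c2.shape):
            raise DataValidationError("pair arrays must share one shape")
        miss1 = np.isnan(y1)
        miss2 = np.isnan(y2)
        if np.any(miss1 & c1) or np.any(miss2 & c2):
            raise DataValidationError("censoring flag set on a missing value")
        both = miss1 & miss2
        if np.any(both):
            raise DataValidationError(
                f"{int(both.sum())} pair(s) have both EA values missing"
            )
        if np.isfinite(threshold):
            bad1 = c1 & (np.abs(y1 - threshold) > 1e-8)
            bad2 = c2 & (np.abs(y2 - threshold) > 1e-8)
            if np.any(bad1) or np.any(bad2):
                raise DataValidationError(
                    "censored values must equal the censoring threshold"
                )
        self.threshold = float(threshold)
        self.n = y1.shape[0]
        self.y1, self.y2 = y1, y2
        obs1 = ~miss1 & ~c1
        obs2 = ~miss2 & ~c2
        self.i_oo = np.flatnonzero(obs1 & obs2)
        self.i_oc = np.flatnonzero(obs1 & c2)
        self.i_co = np.flatnonzero(c1 & obs2)
        self.i_cc = np.flatnonzero(c1 & c2)
        self.i_o1 = np.flatnonzero(obs1 & miss2)
        self.i_c1 = np.flatnonzero(c1 & miss2)
        self.i_o2 = np.flatnonzero(miss1 & obs2)
        self.i_c2 = np.flatnonzero(miss1 & c2)
        self.n_censored = int(c1.sum() + c2.sum())

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        censoring: bool = True,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "PairArrays":
        """Build arrays from the package-standard twin frame.

        A stored score equal to the threshold is always treated as
        censored (the flag is derived, not trusted).  With ``censoring``
        disabled all flags are cleared and ceiling values are treated as
        exact observations (the "naive" model).
        """
        y1 = df["ea1"].to_numpy(dtype=float)
        y2 = df["ea2"].to_numpy(dtype=float)
        if censoring and np.isfinite(threshold):
            c1 = np.nan_to_num(y1, nan=-np.inf) >= threshold - 1e-8
            c2 = np.nan_to_num(y2, nan=-np.inf) >= threshold - 1e-8
            y1 = np.where(c1, threshold, y1)
            y2 = np.where(c2, threshold, y2)
        else:
            c1 = np.zeros(len(y1), dtype=bool)
            c2 = np.zeros(len(y2), dtype=bool)
        return cls(y1, y2, c1, c2, threshold if censoring else np.inf)


def loglik_terms(
    pa: PairArrays,
    mu1: np.ndarray,
    mu2: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
    cov: np.ndarray,
) -> float:
    """Sum of pair log-likelihoods for moment arrays aligned with ``pa``.

    Raises :class:`LikelihoodError` when any pair's moment matrix is not
    positive definite.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    v1 = np.broadcast_to(np.asarray(v1, dtype=float), (pa.n,))
    v2 = np.broadcast_to(np.asarray(v2, dtype=float), (pa.n,))
    cov = np.broadcast_to(np.asarray(cov, dtype=float), (pa.n,))
    det = v1 * v2 - cov * cov
    if np.any(v1 <= 0.0) or np.any(v2 <= 0.0) or np.any(det <= 0.0):
        raise LikelihoodError("non-positive-definite pair moments")
    T = pa.threshold
    total = 0.0

    i = pa.i_oo
    if i.size:
        d1 = pa.y1[i] - mu1[i]
        d2 = pa.y2[i] - mu2[i]
        q = (v2[i] * d1 * d1 - 2.0 * cov[i] * d1 * d2 + v1[i] * d2 * d2) / det[i]
        total += np.sum(-0.5 * (2.0 * _LOG_2PI + np.log(det[i]) + q))

    for i, iy, imu, iv, jmu, jv in (
        (pa.i_oc, pa.y1, mu1, v1, mu2, v2),
        (pa.i_co, pa.y2, mu2, v2, mu1, v1),
    ):
        if i.size:
            d = iy[i] - imu[i]
            total += np.sum(-0.5 * (_LOG_2PI + np.log(iv[i]) + d * d / iv[i]))
            cm = jmu[i] + cov[i] / iv[i] * d
            cs = np.sqrt(det[i] / iv[i])
            total += np.sum(log_ndtr((cm - T) / cs))

    i = pa.i_cc
    if i.size:
        s1 = np.sqrt(v1[i])
        s2 = np.sqrt(v2[i])
        r = np.clip(cov[i] / (s1 * s2), -_RHO_EDGE, _RHO_EDGE)
        p = _bvn_upper_vec((T - mu1[i]) / s1, (T - mu2[i]) / s2, r)
        total += np.sum(np.log(np.maximum(p, 1e-300)))

    for i, iy, imu, iv in ((pa.i_o1, pa.y1, mu1, v1), (pa.i_o2, pa.y2, mu2, v2)):
        if i.size:
            d = iy[i] - imu[i]
            total += np.sum(-0.5 * (_LOG_2PI + np.log(iv[i]) + d * d / iv[i]))

    for i, imu, iv in ((pa.i_c1, mu1, v1), (pa.i_c2, mu2, v2)):
        if i.size:
            total += np.sum(log_ndtr((imu[i] - T) / np.sqrt(iv[i])))

    return float(total)


def pair_loglik(
    obs: PairObservation, mom: PairMoments, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Log-likelihood of a single pair under censored bivariate normality.

    The observation pattern is derived from ``obs``; censored values
    must equal ``threshold``.  In the uncensored limit
    ``threshold = +inf`` the OO pattern reduces to the plain bivariate
    normal log-density.
    """
    pattern = obs.pattern  # validates
    if np.isfinite(threshold):
        for y, c in ((obs.y1, obs.c1), (obs.y2, obs.c2)):
            if c and abs(float(y) - threshold) > 1e-8:
                raise DataValidationError(
                    f"censored value {y} differs from threshold {threshold}"
                )
    elif "C" in pattern:
        raise DataValidationError("censoring flags require a finite threshold")
    if mom.v1 * mom.v2 - mom.cov**2 <= 0:
        raise LikelihoodError("pair moments are not positive definite")
    y1 = np.nan if obs.y1 is None else float(obs.y1)
    y2 = np.nan if obs.y2 is None else float(obs.y2)
    pa = PairArrays(
        np.array([y1]), np.array([y2]),
        np.array([obs.c1]), np.array([obs.c2]),
        threshold,
    )
    return loglik_terms(
        pa,
        np.array([mom.mu1]),
        np.array([mom.mu2]),
        np.array([mom.v1]),
        np.array([mom.v2]),
        np.array([mom.cov]),
    )


MomentsSource = Union[
    Callable[[TwinPairRecord], PairMoments], Mapping[tuple, PairMoments]
]


def dataset_minus2ll(
    data: pd.DataFrame,
    moments: MomentsSource,
    threshold: float = DEFAULT_THRESHOLD,
    censoring: bool = True,
) -> float:
    """-2 times the summed pair log-likelihood of a twin frame.

    ``moments`` is either a callable mapping a :class:`TwinPairRecord`
    to :class:`PairMoments`, or a mapping keyed by ``(ses, zygosity)``.
    The result is additive over pairs, hence invariant to row order.
    """
    from .io import frame_to_records  # local import to avoid a cycle

    if len(data) == 0:
        return 0.0
    records = frame_to_records(data)
    mu1 = np.empty(len(records))
    mu2 = np.empty(len(records))
    v1 = np.empty(len(records))
    v2 = np.empty(len(records))
    cov = np.empty(len(records))
    for j, rec in enumerate(records):
        if callable(moments):
            mom = moments(rec)
        else:
            try:
                mom = moments[(rec.ses, rec.zygosity)]
            except KeyError as exc:
                raise LikelihoodError(
                    f"no moments for cell (ses={rec.ses}, {rec.zygosity})"
                ) from exc
        mu1[j], mu2[j] = mom.mu1, mom.mu2
        v1[j], v2[j], cov[j] = mom.v1, mom.v2, mom.cov
    pa = PairArrays.from_frame(data, censoring=censoring, threshold=threshold)
    return -2.0 * loglik_terms(pa, mu1, mu2, v1, v2, cov)
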