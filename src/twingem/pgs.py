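"""Polygenic-score analyses: between-family and within-family designs.

Three analyses relate a standardized educational-attainment PGS to EA:

1. :func:`pgs_by_ses_tests` - the PGS distribution itself across SES
   strata (between-family): stratified means/variances with MZ pairs
   contributing one informative value (their PGSs are identical) and DZ
   pairs a free within-pair correlation, against models equating the
   means or the variances across strata.
2. :func:`ea_on_pgs_fit` - EA regressed on PGS and sex within each SES
   group *inside* the censored twin model, the residual decomposed into
   A/C/E; slope and intercept homogeneity are testable by LRT.
3. :func:`within_family_test` - the DZ co-twin contrast: within each
   pair twins are ordered by PGS and the EA advantage of the higher-PGS
   twin is estimated under the censored pair likelihood.  Because both
   co-twins share their family (and hence parental SES), this design is
   immune to family-level confounding such as genotype-SES correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .datatypes import (
    CorrelationResult,
    FitResult,
    LRTResult,
    ModelSpec,
    WithinFamilyResult,
    group_label,
)
from .exceptions import DataValidationError, FitError
from .likelihood import PairArrays, loglik_terms
from .model import _scalar_profile_bound, fit, lrt, minimize_with_retry

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# 1. PGS distribution by SES


class _PGSProblem:
    """Gaussian model of pair PGS values with zygosity-aware correlation.

    MZ within-pair correlation is fixed at 1, so an MZ pair enters as a
    single observation; the DZ correlation is a free parameter.
    """

    def __init__(self, data: pd.DataFrame, stratify_means: bool, stratify_vars: bool):
        p1 = data["pgs1"].to_numpy(dtype=float)
        p2 = data["pgs2"].to_numpy(dtype=float)
        ses = data["ses"].to_numpy(dtype=int)
        mz = data["zygosity"].to_numpy() == "MZ"

        self.group_codes = tuple(sorted(np.unique(ses)))
        self.groups = tuple(group_label(s) for s in self.group_codes)
        code_to_idx = {s: i for i, s in enumerate(self.group_codes)}
        g = np.array([code_to_idx[s] for s in ses])

        both = ~np.isnan(p1) & ~np.isnan(p2)
        one = np.isnan(p1) ^ np.isnan(p2)
        mism = mz & both & (np.abs(p1 - p2) > 1e-6)
        if mism.any():
            logger.warning(
                "%d MZ pairs with unequal PGS values; using the pair mean",
                int(mism.sum()),
            )
        # singles: MZ pairs (one informative value) and incomplete pairs
        mz_val = np.where(both, 0.5 * (p1 + p2), np.where(np.isnan(p1), p2, p1))
        single_vals = [mz_val[mz & (both | one)]]
        single_g = [g[mz & (both | one)]]
        dz_one = ~mz & one
        single_vals.append(np.where(np.isnan(p1), p2, p1)[dz_one])
        single_g.append(g[dz_one])
        self.sv = np.concatenate(single_vals)
        self.sg = np.concatenate(single_g)
        dz_both = ~mz & both
        self.d1 = p1[dz_both]
        self.d2 = p2[dz_both]
        self.dg = g[dz_both]
        self.n_used = int(self.sv.size + 2 * self.d1.size)
        G = len(self.groups)
        covered = np.zeros(G, dtype=bool)
        covered[np.unique(np.concatenate([self.sg, self.dg]).astype(int))] = True
        if not covered.all():
            missing = [self.groups[i] for i in np.flatnonzero(~covered)]
            raise DataValidationError(f"SES groups without PGS data: {missing}")
        self.stratify_means = stratify_means
        self.stratify_vars = stratify_vars
        self.G = G
        self.n_free = (G if stratify_means else 1) + (G if stratify_vars else 1) + 1

    def unpack(self, theta):
        G = self.G
        i = 0
        if self.stratify_means:
            m = theta[:G]
            i = G
        else:
            m = np.full(G, theta[0])
            i = 1
        if self.stratify_vars:
            s = theta[i : i + G]
            i += G
        else:
            s = np.full(G, theta[i])
            i += 1
        return m, s, theta[i]

    def minus2ll(self, theta):
        m, s, rho = self.unpack(theta)
        v = s * s
        total = 0.0
        d = self.sv - m[self.sg]
        total += np.sum(-0.5 * (_LOG_2PI + np.log(v[self.sg]) + d * d / v[self.sg]))
        if self.d1.size:
            mu = m[self.dg]
            vv = v[self.dg]
            det = vv * vv * (1.0 - rho * rho)
            d1 = self.d1 - mu
            d2 = self.d2 - mu
            q = (vv * d1 * d1 - 2.0 * rho * vv * d1 * d2 + vv * d2 * d2) / det
            total += np.sum(-0.5 * (2.0 * _LOG_2PI + np.log(det) + q))
        return -2.0 * total

    def start(self):
        allv = np.concatenate([self.sv, self.d1, self.d2])
        m0, s0 = float(np.mean(allv)), float(np.std(allv) + 1e-6)
        x = []
        x += [m0] * (self.G if self.stratify_means else 1)
        x += [s0] * (self.G if self.stratify_vars else 1)
        r0 = 0.5
        if self.d1.size >= 3:
            r0 = float(np.clip(np.corrcoef(self.d1, self.d2)[0, 1], -0.9, 0.9))
        x.append(r0)
        return np.array(x)

    def bounds(self):
        b = [(None, None)] * (self.G if self.stratify_means else 1)
        b += [(1e-3, None)] * (self.G if self.stratify_vars else 1)
        b.append((-0.999, 0.999))
        return b


def _fit_pgs_problem(data, stratify_means, stratify_vars) -> FitResult:
    prob = _PGSProblem(data, stratify_means, stratify_vars)
    res = minimize_with_retry(prob.minus2ll, prob.start(), prob.bounds(),
                              maxiter=500)
    m, s, rho = prob.unpack(res.x)
    est = {}
    for i, lab in enumerate(prob.groups):
        est[f"pgs_mean[{lab}]" if stratify_means else "pgs_mean"] = float(m[i])
        est[f"pgs_var[{lab}]" if stratify_vars else "pgs_var"] = float(s[i] ** 2)
    est["rho_dz"] = float(rho)
    return FitResult(
        spec=None,
        estimates=est,
        minus2ll=float(res.fun),
        n_free_params=prob.n_free,
        converged=bool(res.success),
        n_pairs=len(data),
        groups=prob.groups,
    )


@dataclass
class PGSBySESResult:
    """Stratified PGS fit plus the two equality tests."""

    fit_stratified: FitResult
    fit_means_equated: FitResult
    fit_variances_equated: FitResult
    lrt_means: LRTResult
    lrt_variances: LRTResult


def pgs_by_ses_tests(data: pd.DataFrame) -> PGSBySESResult:
    """Stratified PGS means/variances and their SES-equality LRTs.

    Both tests carry ``n_groups - 1`` degrees of freedom; a significant
    mean test is the between-family signature of genotype-SES
    correlation.
    """
    full = _fit_pgs_problem(data, True, True)
    means_eq = _fit_pgs_problem(data, False, True)
    vars_eq = _fit_pgs_problem(data, True, False)
    return PGSBySESResult(
        fit_stratified=full,
        fit_means_equated=means_eq,
        fit_variances_equated=vars_eq,
        lrt_means=lrt(full, means_eq),
        lrt_variances=lrt(full, vars_eq),
    )


# ---------------------------------------------------------------------------
# 2. EA on PGS inside the censored twin model


def ea_on_pgs_fit(
    data: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    **fit_kwargs,
) -> FitResult:
    """Censored-FIML twin model with per-group intercepts and PGS slopes.

    The default spec stratifies intercepts, slopes and residual A/C/E by
    SES with a shared sex effect.  Slope or intercept homogeneity is
    tested by refitting with ``equate_pgs_slopes=True`` or
    ``stratify_means_by_ses=False`` and comparing via :func:`lrt`.
    """
    if spec is None:
        spec = ModelSpec(
            stratify_means_by_ses=True,
            stratify_variances_by_ses=True,
            include_c=True,
            include_pgs=True,
            equate_pgs_slopes=False,
            equate_sex_effect=True,
        )
    if not spec.include_pgs:
        raise DataValidationError("ea_on_pgs_fit requires include_pgs=True")
    return fit(data, spec, **fit_kwargs)


# ---------------------------------------------------------------------------
# 3. DZ PGS correlation and the within-family contrast


def dz_pgs_correlation(data: pd.DataFrame, level: float = 0.95) -> CorrelationResult:
    """ML within-pair PGS correlation in complete DZ pairs.

    The exchangeable bivariate-normal model (common mean and variance,
    free correlation) is the natural parameterization for twins, whose
    within-pair ordering is arbitrary.  Values above the biometrical
    expectation of 0.5 are consistent with assortative mating.  MZ pairs
    are excluded by design: their PGS correlation is fixed at 1.
    """
    dz = data[data["zygosity"] == "DZ"]
    p1 = dz["pgs1"].to_numpy(dtype=float)
    p2 = dz["pgs2"].to_numpy(dtype=float)
    ok = ~np.isnan(p1) & ~np.isnan(p2)
    if len(dz) == 0:
        raise DataValidationError(
            "no DZ pairs; the MZ PGS correlation is fixed at 1 and not estimable"
        )
    if int(ok.sum()) < 2:
        raise DataValidationError("need at least 2 complete DZ PGS pairs")
    x, y = p1[ok], p2[ok]
    n = x.size

    def minus2ll(theta):
        mu, s, rho = theta
        v = s * s
        det = v * v * (1 - rho * rho)
        d1, d2 = x - mu, y - mu
        q = (v * d1 * d1 - 2 * rho * v * d1 * d2 + v * d2 * d2) / det
        return float(np.sum(2.0 * _LOG_2PI + np.log(det) + q))

    mu0 = float(np.mean(np.concatenate([x, y])))
    s0 = float(np.std(np.concatenate([x, y])) + 1e-9)
    r0 = float(np.clip(np.corrcoef(x, y)[0, 1], -0.9, 0.9))
    res = minimize_with_retry(
        minus2ll, np.array([mu0, s0, r0]),
        [(None, None), (1e-6, None), (-0.999, 0.999)], maxiter=500,
    )
    rho_hat = float(res.x[2])
    ci = None
    if level is not None:
        target = float(res.fun) + float(chi2.ppf(level, 1))

        def prof(r):
            rr = optimize.minimize(
                minus2ll, np.array([res.x[0], res.x[1], r]), method="L-BFGS-B",
                bounds=[(None, None), (1e-6, None), (r, r)],
                options={"maxiter": 300, "ftol": 1e-12},
            )
            return rr.fun

        ci = (
            _scalar_profile_bound(prof, rho_hat, target, -1, 0.03, -0.999),
            _scalar_profile_bound(prof, rho_hat, target, +1, 0.03, 0.999),
        )
    return CorrelationResult(
        rho=rho_hat, ci=ci, n_pairs=n, minus2ll=float(res.fun),
        converged=bool(res.success),
    )


class _WithinFamilyProblem:
    """Censored pair likelihood of PGS-ordered DZ pairs.

    Twin 1 is the higher-PGS twin.  Means are ``m_g +/- (delta +
    gamma * sex_gap) / 2`` so that ``delta`` is the EA gap attributable
    to being the higher-PGS co-twin, ``gamma`` adjusts for the pair's
    sex composition, and the per-SES baselines ``m_g`` absorb all
    family-level (between-family) differences.
    """

    def __init__(self, yh, yl, sexgap, g, G, threshold, censoring, include_delta,
                 adjust_sex):
        ch = yh >= threshold - 1e-8 if censoring else np.zeros(len(yh), bool)
        cl = yl >= threshold - 1e-8 if censoring else np.zeros(len(yl), bool)
        self.pa = PairArrays(
            np.where(ch, threshold, yh), np.where(cl, threshold, yl), ch, cl,
            threshold if censoring else np.inf,
        )
        self.sexgap = sexgap
        self.g = g
        self.G = G
        self.include_delta = include_delta
        self.adjust_sex = adjust_sex
        self.n_free = G + include_delta + adjust_sex + 2

    def unpack(self, theta):
        m = theta[: self.G]
        i = self.G
        delta = 0.0
        gamma = 0.0
        if self.include_delta:
            delta = theta[i]
            i += 1
        if self.adjust_sex:
            gamma = theta[i]
            i += 1
        sd, rho = theta[i], theta[i + 1]
        return m, delta, gamma, sd, rho

    def minus2ll(self, theta):
        m, delta, gamma, sd, rho = self.unpack(theta)
        half = 0.5 * (delta + gamma * self.sexgap)
        mu1 = m[self.g] + half
        mu2 = m[self.g] - half
        v = np.full(self.pa.n, sd * sd)
        return -2.0 * loglik_terms(self.pa, mu1, mu2, v, v, rho * sd * sd)

    def bounds(self):
        b = [(None, None)] * self.G
        if self.include_delta:
            b.append((None, None))
        if self.adjust_sex:
            b.append((None, None))
        b += [(0.5, 60.0), (-0.999, 0.999)]
        return b

    def start(self, yh, yl):
        m0 = [float(np.mean(np.concatenate([yh[self.g == i], yl[self.g == i]])))
              for i in range(self.G)]
        x = list(m0)
        if self.include_delta:
            x.append(float(np.mean(yh - yl)))
        if self.adjust_sex:
            x.append(0.0)
        x += [float(np.std(np.concatenate([yh, yl])) + 1e-6), 0.3]
        return np.array(x)


def within_family_test(
    data: pd.DataFrame,
    adjust_sex: bool = True,
    censoring: bool = True,
    threshold: float = 550.0,
    min_pairs: int = 10,
    level: Optional[float] = None,
) -> WithinFamilyResult:
    """EA gap between the higher- and lower-PGS DZ co-twins.

    Uses complete DZ pairs with both PGS and both EA; exact PGS ties
    are dropped (logged).  The gap ``delta`` is estimated under the
    censored pair likelihood with per-SES baselines and tested against
    the zero-gap model with a 1-df LRT.  A secondary OLS of the EA
    difference on the PGS difference (and sex difference) is reported
    as ``regression_slope`` for sensitivity.
    """
    dz = data[data["zygosity"] == "DZ"]
    ok = (
        dz["pgs1"].notna() & dz["pgs2"].notna()
        & dz["ea1"].notna() & dz["ea2"].notna()
    )
    dz = dz[ok].reset_index(drop=True)
    p1 = dz["pgs1"].to_numpy(float)
    p2 = dz["pgs2"].to_numpy(float)
    ties = p1 == p2
    n_ties = int(ties.sum())
    if n_ties:
        logger.info("dropping %d DZ pairs with exactly tied PGS", n_ties)
        dz = dz[~ties].reset_index(drop=True)
        p1, p2 = p1[~ties], p2[~ties]
    if len(dz) < min_pairs:
        raise DataValidationError(
            f"need at least {min_pairs} usable DZ pairs, have {len(dz)}"
        )
    hi_is_1 = p1 > p2
    y1 = dz["ea1"].to_numpy(float)
    y2 = dz["ea2"].to_numpy(float)
    s1 = (dz["sex1"].to_numpy() == "M").astype(float)
    s2 = (dz["sex2"].to_numpy() == "M").astype(float)
    yh = np.where(hi_is_1, y1, y2)
    yl = np.where(hi_is_1, y2, y1)
    ph = np.where(hi_is_1, p1, p2)
    pl = np.where(hi_is_1, p2, p1)
    sexgap = np.where(hi_is_1, s1 - s2, s2 - s1)

    ses = dz["ses"].to_numpy(int)
    codes = sorted(np.unique(ses))
    gmap = {s: i for i, s in enumerate(codes)}
    g = np.array([gmap[s] for s in ses])
    G = len(codes)

    full = _WithinFamilyProblem(yh, yl, sexgap, g, G, threshold, censoring,
                                include_delta=True, adjust_sex=adjust_sex)
    x0 = full.start(yh, yl)
    res_full = minimize_with_retry(full.minus2ll, x0, full.bounds(), maxiter=500)
    null = _WithinFamilyProblem(yh, yl, sexgap, g, G, threshold, censoring,
                                include_delta=False, adjust_sex=adjust_sex)
    xn = np.delete(res_full.x, G)
    res_null = minimize_with_retry(null.minus2ll, xn, null.bounds(), maxiter=500)
    delta_hat = float(res_full.x[G])
    gamma_hat = float(res_full.x[G + 1]) if adjust_sex else None
    delta_m2 = max(0.0, float(res_null.fun) - float(res_full.fun))
    test = LRTResult(
        delta_minus2ll=delta_m2,
        delta_df=1,
        p_value=float(chi2.sf(delta_m2, 1)) if delta_m2 > 0 else 1.0,
    )

    import statsmodels.api as sm

    dy = yh - yl
    X = np.column_stack([ph - pl] + ([sexgap] if adjust_sex else []))
    ols = sm.OLS(dy, sm.add_constant(X)).fit()
    ci = None
    if level is not None:
        target = float(res_full.fun) + float(chi2.ppf(level, 1))

        def prof(v):
            xs = res_full.x.copy()
            xs[G] = v
            b = full.bounds()
            b[G] = (v, v)
            rr = optimize.minimize(
                full.minus2ll, xs, method="L-BFGS-B", bounds=b,
                options={"maxiter": 300, "ftol": 1e-11},
            )
            return rr.fun

        ci = (
            _scalar_profile_bound(prof, delta_hat, target, -1, 0.25, delta_hat - 50),
            _scalar_profile_bound(prof, delta_hat, target, +1, 0.25, delta_hat + 50),
        )
    if not (res_full.success and res_null.success):
        raise FitError("within-family fit did not converge")
    return WithinFamilyResult(
        mean_pgs_gap=float(np.mean(ph - pl)),
        mean_ea_gap=delta_hat,
        lrt=test,
        n_pairs=int(len(dz)),
        n_ties_dropped=n_ties,
        regression_slope=float(ols.params[1]),
        sex_gap_coef=gamma_hat,
        minus2ll=float(res_full.fun),
        ci=ci,
    )
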