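"""FIML estimation of saturated and ACE twin models with SES strata.

The classical twin design decomposes phenotypic variance into additive
genetic (A), common environmental (C) and unique environmental (E)
components from the differential resemblance of MZ pairs (sharing all
segregating alleles) and DZ pairs (sharing half on average): the
model-implied within-pair covariance is ``a2 + c2`` for MZ and
``0.5 a2 + c2`` for DZ pairs.  Means carry a per-twin sex covariate and
optionally a polygenic-score slope; any of the mean or variance blocks
can be stratified by the four SES groups.  All models are fitted by raw
full-information maximum likelihood on the censored bivariate-normal
pair likelihood, so incomplete pairs and ceiling scores contribute
exactly.

Variances are optimized on the standard-deviation scale (squared inside
the model) so that the C -> 0 boundary is reached cleanly; a2 and c2
estimates of exactly 0 are therefore legitimate boundary solutions.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .datatypes import (
    ACEParams,
    CorrelationResult,
    FitResult,
    LRTResult,
    ModelSpec,
    group_label,
)
from .exceptions import (
    DataValidationError,
    FitError,
    LikelihoodError,
    NotNestedError,
)
from .likelihood import PairArrays, loglik_terms

logger = logging.getLogger(__name__)

_SD_MAX = 60.0
_E_SD_MIN = 0.1  # identifiability floor for the unique-environment SD
_START_AGREEMENT = 5e-4


def implied_cov(ace: ACEParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 covariance block of a twin pair."""
    if zygosity not in ("MZ", "DZ"):
        raise DataValidationError(f"unknown zygosity {zygosity!r}")
    total = ace.total
    share = 1.0 if zygosity == "MZ" else 0.5
    off = share * ace.a2 + ace.c2
    return np.array([[total, off], [off, total]])


def standardize(ace: ACEParams) -> dict:
    """Proportions of phenotypic variance (h2, c2, e2); they sum to 1."""
    total = ace.total
    if total <= 0:
        raise DataValidationError("total variance must be positive")
    return {"h2": ace.a2 / total, "c2": ace.c2 / total, "e2": ace.e2 / total}


class FIMLProblem:
    """Objective, parameter layout and starting values for one ModelSpec.

    Public parameter names follow ``kind`` or ``kind[group]``: ``mu``
    (girls' intercept), ``bsex`` (male effect), ``bpgs`` (EA per PGS
    SD), and the variance components ``a2``, ``c2``, ``e2``.  The
    optimizer works on an internal vector where variance components are
    standard deviations.
    """

    _VAR_KINDS = {"a": "a2", "c": "c2", "e": "e2"}

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        fixed: Optional[dict] = None,
    ):
        self.spec = spec
        self.fixed = dict(fixed or {})
        df = data.reset_index(drop=True)
        if len(df) == 0:
            raise DataValidationError("empty dataset")

        self.n_dropped_for_pgs = 0
        if spec.include_pgs:
            df = df.copy()
            for s in ("1", "2"):
                no_pgs = df[f"pgs{s}"].isna() & df[f"ea{s}"].notna()
                self.n_dropped_for_pgs += int(no_pgs.sum())
                df.loc[no_pgs, f"ea{s}"] = np.nan
                df.loc[no_pgs, f"cens{s}"] = False
            keep = df["ea1"].notna() | df["ea2"].notna()
            if self.n_dropped_for_pgs:
                logger.info(
                    "PGS model: %d twins without PGS treated as missing, "
                    "%d pairs dropped entirely",
                    self.n_dropped_for_pgs,
                    int((~keep).sum()),
                )
            df = df.loc[keep].reset_index(drop=True)
            if len(df) == 0:
                raise DataValidationError("no pairs with PGS data")

        ses = df["ses"].to_numpy(dtype=int)
        self.group_codes = tuple(sorted(np.unique(ses)))
        self.groups = tuple(group_label(s) for s in self.group_codes)
        code_to_idx = {s: i for i, s in enumerate(self.group_codes)}
        self.g = np.array([code_to_idx[s] for s in ses])
        self.is_mz = (df["zygosity"].to_numpy() == "MZ")
        if self.spec.include_c and not self._c_fully_fixed():
            if self.is_mz.all() or (~self.is_mz).all():
                raise DataValidationError(
                    "separating A from C requires both MZ and DZ pairs"
                )
        self.s1 = (df["sex1"].to_numpy() == "M").astype(float)
        self.s2 = (df["sex2"].to_numpy() == "M").astype(float)
        if spec.include_pgs:
            self.p1 = np.nan_to_num(df["pgs1"].to_numpy(dtype=float))
            self.p2 = np.nan_to_num(df["pgs2"].to_numpy(dtype=float))
        self.pa = PairArrays.from_frame(
            df, censoring=spec.censoring, threshold=spec.threshold
        )
        self.df = df
        self._build_layout()

    def _c_fully_fixed(self) -> bool:
        names = (
            [f"c2[{lab}]" for lab in getattr(self, "groups", ())]
            if self.spec.stratify_variances_by_ses
            else ["c2"]
        )
        return bool(names) and all(n in self.fixed for n in names)

    # -- parameter layout -------------------------------------------------
    def _build_layout(self) -> None:
        spec = self.spec
        G = len(self.groups)
        kinds = [
            ("mu", spec.stratify_means_by_ses),
            ("bsex", spec.stratify_means_by_ses and not spec.equate_sex_effect),
        ]
        if spec.include_pgs:
            kinds.append(("bpgs", not spec.equate_pgs_slopes))
        var_strat = spec.stratify_variances_by_ses
        kinds.append(("a", var_strat))
        if spec.include_c:
            kinds.append(("c", var_strat))
        kinds.append(("e", var_strat))

        self.free_names: list[str] = []
        self._slots: dict = {}
        bounds: list[tuple] = []
        for kind, strat in kinds:
            public = self._VAR_KINDS.get(kind, kind)
            idx = np.full(G, -1, dtype=int)
            fixed_vals = np.zeros(G)
            cells = self.groups if strat else (None,)
            for cell in cells:
                name = public if cell is None else f"{public}[{cell}]"
                where = (
                    slice(None) if cell is None else self.groups.index(cell)
                )
                if name in self.fixed:
                    val = float(self.fixed[name])
                    if kind in self._VAR_KINDS.values() or kind in ("a", "c", "e"):
                        if val < 0:
                            raise DataValidationError(
                                f"fixed variance {name} must be >= 0"
                            )
                        val = np.sqrt(val)
                    fixed_vals[where] = val
                else:
                    pos = len(self.free_names)
                    self.free_names.append(name)
                    idx[where] = pos
                    if kind == "e":
                        bounds.append((_E_SD_MIN, _SD_MAX))
                    elif kind in ("a", "c"):
                        bounds.append((0.0, _SD_MAX))
                    else:
                        bounds.append((None, None))
            self._slots[kind] = (idx, fixed_vals)
        unknown = set(self.fixed) - {
            n
            for kind, strat in kinds
            for n in (
                [self._VAR_KINDS.get(kind, kind)]
                if not strat
                else [f"{self._VAR_KINDS.get(kind, kind)}[{c}]" for c in self.groups]
            )
        }
        if unknown:
            raise DataValidationError(f"fixed parameters not in model: {sorted(unknown)}")
        self.bounds = bounds
        if not spec.include_c:
            self._slots["c"] = (np.full(G, -1, dtype=int), np.zeros(G))

        if spec.stratify_means_by_ses or spec.stratify_variances_by_ses:
            present = np.bincount(self.g, minlength=G)
            if np.any(present == 0):
                raise DataValidationError("empty SES cell under stratification")

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def _expand(self, theta: np.ndarray, kind: str) -> np.ndarray:
        idx, fixed_vals = self._slots[kind]
        vals = fixed_vals.copy()
        m = idx >= 0
        if m.any():
            vals[m] = theta[idx[m]]
        return vals

    # -- objective --------------------------------------------------------
    def minus2ll(self, theta: np.ndarray) -> float:
        a = self._expand(theta, "a")
        c = self._expand(theta, "c")
        e = self._expand(theta, "e")
        a2, c2, e2 = a * a, c * c, e * e
        total = a2 + c2 + e2
        cov_mz = a2 + c2
        cov_dz = 0.5 * a2 + c2
        g = self.g
        v = total[g]
        cov = np.where(self.is_mz, cov_mz[g], cov_dz[g])
        mu_g = self._expand(theta, "mu")[g]
        bsex = self._expand(theta, "bsex")[g]
        mu1 = mu_g + bsex * self.s1
        mu2 = mu_g + bsex * self.s2
        if self.spec.include_pgs:
            bpgs = self._expand(theta, "bpgs")[g]
            mu1 = mu1 + bpgs * self.p1
            mu2 = mu2 + bpgs * self.p2
        try:
            return -2.0 * loglik_terms(self.pa, mu1, mu2, v, v, cov)
        except LikelihoodError:
            return 1e100

    # -- starting values --------------------------------------------------
    def start(self) -> np.ndarray:
        """Moment-based starting vector (censoring ignored, fine as a start)."""
        df = self.df
        y = np.concatenate([df["ea1"].to_numpy(float), df["ea2"].to_numpy(float)])
        male = np.concatenate([self.s1, self.s2])
        gg = np.concatenate([self.g, self.g])
        ok = ~np.isnan(y)
        grand_mean = float(np.nanmean(y))
        grand_var = float(np.nanvar(y))
        d_sex = 0.0
        if male[ok].std() > 0:
            d_sex = float(np.nanmean(y[ok & (male == 1)]) - np.nanmean(y[ok & (male == 0)]))

        complete = df["ea1"].notna().to_numpy() & df["ea2"].notna().to_numpy()
        y1 = df["ea1"].to_numpy(float)
        y2 = df["ea2"].to_numpy(float)

        def _cov(mask):
            if mask.sum() < 3:
                return 0.5 * grand_var
            return float(np.cov(y1[mask], y2[mask])[0, 1])

        c_mz = _cov(complete & self.is_mz)
        c_dz = _cov(complete & ~self.is_mz)
        a2 = np.clip(2.0 * (c_mz - c_dz), 0.05 * grand_var, 0.95 * grand_var)
        c2 = np.clip(2.0 * c_dz - c_mz, 0.0, 0.5 * grand_var)
        e2 = np.clip(grand_var - a2 - c2, 0.05 * grand_var, None)

        slope = 0.0
        if self.spec.include_pgs:
            p = np.concatenate([self.p1, self.p2])
            if np.nanvar(p[ok]) > 0:
                slope = float(
                    np.cov(p[ok], y[ok])[0, 1] / np.var(p[ok])
                )

        theta = np.zeros(self.n_free)
        for pos, name in enumerate(self.free_names):
            base = name.split("[")[0]
            gi = None
            if "[" in name:
                gi = self.groups.index(name[name.index("[") + 1 : -1])
            if base == "mu":
                sel = ok if gi is None else ok & (gg == gi)
                theta[pos] = float(np.mean(y[sel])) if sel.any() else grand_mean
            elif base == "bsex":
                theta[pos] = d_sex
            elif base == "bpgs":
                theta[pos] = slope
            elif base == "a2":
                theta[pos] = np.sqrt(a2)
            elif base == "c2":
                theta[pos] = np.sqrt(c2)
            elif base == "e2":
                theta[pos] = max(np.sqrt(e2), 2.0 * _E_SD_MIN)
        return theta

    def jitter_scales(self) -> np.ndarray:
        scales = np.empty(self.n_free)
        for pos, name in enumerate(self.free_names):
            base = name.split("[")[0]
            scales[pos] = {"mu": 0.8, "bsex": 0.5, "bpgs": 0.5}.get(base, 1.0)
        return scales

    def estimates_dict(self, theta: np.ndarray) -> dict:
        out = {}
        for pos, name in enumerate(self.free_names):
            base = name.split("[")[0]
            val = float(theta[pos])
            if base in ("a2", "c2", "e2"):
                val = val * val
            out[name] = val
        for name, val in self.fixed.items():
            out[name] = float(val)
        return out

    def theta_from_estimates(self, estimates: dict) -> np.ndarray:
        """Internal vector matching ``estimates`` (warm starts)."""
        theta = self.start()
        for pos, name in enumerate(self.free_names):
            if name in estimates:
                val = float(estimates[name])
                if name.split("[")[0] in ("a2", "c2", "e2"):
                    val = np.sqrt(max(val, 0.0))
                theta[pos] = val
        return np.clip(
            theta,
            [lo if lo is not None else -np.inf for lo, _ in self.bounds],
            [hi if hi is not None else np.inf for _, hi in self.bounds],
        )


def minimize_with_retry(fun, x0, bounds, maxiter=1000, polish_attempts=2):
    """L-BFGS-B with re-polish on abnormal line-search termination.

    A restart from the terminal point (occasionally with a loosened
    ftol) almost always converts a spurious ABNORMAL_TERMINATION into a
    clean success at the same optimum.
    """
    res = optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    for attempt in range(polish_attempts):
        if res.success:
            break
        retry = optimize.minimize(
            fun, res.x, method="L-BFGS-B", bounds=bounds,
            options={
                "maxiter": maxiter,
                "ftol": 1e-11 if attempt == 0 else 1e-9,
                "gtol": 1e-7 if attempt == 0 else 1e-6,
            },
        )
        if retry.fun <= res.fun or retry.success:
            res = retry
    if not res.success:
        # line-search failures can occur at the optimum itself (finite-
        # difference gradient noise); a derivative-free polish decides
        nm = optimize.minimize(
            fun, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-9, "xatol": 1e-7},
        )
        lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
        hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
        if nm.success and nm.fun <= res.fun + 1e-6 and np.all(
            (nm.x >= lo - 1e-9) & (nm.x <= hi + 1e-9)
        ):
            nm.x = np.clip(nm.x, lo, hi)
            res = nm
    return res


def _minimize(prob: FIMLProblem, x0: np.ndarray) -> optimize.OptimizeResult:
    return minimize_with_retry(prob.minus2ll, x0, prob.bounds)


def fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    n_starts: int = 5,
    seed: int = 0,
    fixed: Optional[dict] = None,
    x0: Optional[dict] = None,
) -> FitResult:
    """Fit a twin model by censored full-information maximum likelihood.

    A moment-based start plus ``n_starts - 1`` jittered restarts guard
    against local optima; the fit is flagged converged when the
    optimizer reports success and the two best restarts agree in -2LL.
    ``fixed`` pins public parameters (e.g. ``{"c2": 0.0}``); ``x0``
    warm-starts from an estimates dict.
    """
    prob = FIMLProblem(data, spec, fixed=fixed)
    rng = np.random.default_rng(seed)
    start0 = prob.start() if x0 is None else prob.theta_from_estimates(x0)
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in prob.bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in prob.bounds])
    starts = [start0]
    scales = prob.jitter_scales()
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.clip(start0 + scales * rng.standard_normal(prob.n_free), lo, hi)
        )
    results = []
    for j, x in enumerate(starts):
        res = _minimize(prob, x)
        logger.info(
            "fit start %d/%d: -2LL=%.6f success=%s", j + 1, len(starts),
            res.fun, res.success,
        )
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    agree = (
        len(results) < 2 or results[1].fun - best.fun < _START_AGREEMENT
    )
    if not agree:
        # a jittered restart may have stalled in a local optimum; confirm
        # the best solution by re-solving from a small perturbation of it
        confirm = _minimize(
            prob, np.clip(best.x + 0.01 * scales * rng.standard_normal(prob.n_free), lo, hi)
        )
        if confirm.fun < best.fun:
            best = confirm
        agree = abs(confirm.fun - best.fun) < _START_AGREEMENT
    converged = bool(best.success) and agree
    if not converged:
        logger.warning(
            "fit flagged non-converged: success=%s start-agreement=%s",
            best.success, agree,
        )
    return FitResult(
        spec=spec,
        estimates=prob.estimates_dict(best.x),
        minus2ll=float(best.fun),
        n_free_params=prob.n_free,
        converged=converged,
        n_pairs=prob.pa.n,
        groups=prob.groups,
        fixed=dict(fixed or {}),
        meta={
            "start_minus2ll": [float(r.fun) for r in results],
            "n_dropped_for_pgs": prob.n_dropped_for_pgs,
        },
    )


def lrt(parent: FitResult, nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of ``nested`` against ``parent``.

    ``delta_minus2ll`` is clipped at 0 (optimizer noise can make a
    nested optimum marginally better).  Structural nesting is checked
    when both results carry a :class:`ModelSpec`; fits of other model
    families are compared on free-parameter counts alone.
    """
    delta_df = parent.n_free_params - nested.n_free_params
    if delta_df <= 0:
        raise NotNestedError(
            f"nested model must have fewer free parameters "
            f"({nested.n_free_params} vs {parent.n_free_params})"
        )
    p_spec = getattr(parent, "spec", None)
    n_spec = getattr(nested, "spec", None)
    if isinstance(p_spec, ModelSpec) and isinstance(n_spec, ModelSpec):
        if not n_spec.is_restriction_of(p_spec):
            raise NotNestedError("nested spec is not a restriction of parent spec")
        if not set(getattr(parent, "fixed", {})) <= set(getattr(nested, "fixed", {})):
            raise NotNestedError("parent fixes parameters the nested model frees")
    delta = max(0.0, nested.minus2ll - parent.minus2ll)
    if nested.minus2ll - parent.minus2ll < -1.0:
        logger.warning(
            "nested model beat parent by %.3f -2LL units; check convergence",
            parent.minus2ll - nested.minus2ll,
        )
    return LRTResult(
        delta_minus2ll=delta,
        delta_df=delta_df,
        p_value=float(chi2.sf(delta, delta_df)) if delta > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# saturated (correlation) model


class _SaturatedProblem:
    """Exchangeable bivariate-normal model: mean, sex effect, SD, rho."""

    def __init__(self, data, censoring, threshold, include_sex):
        self.include_sex = include_sex
        self.pa = PairArrays.from_frame(data, censoring=censoring, threshold=threshold)
        self.s1 = (data["sex1"].to_numpy() == "M").astype(float)
        self.s2 = (data["sex2"].to_numpy() == "M").astype(float)
        self.df = data
        self.n_free = 4 if include_sex else 3

    def minus2ll(self, theta):
        if self.include_sex:
            mu, bsex, sd, rho = theta
        else:
            (mu, sd, rho), bsex = theta, 0.0
        v = sd * sd
        mu1 = mu + bsex * self.s1
        mu2 = mu + bsex * self.s2
        try:
            return -2.0 * loglik_terms(
                self.pa, mu1, mu2, np.full(self.pa.n, v), np.full(self.pa.n, v),
                np.full(self.pa.n, rho * v),
            )
        except LikelihoodError:
            return 1e100

    def bounds(self):
        b = [(None, None), (0.5, _SD_MAX), (-0.999, 0.999)]
        if self.include_sex:
            b.insert(1, (None, None))
        return b

    def start(self):
        y = np.concatenate(
            [self.df["ea1"].to_numpy(float), self.df["ea2"].to_numpy(float)]
        )
        mu = float(np.nanmean(y))
        sd = float(np.nanstd(y))
        comp = self.df["ea1"].notna().to_numpy() & self.df["ea2"].notna().to_numpy()
        rho = 0.3
        if comp.sum() >= 3:
            rho = float(
                np.clip(
                    np.corrcoef(
                        self.df["ea1"].to_numpy(float)[comp],
                        self.df["ea2"].to_numpy(float)[comp],
                    )[0, 1],
                    -0.95,
                    0.95,
                )
            )
        x = [mu, max(sd, 1.0), rho]
        if self.include_sex:
            x.insert(1, 0.0)
        return np.array(x)


def saturated_twin_correlation(
    data: pd.DataFrame,
    zygosity: str,
    censoring: bool = True,
    threshold: float = 550.0,
    ses: Optional[int] = None,
    include_sex: bool = True,
    level: Optional[float] = None,
) -> CorrelationResult:
    """Censoring-corrected ML within-pair correlation for one zygosity.

    Fits the saturated exchangeable pair model (free mean, optional sex
    effect, free variance, free correlation) to the selected pairs.  On
    uncensored data the estimate coincides with the ML product-moment
    correlation under exchangeability.  With ``level`` a profile-
    likelihood CI for rho is returned.
    """
    sub = data[data["zygosity"] == zygosity]
    if ses is not None:
        sub = sub[sub["ses"] == ses]
    sub = sub.reset_index(drop=True)
    complete = sub["ea1"].notna() & sub["ea2"].notna()
    if int(complete.sum()) < 2:
        raise DataValidationError("need at least 2 complete pairs")
    prob = _SaturatedProblem(sub, censoring, threshold, include_sex)
    if censoring and prob.pa.n_censored >= 2 * prob.pa.n:
        raise FitError("all scores censored; correlation not estimable")
    res = minimize_with_retry(prob.minus2ll, prob.start(), prob.bounds(),
                              maxiter=500)
    rho_idx = prob.n_free - 1
    rho_hat = float(res.x[rho_idx])
    ci = None
    if level is not None:
        target = float(res.fun) + chi2.ppf(level, 1)

        def prof(r):
            xs = res.x.copy()
            xs[rho_idx] = r
            b = prob.bounds()
            b[rho_idx] = (r, r)
            rr = optimize.minimize(
                prob.minus2ll, xs, method="L-BFGS-B", bounds=b,
                options={"maxiter": 300, "ftol": 1e-11},
            )
            return rr.fun

        ci = (
            _scalar_profile_bound(prof, rho_hat, target, -1, 0.05, -0.999),
            _scalar_profile_bound(prof, rho_hat, target, +1, 0.05, 0.999),
        )
    return CorrelationResult(
        rho=rho_hat,
        ci=ci,
        n_pairs=int(len(sub)),
        minus2ll=float(res.fun),
        converged=bool(res.success),
    )


def _scalar_profile_bound(prof, est, target, direction, step, limit):
    """Bracket-and-bisect one profile-likelihood bound.

    Returns ``limit`` when the profile never crosses ``target`` before
    the feasible boundary, and ``nan`` when bracketing fails.
    """
    from scipy.optimize import brentq

    x_in = est
    x_out = est
    for _ in range(60):
        nxt = x_out + direction * step
        if (direction > 0 and nxt >= limit) or (direction < 0 and nxt <= limit):
            if prof(limit) <= target:
                return float(limit)
            x_out_candidate = limit
            try:
                return float(
                    brentq(lambda v: prof(v) - target, *sorted((x_in, x_out_candidate)), xtol=1e-5)
                )
            except ValueError:
                return float("nan")
        x_out = nxt
        if prof(x_out) > target:
            try:
                return float(
                    brentq(lambda v: prof(v) - target, *sorted((x_in, x_out)), xtol=1e-5)
                )
            except ValueError:
                return float("nan")
        x_in = x_out
        step *= 2.0
    return float("nan")


def profile_ci(
    data: pd.DataFrame,
    spec: ModelSpec,
    fit_result: FitResult,
    param: str,
    level: float = 0.95,
) -> tuple:
    """Profile-likelihood confidence interval for one public parameter.

    The bounds are the parameter values at which the profiled -2LL rises
    above the minimum by the chi-squared(1) quantile of ``level``.  For
    variance components the profile respects the 0 boundary: when even
    the zero-variance model stays within the quantile the lower bound is
    reported as exactly 0.0.  A bound that cannot be bracketed is
    returned as ``nan`` (with a log diagnostic).
    """
    if not 0.0 < level < 1.0:
        raise DataValidationError("level must be in (0, 1)")
    if param not in fit_result.estimates:
        raise DataValidationError(f"unknown parameter {param!r}")
    if not fit_result.converged:
        raise FitError("profile CI requires a converged fit")
    est = float(fit_result.estimates[param])
    target = fit_result.minus2ll + float(chi2.ppf(level, 1))
    is_variance = param.split("[")[0] in ("a2", "c2", "e2")

    def prof(value: float) -> float:
        fixed = dict(fit_result.fixed)
        fixed[param] = value
        r = fit(
            data, spec, n_starts=1, fixed=fixed, x0=fit_result.estimates
        )
        return r.minus2ll

    scale = max(0.25 * abs(est), 1.0 if is_variance else 0.2)
    if is_variance:
        if est <= 1e-8 or prof(0.0) <= target:
            lower = 0.0
        else:
            lower = _scalar_profile_bound(prof, est, target, -1, scale, 0.0)
    else:
        lower = _scalar_profile_bound(prof, est, target, -1, scale, est - 1e4)
    upper = _scalar_profile_bound(prof, est, target, +1, scale, est + 1e4)
    if np.isnan(lower) or np.isnan(upper):
        logger.warning("profile CI for %s failed to bracket a bound", param)
    return (lower, upper)
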