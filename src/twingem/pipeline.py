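"""The full analysis ladder on a conforming twin dataset.

Stages, in order (PGS stages are skipped with a notice when the data
carry no PGS):

1.  total-sample ACE model (shared means, sex covariate, censoring);
2.  significance of C (drop the common-environment component, 1 df);
3.  SES-stratified means (per-group intercepts and sex effects) with a
    C-after-SES test and per-group sex-effect tests;
4.  SES-stratified variance components, tested against stage 3 with a
    9-df moderation LRT (3 components x 4 groups collapsing to 3);
5.  PGS means/variances by SES with equality LRTs;
6.  EA-on-PGS inside the twin model: slope- and intercept-equality;
7.  DZ within-pair PGS correlation;
8.  the DZ within-family higher-vs-lower-PGS contrast.

Every number in the report is taken from a persisted fit; the report is
a plain JSON-serializable dict.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ModelSpec, group_label
from .model import fit, lrt, profile_ci, saturated_twin_correlation, standardize
from .pgs import dz_pgs_correlation, ea_on_pgs_fit, pgs_by_ses_tests, within_family_test

logger = logging.getLogger(__name__)


def _fit_row(name: str, f, parent: Optional[str] = None, test=None) -> dict:
    row = {
        "name": name,
        "minus2ll": f.minus2ll,
        "n_free_params": f.n_free_params,
        "converged": f.converged,
        "parent": parent,
    }
    if test is not None:
        row["lrt"] = asdict(test)
    return row


def descriptives(data: pd.DataFrame) -> dict:
    """Observed (not censoring-corrected) summaries per SES group."""
    out = {}
    for ses in sorted(data["ses"].unique()):
        sub = data[data["ses"] == ses]
        y = np.concatenate([sub["ea1"].to_numpy(float), sub["ea2"].to_numpy(float)])
        male = np.concatenate(
            [(sub["sex1"] == "M").to_numpy(), (sub["sex2"] == "M").to_numpy()]
        )
        cens = np.concatenate(
            [sub["cens1"].to_numpy(bool), sub["cens2"].to_numpy(bool)]
        )
        ok = ~np.isnan(y)
        entry = {
            "n_pairs_mz": int((sub["zygosity"] == "MZ").sum()),
            "n_pairs_dz": int((sub["zygosity"] == "DZ").sum()),
            "mean_ea_girls_observed": float(np.mean(y[ok & ~male])),
            "mean_ea_boys_observed": float(np.mean(y[ok & male])),
            "sd_ea_observed": float(np.std(y[ok])),
            "censored_fraction": float(np.mean(cens[ok])),
        }
        pgs = np.concatenate(
            [sub["pgs1"].to_numpy(float), sub["pgs2"].to_numpy(float)]
        )
        if np.any(~np.isnan(pgs)):
            entry["pgs_mean"] = float(np.nanmean(pgs))
            entry["pgs_var"] = float(np.nanvar(pgs))
        out[group_label(int(ses))] = entry
    return out


def run_analysis_ladder(
    data: pd.DataFrame,
    alpha: float = 0.01,
    threshold: float = 550.0,
    censoring: bool = True,
    seed: int = 0,
    n_starts: int = 2,
    compute_ci: bool = False,
    ci_level: float = 0.95,
) -> dict:
    """Run the complete model ladder and return the analysis report.

    ``alpha`` is only a reporting convenience (each LRT's decision at
    that level is included alongside the exact p-value).  Profile CIs
    for the stratified variance model are computed when ``compute_ci``
    (they dominate the runtime).
    """
    groups = [group_label(int(s)) for s in sorted(data["ses"].unique())]
    report: dict = {
        "options": {
            "alpha": alpha,
            "threshold": threshold,
            "censoring": censoring,
            "seed": seed,
        },
        "n_pairs": int(len(data)),
        "groups": groups,
        "descriptives": descriptives(data),
    }
    kw = dict(n_starts=n_starts, seed=seed)

    # twin correlations, censoring-corrected, overall and per group
    corrs: dict = {}
    for zyg in ("MZ", "DZ"):
        c = saturated_twin_correlation(
            data, zyg, censoring=censoring, threshold=threshold
        )
        corrs[zyg] = {"overall": c.rho, "by_group": {}}
        for ses in sorted(data["ses"].unique()):
            cg = saturated_twin_correlation(
                data, zyg, censoring=censoring, threshold=threshold, ses=int(ses)
            )
            corrs[zyg]["by_group"][group_label(int(ses))] = cg.rho
    report["twin_correlations"] = corrs

    # stage 1-2: total-sample ACE and the C test
    base = ModelSpec(censoring=censoring, threshold=threshold)
    m1 = fit(data, base, **kw)
    m2 = fit(data, base, fixed={"c2": 0.0}, **kw)
    t_c_total = lrt(m1, m2)
    ladder = [
        _fit_row("ace_total", m1),
        _fit_row("ace_total_no_c", m2, "ace_total", t_c_total),
    ]
    ace_total = m1.ace()
    report["total_sample"] = {
        "ace": asdict(ace_total),
        "standardized": standardize(ace_total),
        "c_significant": bool(t_c_total.p_value < alpha),
    }

    # stage 3: SES-stratified means, C after SES, per-group sex tests
    spec3 = ModelSpec(
        stratify_means_by_ses=True,
        equate_sex_effect=False,
        censoring=censoring,
        threshold=threshold,
    )
    m3 = fit(data, spec3, **kw)
    m3_no_c = fit(data, spec3, fixed={"c2": 0.0}, x0=m3.estimates, **kw)
    t_c_after = lrt(m3, m3_no_c)
    ladder.append(_fit_row("ses_means", m3, "ace_total"))
    ladder.append(_fit_row("ses_means_no_c", m3_no_c, "ses_means", t_c_after))
    sex_tests = {}
    for lab in groups:
        m_sex = fit(
            data, spec3, fixed={f"bsex[{lab}]": 0.0}, x0=m3.estimates, **kw
        )
        t = lrt(m3, m_sex)
        sex_tests[lab] = asdict(t) | {
            "estimate": m3.estimates[f"bsex[{lab}]"],
            "significant": bool(t.p_value < alpha),
        }
    report["sex_effect_tests"] = sex_tests
    report["c_after_ses"] = asdict(t_c_after) | {
        "significant": bool(t_c_after.p_value < alpha)
    }

    # stage 4: SES-stratified variance components (moderation test)
    spec4 = ModelSpec(
        stratify_means_by_ses=True,
        stratify_variances_by_ses=True,
        equate_sex_effect=False,
        censoring=censoring,
        threshold=threshold,
    )
    m4 = fit(data, spec4, x0=m3.estimates, **kw)
    t_mod = lrt(m4, m3)
    expected_df = 3 * (len(groups) - 1)
    assert t_mod.delta_df == expected_df, "moderation df bookkeeping broken"
    ladder.append(_fit_row("ses_means_variances", m4))
    ladder[-1]["lrt_vs_ses_means"] = asdict(t_mod)
    report["variance_moderation"] = asdict(t_mod) | {
        "significant": bool(t_mod.p_value < alpha)
    }

    stratified = {}
    for lab in groups:
        ace = m4.ace(lab)
        entry = {
            "mean_girls": m4.mean(lab, "F"),
            "mean_boys": m4.mean(lab, "M"),
            "a2": ace.a2,
            "c2": ace.c2,
            "e2": ace.e2,
            "phenotypic": ace.total,
            "standardized": standardize(ace),
        }
        if compute_ci:
            for pname in (f"mu[{lab}]", f"a2[{lab}]", f"c2[{lab}]", f"e2[{lab}]"):
                entry.setdefault("ci", {})[pname] = list(
                    profile_ci(data, spec4, m4, pname, level=ci_level)
                )
        stratified[lab] = entry
    report["stratified_estimates"] = stratified
    report["ladder"] = ladder

    # stages 5-8: PGS analyses
    has_pgs = bool(
        data["pgs1"].notna().any() or data["pgs2"].notna().any()
    )
    if not has_pgs:
        logger.info("no PGS data: skipping PGS stages")
        report["pgs"] = {"skipped": "no PGS data in dataset"}
        return report

    pgs_section: dict = {}
    by_ses = pgs_by_ses_tests(data)
    pgs_section["by_ses"] = {
        "estimates": by_ses.fit_stratified.estimates,
        "mean_equality": asdict(by_ses.lrt_means)
        | {"significant": bool(by_ses.lrt_means.p_value < alpha)},
        "variance_equality": asdict(by_ses.lrt_variances)
        | {"significant": bool(by_ses.lrt_variances.p_value < alpha)},
    }

    parent_spec = ModelSpec(
        stratify_means_by_ses=True,
        stratify_variances_by_ses=True,
        include_pgs=True,
        equate_pgs_slopes=False,
        equate_sex_effect=True,
        censoring=censoring,
        threshold=threshold,
    )
    mp = ea_on_pgs_fit(data, parent_spec, **kw)
    m_slopes = fit(
        data,
        ModelSpec(**{**parent_spec.to_dict(), "equate_pgs_slopes": True}),
        x0=mp.estimates,
        **kw,
    )
    m_icept = fit(
        data,
        ModelSpec(**{**parent_spec.to_dict(), "stratify_means_by_ses": False}),
        x0=mp.estimates,
        **kw,
    )
    t_slope = lrt(mp, m_slopes)
    t_icept = lrt(mp, m_icept)
    pgs_section["ea_on_pgs"] = {
        "slopes": {lab: mp.estimates[f"bpgs[{lab}]"] for lab in groups},
        "intercepts": {lab: mp.estimates[f"mu[{lab}]"] for lab in groups},
        "slope_equality": asdict(t_slope)
        | {"significant": bool(t_slope.p_value < alpha)},
        "intercept_equality": asdict(t_icept)
        | {"significant": bool(t_icept.p_value < alpha)},
    }

    dzc = dz_pgs_correlation(data)
    pgs_section["dz_pgs_correlation"] = {
        "rho": dzc.rho,
        "ci": list(dzc.ci) if dzc.ci else None,
        "n_pairs": dzc.n_pairs,
    }
    wf = within_family_test(
        data, censoring=censoring, threshold=threshold
    )
    pgs_section["within_family"] = {
        "mean_pgs_gap": wf.mean_pgs_gap,
        "mean_ea_gap": wf.mean_ea_gap,
        "lrt": asdict(wf.lrt) | {"significant": bool(wf.lrt.p_value < alpha)},
        "n_pairs": wf.n_pairs,
        "regression_slope": wf.regression_slope,
    }
    report["pgs"] = pgs_section
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization of a report."""
    return json.dumps(report, indent=2, sort_keys=True)


def summarize(report: dict) -> str:
    """Human-readable synopsis of the qualitative ladder outcome."""
    lines = [f"Twin cohort: {report['n_pairs']} pairs, groups {report['groups']}"]
    tc = report["twin_correlations"]
    lines.append(
        f"Twin correlations (censoring-corrected): "
        f"rMZ={tc['MZ']['overall']:.2f}, rDZ={tc['DZ']['overall']:.2f}"
    )
    ts = report["total_sample"]["standardized"]
    lines.append(
        f"Total-sample standardized variance: h2={ts['h2']:.2f}, "
        f"c2={ts['c2']:.2f}, e2={ts['e2']:.2f}"
    )
    lines.append(
        "C after SES stratification: "
        + ("significant" if report["c_after_ses"]["significant"] else "not significant")
        + f" (p={report['c_after_ses']['p_value']:.3f})"
    )
    vm = report["variance_moderation"]
    lines.append(
        f"SES moderation of A/C/E: delta -2LL={vm['delta_minus2ll']:.1f}, "
        f"df={vm['delta_df']}, p={vm['p_value']:.2e}"
    )
    for lab, row in report["stratified_estimates"].items():
        lines.append(
            f"  {lab:8s} mean(girls)={row['mean_girls']:.1f} "
            f"A={row['a2']:.1f} C={row['c2']:.1f} E={row['e2']:.1f}"
        )
    pgs = report.get("pgs", {})
    if "skipped" in pgs:
        lines.append(f"PGS stages skipped: {pgs['skipped']}")
    else:
        lines.append(
            "PGS mean equality across SES: "
            f"p={pgs['by_ses']['mean_equality']['p_value']:.2e}; "
            "slope equality: "
            f"p={pgs['ea_on_pgs']['slope_equality']['p_value']:.3f}; "
            "intercept equality: "
            f"p={pgs['ea_on_pgs']['intercept_equality']['p_value']:.2e}"
        )
        wf = pgs["within_family"]
        lines.append(
            f"Within-family: higher-PGS DZ twin leads by {wf['mean_pgs_gap']:.2f} "
            f"SD in PGS and {wf['mean_ea_gap']:.2f} points in EA "
            f"(p={wf['lrt']['p_value']:.2e}, n={wf['n_pairs']})"
        )
    return "\n".join(lines)
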