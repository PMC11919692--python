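"""Downstream analyses: power curves, geneset enrichment, exome-overlap
Poisson tests, polygenic-score comparisons and clinical contingency tests.

The power model is carrier-based: one observation per person, a
multiplicative risk model relating the case carrier frequency to the
population (control) frequency, f_case = f*RR / (1 + f*(RR-1)), and a
two-sided two-proportion z-test at the Bonferroni-corrected per-test
alpha. RR*(f), the smallest relative risk detectable at the target
power, is solved by root finding on the analytic power function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from .burden import design_matrix
from .locus_assoc import bh_fdr
from .config import PowerConfig

__all__ = [
    "PowerConfig",
    "EnrichmentResult",
    "ClinicalComparison",
    "analytic_power",
    "power_curve",
    "monte_carlo_power",
    "geneset_enrichment",
    "brainset_concentration",
    "poisson_overlap_test",
    "prs_carrier_test",
    "clinical_comparisons",
    "percent_improvement",
]


@dataclass
class EnrichmentResult:
    geneset: str
    estimate: float
    se: float
    p: float
    fdr_q: float
    covariate_mode: str
    flagged: bool = False
    note: str = ""


@dataclass
class ClinicalComparison:
    name: str
    carrier_class: str
    test: str  # "chi2" | "fisher" | "ttest"
    statistic: float
    df: float
    p: float
    table: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    group_means: Optional[Tuple[float, float]] = None  # carrier, non-carrier
    n_carrier: int = 0
    n_noncarrier: int = 0


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def _case_freq(f: float, rr: float) -> float:
    return f * rr / (1.0 + f * (rr - 1.0))


def analytic_power(f: float, rr: float, n_cases: int, n_controls: int, alpha: float) -> float:
    """Two-sided two-proportion z-test power under the carrier risk model."""
    p1 = _case_freq(f, rr)
    p2 = f
    pbar = (n_cases * p1 + n_controls * p2) / (n_cases + n_controls)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n_cases + 1 / n_controls))
    se1 = np.sqrt(p1 * (1 - p1) / n_cases + p2 * (1 - p2) / n_controls)
    if se1 == 0:
        return 0.0
    z = stats.norm.isf(alpha / 2.0)
    d = p1 - p2
    return float(stats.norm.cdf((d - z * se0) / se1) + stats.norm.cdf((-d - z * se0) / se1))


def power_curve(config: PowerConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Power over the (frequency, RR) grid and RR*(f) at the target power.

    Returns ``(grid, rr_star)``: the grid frame has one row per (f, RR)
    with the analytic power; ``rr_star`` has one row per frequency with
    the smallest RR achieving the target power (NaN and
    ``attainable=False`` when no RR below ``rr_max`` suffices).
    """
    config.validate()
    alpha = config.alpha_family / config.n_tests
    rows = [
        (f, rr, analytic_power(f, rr, config.n_cases, config.n_controls, alpha))
        for f in config.freq_grid
        for rr in config.rr_grid
    ]
    grid = pd.DataFrame(rows, columns=["frequency", "rr", "power"])
    star_rows = []
    for f in config.freq_grid:
        g = lambda rr: analytic_power(f, rr, config.n_cases, config.n_controls, alpha) - config.target_power
        if g(config.rr_max) < 0:
            star_rows.append((f, np.nan, False))
            continue
        rr_star = brentq(g, 1.0 + 1e-9, config.rr_max, xtol=1e-9)
        # refine to |power - target| < 1e-6
        assert abs(g(rr_star)) < 1e-6
        star_rows.append((f, float(rr_star), True))
    rr_star = pd.DataFrame(star_rows, columns=["frequency", "rr_star", "attainable"])
    return grid, rr_star


def monte_carlo_power(
    f: float, rr: float, n_cases: int, n_controls: int, alpha: float,
    n_rep: int = 100_000, seed: int = 0,
) -> float:
    """Simulation estimate of the same two-proportion z-test's power."""
    rng = np.random.default_rng(seed)
    p1 = _case_freq(f, rr)
    x1 = rng.binomial(n_cases, p1, n_rep)
    x2 = rng.binomial(n_controls, f, n_rep)
    ph1 = x1 / n_cases
    ph2 = x2 / n_controls
    pbar = (x1 + x2) / (n_cases + n_controls)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n_cases + 1 / n_controls))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se0 > 0, (ph1 - ph2) / se0, 0.0)
    zcrit = stats.norm.isf(alpha / 2.0)
    return float(np.mean(np.abs(z) > zcrit))


# ---------------------------------------------------------------------------
# geneset enrichment
# ---------------------------------------------------------------------------

def geneset_enrichment(
    geneset_counts: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: Sequence[str],
    total_counts: pd.Series,
    covariate_mode: str = "total",
    fdr_alpha: float = 0.1,
) -> List[EnrichmentResult]:
    """Logistic enrichment of per-sample geneset impact counts.

    ``geneset_counts``: frame indexed by sample_id, one column per
    geneset (impacted genes in the set per person). ``total_counts``:
    the per-person control covariate (total impacted genes, or total
    impacted intolerant genes when ``covariate_mode='intolerant_subset'``).
    BH-FDR at ``fdr_alpha`` across the tested family. Genesets with no
    impacted genes cohort-wide are skipped; a geneset count collinear
    with the control covariate is returned flagged.
    """
    base = design_matrix(samples, covariates).reset_index(drop=True)
    y = samples["is_case"].to_numpy(float)
    tot = total_counts.reindex(samples["sample_id"]).fillna(0).to_numpy(float)
    results: List[EnrichmentResult] = []
    for gs in geneset_counts.columns:
        cnt = geneset_counts[gs].reindex(samples["sample_id"]).fillna(0).to_numpy(float)
        if cnt.sum() == 0:
            results.append(EnrichmentResult(gs, np.nan, np.nan, np.nan, np.nan,
                                            covariate_mode, True, "no impacted genes cohort-wide"))
            continue
        if np.ptp(tot) > 0 and abs(np.corrcoef(cnt, tot)[0, 1]) > 0.999:
            results.append(EnrichmentResult(gs, 0.0, np.nan, np.nan, np.nan,
                                            covariate_mode, True, "collinear with control covariate"))
            continue
        X = base.copy()
        X["_total"] = tot
        X["_geneset"] = cnt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=100)
                est = float(res.params["_geneset"])
                se = float(res.bse["_geneset"])
                p = float(res.pvalues["_geneset"])
                flagged = not np.isfinite(se) or se > 50
            except Exception as exc:
                results.append(EnrichmentResult(gs, np.nan, np.nan, np.nan, np.nan,
                                                covariate_mode, True, f"fit failed: {exc}"))
                continue
        results.append(EnrichmentResult(gs, est, se, p, np.nan, covariate_mode, flagged))
    tested = [r for r in results if np.isfinite(r.p)]
    if tested:
        qs = bh_fdr([r.p for r in tested])
        for r, q in zip(tested, qs):
            r.fdr_q = float(q)
    return results


def brainset_concentration(significant: Sequence[bool], is_brain: Sequence[bool]) -> float:
    """Two-sided Fisher exact P for significant results piling into brain sets."""
    sig = np.asarray(list(significant), dtype=bool)
    brain = np.asarray(list(is_brain), dtype=bool)
    if sig.size == 0:
        raise ValueError("no enrichment results supplied")
    table = [
        [int((sig & brain).sum()), int((sig & ~brain).sum())],
        [int((~sig & brain).sum()), int((~sig & ~brain).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# exome overlap and PRS
# ---------------------------------------------------------------------------

def poisson_overlap_test(observed: int, expected: float) -> float:
    """One-sided upper-tail Poisson P: Pr(X >= observed | X ~ Pois(expected))."""
    if observed < 0:
        raise ValueError("observed count must be nonnegative")
    if expected <= 0:
        raise ValueError("expected rate must be positive")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def prs_carrier_test(
    samples: pd.DataFrame,
    carrier_ids: Sequence[str],
    prs_column: str,
    covariates: Sequence[str],
    cases_only: bool = True,
):
    """Linear model of normalized PRS on deleterious-CNV carrier status.

    Returns a dict with the carrier-term estimate (in SD units of the
    normalized score), 95% CI, P, and carrier counts; ``flagged`` is
    set (no estimate) with fewer than 2 carriers or a constant
    indicator.
    """
    df = samples[samples["is_case"]] if cases_only else samples
    df = df.reset_index(drop=True)
    carrier = df["sample_id"].isin(set(carrier_ids)).to_numpy(float)
    out = {"prs": prs_column, "n_carriers": int(carrier.sum()), "n": len(df),
           "estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan, "flagged": False, "note": ""}
    if carrier.sum() < 2 or np.ptp(carrier) == 0:
        out["flagged"] = True
        out["note"] = "fewer than 2 carriers (or constant indicator)"
        return out
    prs = df[prs_column].to_numpy(float)
    prs = (prs - prs.mean()) / prs.std(ddof=1)  # normalize within analysis set
    X = design_matrix(df, covariates).reset_index(drop=True)
    X["_carrier"] = carrier
    res = sm.OLS(prs, sm.add_constant(X, has_constant="add")).fit()
    est, se = float(res.params["_carrier"]), float(res.bse["_carrier"])
    z = stats.norm.ppf(0.975)
    out.update(estimate=est, ci_lo=est - z * se, ci_hi=est + z * se, p=float(res.pvalues["_carrier"]))
    return out


# ---------------------------------------------------------------------------
# clinical comparisons
# ---------------------------------------------------------------------------

def percent_improvement(pre, post) -> np.ndarray:
    """Per-individual percent YBOCS improvement, 100*(pre-post)/pre."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(pre > 0, 100.0 * (pre - post) / pre, np.nan)


def contingency_comparison(
    name: str, carrier_class: str, carrier_with: int, n_with: int,
    carrier_without: int, n_without: int, force_chi2: bool = False,
    continuity: bool = False,
) -> ClinicalComparison:
    """Chi-square (df=1, no continuity correction by default) or Fisher.

    Fisher's exact test is substituted when any expected cell count is
    below 5, unless ``force_chi2``.
    """
    table = np.array([
        [carrier_with, n_with - carrier_with],
        [carrier_without, n_without - carrier_without],
    ])
    if (table < 0).any():
        raise ValueError("negative contingency cell")
    exp = stats.contingency.expected_freq(table)
    if (exp < 5).any() and not force_chi2:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return ClinicalComparison(name, carrier_class, "fisher", np.nan, np.nan, float(p),
                                  tuple(map(tuple, table)))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    return ClinicalComparison(name, carrier_class, "chi2", float(chi2), float(df), float(p),
                              tuple(map(tuple, table)))


def clinical_comparisons(
    samples: pd.DataFrame,
    carrier_classes: Dict[str, Sequence[str]],
    comorbidity_columns: Optional[Sequence[str]] = None,
    outcome_classes: Optional[Sequence[str]] = None,
) -> List[ClinicalComparison]:
    """Comorbidity contingency tests and YBOCS treatment-response t-tests.

    ``carrier_classes`` maps a class label (e.g. "NDD duplication") to
    the carrier sample ids. Comorbidity tests cross each flag against
    each carrier class within the clinical subset. For treatment
    outcome, per-individual percent YBOCS improvement is compared
    between carriers and non-carriers with a pooled-variance two-sided
    t-test; samples missing YBOCS are excluded from the outcome test.
    """
    clin = samples[samples.get("has_clinical", pd.Series(True, index=samples.index)).astype(bool)]
    clin = clin.reset_index(drop=True)
    if comorbidity_columns is None:
        comorbidity_columns = [c for c in clin.columns if c.startswith("comorbid_")]
    results: List[ClinicalComparison] = []
    for cls, ids in carrier_classes.items():
        carrier = clin["sample_id"].isin(set(ids)).to_numpy()
        for col in comorbidity_columns:
            flag = clin[col].astype(bool).to_numpy()
            r = contingency_comparison(
                col, cls,
                int((carrier & flag).sum()), int(flag.sum()),
                int((carrier & ~flag).sum()), int((~flag).sum()),
            )
            results.append(r)
    for cls in (outcome_classes or carrier_classes):
        ids = set(carrier_classes[cls])
        has_ybocs = clin["ybocs_pre"].notna() & clin["ybocs_post"].notna()
        sub = clin[has_ybocs]
        carrier = sub["sample_id"].isin(ids).to_numpy()
        impr = percent_improvement(sub["ybocs_pre"], sub["ybocs_post"])
        ok = np.isfinite(impr)
        carrier, impr = carrier[ok], impr[ok]
        if carrier.sum() < 2 or (~carrier).sum() < 2:
            results.append(ClinicalComparison("ybocs_improvement", cls, "ttest", np.nan, np.nan,
                                              np.nan, None, None, int(carrier.sum()), int((~carrier).sum())))
            continue
        t, p = stats.ttest_ind(impr[carrier], impr[~carrier], equal_var=True)
        df = carrier.sum() + (~carrier).sum() - 2
        results.append(ClinicalComparison(
            "ybocs_improvement", cls, "ttest", float(t), float(df), float(p), None,
            (float(impr[carrier].mean()), float(impr[~carrier].mean())),
            int(carrier.sum()), int((~carrier).sum()),
        ))
    return results
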