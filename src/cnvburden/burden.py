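"""Global and partitioned CNV burden tests.

The primary model is a logistic regression of case status on ancestry
principal components, sex, selected technical covariates and one burden
metric at a time::

    case ~ pc1 + pc2 + pc3 + pc4 + pc5 [+ selected] + sex [+ lrrsd] + metric

reporting exp(coef), Wald 95% CI and a two-sided P for the metric term.
Burden metrics are per-sample summaries of the filtered rare callset:
counts by state and size bin, CNV-impacted basepairs, coding/noncoding
counts, dosage-sensitivity (pLI) partitions, geneset counts,
evolutionarily constrained kilobases impacted, and singleton counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .filters import cluster_loci
from .intervals import IntervalSet
from .io_formats import AnnotationBundle

__all__ = [
    "BurdenResult",
    "CovariateSet",
    "select_covariates",
    "fit_burden",
    "partition_metrics",
    "constrained_base_burden",
    "leave_one_out",
    "excess_rate",
    "homogeneity_test",
    "design_matrix",
    "SIZE_BINS",
    "PARTITION_FAMILIES",
]

SIZE_BINS = ((30_000, 100_000), (100_000, 500_000), (500_000, 1_000_000), (1_000_000, None))
_SIZE_LABELS = ("30-100kb", "100-500kb", "500kb-1Mb", ">1Mb")

PARTITION_FAMILIES = (
    "total", "state", "size", "bp", "coding", "pli", "genes_impacted",
    "genesets", "constrained", "singleton",
)

DEFAULT_PHYLOP_CUTS = (1.0, 2.0, 4.0)


@dataclass
class BurdenResult:
    metric: str
    model: str  # "logistic" | "linear"
    estimate: float  # log-odds or slope
    or_: float
    ci_lo: float
    ci_hi: float
    p: float
    n_cases: int
    n_controls: int
    covariates: Tuple[str, ...]
    converged: bool = True
    note: str = ""


@dataclass
class CovariateSet:
    always: Tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4", "pc5", "sex")
    selected: Tuple[str, ...] = ()
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def all(self) -> Tuple[str, ...]:
        return tuple(self.always) + tuple(self.selected)


def design_matrix(samples: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=samples.index)
    for c in covariates:
        if c == "sex":
            X["sex"] = (samples["sex"] == "F").astype(float)
        elif c == "country":
            X["country"] = (samples["country"] == "NOR").astype(float)
        else:
            X[c] = samples[c].astype(float)
    return X


def select_covariates(
    samples: pd.DataFrame,
    raw_call_counts: pd.Series,
    screening_alpha: float = 0.05,
    candidates: Optional[Sequence[str]] = None,
) -> CovariateSet:
    """Screen candidate covariates against raw call count and case status.

    PC1-PC5 and sex are always included. Each candidate (PC6-PC20 and
    LRRSD by default) is added iff its marginal association P is below
    ``screening_alpha`` for BOTH the raw (pre-filter) per-sample call
    count (linear regression) and case status (logistic regression).
    Constant candidates are excluded with a log entry.
    """
    if candidates is None:
        candidates = [f"pc{i}" for i in range(6, 21)] + ["lrrsd"]
    counts = raw_call_counts.reindex(samples["sample_id"]).fillna(0).to_numpy(float)
    y_case = samples["is_case"].to_numpy(float)
    rows = []
    selected = []
    for cand in candidates:
        x = samples[cand].to_numpy(float)
        if np.ptp(x) == 0.0:
            rows.append((cand, np.nan, np.nan, False, "constant"))
            continue
        # linear screen against raw call count (slope t-test == Pearson test)
        p_count = stats.pearsonr(x, counts).pvalue if np.ptp(counts) > 0 else np.nan
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                p_case = sm.Logit(y_case, X).fit(disp=0).pvalues[1]
            except Exception:
                p_case = np.nan
        ok = bool(p_count < screening_alpha and p_case < screening_alpha)
        rows.append((cand, p_count, p_case, ok, ""))
        if ok:
            selected.append(cand)
    log = pd.DataFrame(rows, columns=["candidate", "p_raw_count", "p_case", "selected", "note"])
    return CovariateSet(selected=tuple(selected), log=log)


def fit_burden(
    samples: pd.DataFrame,
    metric: pd.Series,
    covariates: Sequence[str],
    name: str = "burden",
    model: str = "logistic",
    scale: float = 1.0,
    extra_metrics: Optional[Dict[str, pd.Series]] = None,
) -> BurdenResult:
    """Fit the burden model and return the metric-term estimate.

    ``metric`` is indexed by sample_id (missing samples count 0). The
    logistic model regresses case status on covariates + metric; the
    linear variant regresses the metric on covariates + case status and
    reports the case-status term. ``scale`` divides the metric (e.g.
    1e5 for a per-100kb odds ratio).
    """
    m = metric.reindex(samples["sample_id"]).fillna(0).to_numpy(float) / scale
    if np.ptp(m) == 0.0:
        raise ValueError(f"degenerate burden metric {name!r}: no variation across samples")
    X = design_matrix(samples, covariates).reset_index(drop=True)
    if extra_metrics:
        for k, v in extra_metrics.items():
            X[k] = v.reindex(samples["sample_id"]).fillna(0).to_numpy(float)
    y = samples["is_case"].to_numpy(float)
    n_cases = int(y.sum())
    n_controls = int(len(y) - y.sum())
    converged, note = True, ""
    if model == "logistic":
        X["_metric"] = m
        Xc = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception as exc:  # separation / singular design
                return BurdenResult(name, model, np.nan, np.nan, np.nan, np.nan, np.nan,
                                    n_cases, n_controls, tuple(covariates), False, f"fit failed: {exc}")
        est = float(res.params["_metric"])
        se = float(res.bse["_metric"])
        if not np.isfinite(se) or se > 50:
            converged, note = False, "unstable standard error (possible separation)"
        p = float(res.pvalues["_metric"])
    elif model == "linear":
        X["_case"] = y
        Xc = sm.add_constant(X, has_constant="add")
        res = sm.OLS(m, Xc).fit()
        est = float(res.params["_case"])
        se = float(res.bse["_case"])
        p = float(res.pvalues["_case"])
    else:
        raise ValueError(f"unknown model {model!r}")
    z = stats.norm.ppf(0.975)
    return BurdenResult(
        metric=name, model=model, estimate=est, or_=float(np.exp(est)),
        ci_lo=float(np.exp(est - z * se)), ci_hi=float(np.exp(est + z * se)), p=p,
        n_cases=n_cases, n_controls=n_controls, covariates=tuple(covariates),
        converged=converged, note=note,
    )


# ---------------------------------------------------------------------------
# per-sample metrics
# ---------------------------------------------------------------------------

def _gene_hit_sets(genes: pd.DataFrame, mask: np.ndarray) -> Dict[str, IntervalSet]:
    sub = genes[mask]
    return {
        str(c): IntervalSet(g["start"].to_numpy(), g["end"].to_numpy())
        for c, g in sub.groupby("chrom")
    }


def _hits_any(calls: pd.DataFrame, sets: Dict[str, IntervalSet]) -> np.ndarray:
    out = np.zeros(len(calls), dtype=bool)
    pos = np.arange(len(calls))
    chrom = calls["chrom"].to_numpy()
    for c in np.unique(chrom):
        iv = sets.get(str(c))
        if iv is None:
            continue
        m = chrom == c
        out[pos[m]] = iv.overlaps(calls["start"].to_numpy()[m], calls["end"].to_numpy()[m])
    return out


def gene_overlaps(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """(call_idx, gene_id) pairs for every >=1 bp call/gene overlap."""
    pairs_call, pairs_gene = [], []
    chrom_arr = calls["chrom"].to_numpy()
    for c, gsub in genes.groupby("chrom"):
        m = chrom_arr == c
        if not m.any():
            continue
        ci = np.flatnonzero(m)
        cs = calls["start"].to_numpy()[m]
        ce = calls["end"].to_numpy()[m]
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        order = np.argsort(gs, kind="stable")
        gs, ge = gs[order], ge[order]
        gids = gsub["gene_id"].to_numpy()[order]
        run_max = np.maximum.accumulate(ge)
        hi = np.searchsorted(gs, ce, side="left")
        lo = np.searchsorted(run_max, cs, side="right")
        for k in range(ci.size):
            for j in range(lo[k], hi[k]):
                if ge[j] > cs[k] and gs[j] < ce[k]:
                    pairs_call.append(ci[k])
                    pairs_gene.append(gids[j])
    return pd.DataFrame({"call_idx": pairs_call, "gene_id": pairs_gene})


def partition_metrics(
    calls: pd.DataFrame,
    bundle: AnnotationBundle,
    samples: pd.DataFrame,
    partitions: Sequence[str] = PARTITION_FAMILIES,
    phylop_cuts: Sequence[float] = DEFAULT_PHYLOP_CUTS,
) -> pd.DataFrame:
    """Per-sample burden metrics for the requested partition families.

    Returns a frame indexed by sample_id (every retained sample, zeros
    for non-carriers) with one column per metric.
    """
    unknown = set(partitions) - set(PARTITION_FAMILIES)
    if unknown:
        raise ValueError(f"unknown partition families: {sorted(unknown)}")
    idx = pd.Index(samples["sample_id"], name="sample_id")
    out = pd.DataFrame(index=idx)
    sid = calls["sample_id"]
    length = (calls["end"] - calls["start"]).to_numpy()
    is_del = (calls["state"] == "del").to_numpy()

    def _count(mask) -> pd.Series:
        return sid[mask].value_counts().reindex(idx).fillna(0).astype(float)

    def _sum(mask, values) -> pd.Series:
        return pd.Series(values[mask], index=sid[mask]).groupby(level=0).sum().reindex(idx).fillna(0.0)

    if "total" in partitions:
        out["cnv_count"] = _count(np.ones(len(calls), dtype=bool))
    if "state" in partitions:
        out["del_count"] = _count(is_del)
        out["dup_count"] = _count(~is_del)
    if "size" in partitions:
        for (lo, hi), lab in zip(SIZE_BINS, _SIZE_LABELS):
            m = (length >= lo) & (length < (hi or np.inf))
            out[f"count_{lab}"] = _count(m)
            out[f"del_count_{lab}"] = _count(m & is_del)
            out[f"dup_count_{lab}"] = _count(m & ~is_del)
    if "bp" in partitions:
        out["cnv_bp"] = _sum(np.ones(len(calls), dtype=bool), length.astype(float))
        out["del_bp"] = _sum(is_del, length.astype(float))
        out["dup_bp"] = _sum(~is_del, length.astype(float))
    genes = bundle.genes
    if "coding" in partitions or "pli" in partitions:
        coding_sets = _gene_hit_sets(genes, np.ones(len(genes), dtype=bool))
        coding = _hits_any(calls, coding_sets)
        if "coding" in partitions:
            out["coding_count"] = _count(coding)
            out["noncoding_count"] = _count(~coding)
            out["coding_del_count"] = _count(coding & is_del)
            out["coding_dup_count"] = _count(coding & ~is_del)
            out["noncoding_del_count"] = _count(~coding & is_del)
            out["noncoding_dup_count"] = _count(~coding & ~is_del)
    if "pli" in partitions:
        for cut, lab in ((0.5, "pli_gt_0.5"), (0.995, "pli_gt_0.995")):
            sets = _gene_hit_sets(genes, (genes["pli"] > cut).to_numpy())
            hit = _hits_any(calls, sets)
            out[f"count_{lab}"] = _count(hit)
            out[f"del_count_{lab}"] = _count(hit & is_del)
            out[f"dup_count_{lab}"] = _count(hit & ~is_del)
        sets = _gene_hit_sets(genes, (genes["pli"] > 0.5).to_numpy())
        hit = _hits_any(calls, sets)
        out["count_no_pli_gt_0.5"] = _count(~hit & _hits_any(calls, _gene_hit_sets(genes, np.ones(len(genes), bool))))
        for col, mask in (("haplosensitive", genes["haplosensitive"]), ("triplosensitive", genes["triplosensitive"]),
                          ("pnull_gt_0.5", genes["pnull"] > 0.5)):
            sets = _gene_hit_sets(genes, mask.to_numpy().astype(bool))
            hit = _hits_any(calls, sets)
            out[f"count_{col}"] = _count(hit)
    if "genes_impacted" in partitions:
        ov = gene_overlaps(calls, genes)
        for state, lab in (("del", "del"), ("dup", "dup")):
            st_mask = is_del if state == "del" else ~is_del
            sub = ov[np.isin(ov["call_idx"], np.flatnonzero(st_mask))]
            pairs = pd.DataFrame({
                "sample_id": sid.to_numpy()[sub["call_idx"].to_numpy(int)],
                "gene_id": sub["gene_id"],
            }).drop_duplicates()
            out[f"genes_{lab}_impacted"] = (
                pairs.groupby("sample_id").size().reindex(idx).fillna(0).astype(float)
            )
    if "genesets" in partitions:
        for gs_id in bundle.geneset_ids:
            mask = genes["genesets"].str.contains(gs_id, regex=False).to_numpy()
            sets = _gene_hit_sets(genes, mask)
            hit = _hits_any(calls, sets)
            out[f"count_{gs_id}"] = _count(hit)
            out[f"del_count_{gs_id}"] = _count(hit & is_del)
            out[f"dup_count_{gs_id}"] = _count(hit & ~is_del)
    if "constrained" in partitions:
        cons = constrained_base_burden(calls, bundle, samples, phylop_cuts)
        for col in cons.columns:
            out[col] = cons[col]
    if "singleton" in partitions:
        labels = cluster_loci(calls) if len(calls) else np.empty(0, dtype=np.int64)
        if len(calls):
            locus_carriers = pd.DataFrame({"locus": labels, "sample_id": sid.to_numpy()}).drop_duplicates()
            singles = locus_carriers["locus"].value_counts()
            single_loci = set(singles[singles == 1].index)
            m = np.array([l in single_loci for l in labels])
        else:
            m = np.zeros(0, dtype=bool)
        out["singleton_count"] = _count(m)
    return out


def constrained_base_burden(
    calls: pd.DataFrame,
    bundle: AnnotationBundle,
    samples: pd.DataFrame,
    phylop_cuts: Sequence[float] = DEFAULT_PHYLOP_CUTS,
) -> pd.DataFrame:
    """Per-sample kb of constrained bases impacted, per state and score cut."""
    idx = pd.Index(samples["sample_id"], name="sample_id")
    missing = set(calls["chrom"].unique()) - set(bundle.constraint)
    if missing:
        raise ValueError(f"constraint track missing chromosomes: {sorted(missing)}")
    sets: Dict[float, Dict[str, IntervalSet]] = {}
    for cut in phylop_cuts:
        per_chrom = {}
        for c, (s, e, sc) in bundle.constraint.items():
            m = sc >= cut
            per_chrom[c] = IntervalSet(s[m], e[m]) if m.any() else IntervalSet()
        sets[cut] = per_chrom
    out = pd.DataFrame(index=idx)
    sid = calls["sample_id"]
    is_del = (calls["state"] == "del").to_numpy()
    chrom_arr = calls["chrom"].to_numpy()
    for cut in phylop_cuts:
        cov = np.zeros(len(calls), dtype=np.int64)
        for c in np.unique(chrom_arr):
            m = chrom_arr == c
            cov[np.flatnonzero(m)] = sets[cut][str(c)].coverage(
                calls["start"].to_numpy()[m], calls["end"].to_numpy()[m]
            )
        kb = cov / 1000.0
        for st_lab, st_mask in (("del", is_del), ("dup", ~is_del)):
            vals = pd.Series(kb[st_mask], index=sid[st_mask]).groupby(level=0).sum()
            out[f"constrained_kb_ge{cut:g}_{st_lab}"] = vals.reindex(idx).fillna(0.0)
    return out


def carriers_of(calls: pd.DataFrame, genes: pd.DataFrame, gene_mask, state: Optional[str] = None) -> set:
    """Sample ids whose calls (optionally of one state) hit a masked gene set."""
    sub = calls if state is None else calls[calls["state"] == state]
    sub = sub.reset_index(drop=True)
    sets = _gene_hit_sets(genes, np.asarray(gene_mask, dtype=bool))
    hit = _hits_any(sub, sets)
    return set(sub["sample_id"].to_numpy()[hit])


def leave_one_out(
    samples: pd.DataFrame,
    metric: pd.Series,
    covariates: Sequence[str],
    group_key: str = "dataset",
    name: str = "burden",
    model: str = "logistic",
    scale: float = 1.0,
) -> List[BurdenResult]:
    """One burden fit per held-out group (dataset, or dropped covariate)."""
    if group_key == "covariate":
        results = []
        for drop in covariates:
            covs = [c for c in covariates if c != drop]
            r = fit_burden(samples, metric, covs, name=f"{name}_drop_{drop}", model=model, scale=scale)
            results.append(r)
        return results
    groups = sorted(samples[group_key].unique())
    if len(groups) < 3:
        raise ValueError(f"leave-one-out needs >=3 groups, found {len(groups)}")
    results = []
    for g in groups:
        sub = samples[samples[group_key] != g]
        r_name = f"{name}_loo_{g}"
        if sub["is_case"].nunique() < 2:
            results.append(BurdenResult(r_name, model, np.nan, np.nan, np.nan, np.nan, np.nan,
                                        int(sub["is_case"].sum()), int((~sub["is_case"]).sum()),
                                        tuple(covariates), False, "single phenotype class after hold-out"))
            continue
        results.append(fit_burden(sub, metric, covariates, name=r_name, model=model, scale=scale))
    return results


def excess_rate(
    samples: pd.DataFrame,
    metric: pd.Series,
    covariates: Sequence[str],
    n_boot: int = 200,
    seed: int = 0,
) -> Tuple[float, Tuple[float, float]]:
    """Adjusted case-control rate difference for a count metric.

    The point estimate is the case-status coefficient of a linear model
    of the metric on covariates; the CI is a seeded bootstrap percentile
    interval over samples.
    """
    def _fit(df) -> float:
        m = metric.reindex(df["sample_id"]).fillna(0).to_numpy(float)
        X = design_matrix(df, covariates).reset_index(drop=True)
        X["_case"] = df["is_case"].to_numpy(float)
        res = sm.OLS(m, sm.add_constant(X, has_constant="add")).fit()
        return float(res.params["_case"])

    est = _fit(samples)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(samples)
    for _ in range(n_boot):
        boots.append(_fit(samples.iloc[rng.integers(0, n, n)].reset_index(drop=True)))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return est, (float(lo), float(hi))


def homogeneity_test(
    samples: pd.DataFrame,
    metric: pd.Series,
    covariates: Sequence[str],
    by: str = "country",
) -> float:
    """Two-sided P for a metric x group interaction on case status.

    Used to ask whether deleterious CNV burden differs between Swedish
    and Norwegian (or male and female) samples.
    """
    m = metric.reindex(samples["sample_id"]).fillna(0).to_numpy(float)
    if np.ptp(m) == 0.0:
        raise ValueError("degenerate metric")
    covs = [c for c in covariates if c != by]
    X = design_matrix(samples, covs).reset_index(drop=True)
    g = design_matrix(samples, [by]).reset_index(drop=True)[by]
    X["_metric"] = m
    X["_group"] = g
    X["_interaction"] = m * g
    y = samples["is_case"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=100)
    return float(res.pvalues["_interaction"])
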