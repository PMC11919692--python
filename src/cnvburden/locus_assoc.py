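"""Gene- and breakpoint-based locus association with exact stratified tests.

Each locus unit is tested with an exact Cochran-Mantel-Haenszel test:
conditioning on all margins of the per-stratum 2x2 tables
(carrier/non-carrier x case/control over the four country x sex strata),
the total case-carrier count T is distributed as the convolution of
per-stratum hypergeometrics. The two-sided P sums the probabilities of
all outcomes no more likely than the observed one (point-probability
rule, relative tolerance 1e-12); the reported common odds ratio is the
conditional maximum-likelihood estimate. With a single stratum this
reduces exactly to Fisher's exact test.

Genomic inflation is estimated by a within-stratum case/control label
permutation: per-unit exact P values (mid-P by default, softening the
discreteness of exact tests) are converted to 1-df chi-square quantiles
and lambda is the ratio of the observed median to the median of the
pooled permutation null. Units with fewer than two carriers are
excluded from lambda by default: their two-sided exact P is ~1 by
construction, carrying no inflation information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .burden import gene_overlaps

__all__ = [
    "LocusUnit",
    "CmhResult",
    "InflationResult",
    "RecurrenceResult",
    "clump_units",
    "cmh_exact",
    "cmh_exact_tables",
    "bh_fdr",
    "permutation_lambda",
    "exclude_inflation_clusters",
    "recurrence_test",
    "units_results_frame",
    "STRATA_ORDER",
]

STRATA_ORDER = ("SWE_M", "SWE_F", "NOR_M", "NOR_F")


@dataclass
class LocusUnit:
    unit_id: str
    state: str  # "del" | "dup"
    chrom: str
    start: int
    end: int
    members: Tuple[str, ...]  # gene ids, or probe-run descriptor
    carriers: Tuple[str, ...]  # sample ids, deduplicated
    mode: str = "gene"


@dataclass
class CmhResult:
    unit_id: str
    state: str
    or_cmh: float  # conditional MLE of the common odds ratio
    p: float
    mid_p: float
    n_carriers: int
    tables: Tuple[Tuple[int, int, int, int], ...]  # per stratum (a, m, n1, n2)
    bh_q: float = np.nan


@dataclass
class InflationResult:
    lambda_: float
    n_perm: int
    n_units_used: int
    excluded_loci: List[str] = field(default_factory=list)
    per_size_bin: Dict[str, float] = field(default_factory=dict)
    note: str = ""


@dataclass
class RecurrenceResult:
    observed: int
    empirical_p: float
    n_perm: int
    perm_mean: float
    perm_max: int
    state: str = "del"


# ---------------------------------------------------------------------------
# exact CMH core
# ---------------------------------------------------------------------------

_REL_TOL = 1e-12


def _stratum_log_coeffs(m: int, n1: int, n2: int) -> Tuple[int, np.ndarray]:
    """Support min and log hypergeometric coefficients C(n1,t)C(n2,m-t)."""
    tmin = max(0, m - n2)
    tmax = min(m, n1)
    t = np.arange(tmin, tmax + 1)
    logc = (
        gammaln(n1 + 1) - gammaln(t + 1) - gammaln(n1 - t + 1)
        + gammaln(n2 + 1) - gammaln(m - t + 1) - gammaln(n2 - (m - t) + 1)
    )
    return tmin, logc


def _convolve_tables(tables: Sequence[Tuple[int, int, int, int]]) -> Tuple[int, np.ndarray]:
    """Convolve per-stratum coefficient vectors; returns (tmin, coeffs).

    Coefficients are kept in linear space after per-stratum max-shift,
    which is numerically safe because only their ratios matter.
    """
    tmin_total = 0
    coeffs = np.array([1.0])
    for (_, m, n1, n2) in tables:
        tmin, logc = _stratum_log_coeffs(m, n1, n2)
        c = np.exp(logc - logc.max())
        coeffs = np.convolve(coeffs, c)
        coeffs /= coeffs.max()  # prevent under/overflow across many strata
        tmin_total += tmin
    return tmin_total, coeffs


def _pmf_and_pvalues(coeffs: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null pmf plus exact and mid two-sided P for every support point."""
    pmf = coeffs / coeffs.sum()
    k = pmf.size
    p_all = np.empty(k)
    midp_all = np.empty(k)
    for i in range(k):
        wi = pmf[i]
        less = pmf < wi * (1.0 - _REL_TOL)
        eq = ~less & (pmf <= wi * (1.0 + _REL_TOL))
        p_all[i] = pmf[less].sum() + pmf[eq].sum()
        midp_all[i] = pmf[less].sum() + 0.5 * pmf[eq].sum()
    return pmf, np.minimum(p_all, 1.0), np.minimum(midp_all, 1.0)


def _conditional_mle_or(tables, tmin: int, coeffs: np.ndarray, t_obs: int) -> float:
    """Conditional MLE of the common odds ratio given observed total T."""
    k = coeffs.size
    if k == 1:
        return np.nan
    tmax = tmin + k - 1
    if t_obs <= tmin:
        return 0.0
    if t_obs >= tmax:
        return np.inf
    logc = np.log(coeffs)
    t = np.arange(k, dtype=float)

    def mean_minus_obs(log_psi: float) -> float:
        logw = logc + t * log_psi
        w = np.exp(logw - logw.max())
        return float((t * w).sum() / w.sum() + tmin - t_obs)

    lo, hi = -35.0, 35.0
    if mean_minus_obs(lo) > 0:
        return 0.0
    if mean_minus_obs(hi) < 0:
        return np.inf
    return float(np.exp(brentq(mean_minus_obs, lo, hi, xtol=1e-12)))


def cmh_exact_tables(tables: Sequence[Tuple[int, int, int, int]],
                     unit_id: str = "", state: str = "",
                     two_sided: str = "point_prob") -> CmhResult:
    """Exact CMH test from per-stratum tables of (a, m, n1, n2).

    ``a`` = case carriers, ``m`` = total carriers, ``n1`` = cases,
    ``n2`` = controls in the stratum. All-zero carrier counts give
    P = 1 with an undefined (NaN) odds ratio. ``two_sided`` selects the
    convention: ``"point_prob"`` (sum of outcomes no more likely than
    observed, the default) or ``"double_tail"`` (twice the smaller
    tail, capped at 1).
    """
    tables = [tuple(int(x) for x in tab) for tab in tables]
    for a, m, n1, n2 in tables:
        if not (0 <= a <= min(m, n1) and max(0, m - n2) <= a):
            raise ValueError(f"inconsistent stratum table (a={a}, m={m}, n1={n1}, n2={n2})")
    m_total = sum(tab[1] for tab in tables)
    t_obs = sum(tab[0] for tab in tables)
    if m_total == 0:
        return CmhResult(unit_id, state, np.nan, 1.0, 1.0, 0, tuple(tables))
    tmin, coeffs = _convolve_tables(tables)
    pmf, p_all, midp_all = _pmf_and_pvalues(coeffs)
    i = t_obs - tmin
    if two_sided == "point_prob":
        p = float(p_all[i])
    elif two_sided == "double_tail":
        p = float(min(1.0, 2.0 * min(pmf[: i + 1].sum(), pmf[i:].sum())))
    else:
        raise ValueError(f"unknown two-sided convention {two_sided!r}")
    or_ = _conditional_mle_or(tables, tmin, coeffs, t_obs)
    return CmhResult(unit_id, state, or_, p, float(midp_all[i]), m_total, tuple(tables))


def _unit_tables(unit: LocusUnit, samples: pd.DataFrame) -> List[Tuple[int, int, int, int]]:
    carriers = set(unit.carriers)
    tables = []
    for stratum in STRATA_ORDER:
        sub = samples[samples["stratum"] == stratum]
        is_case = sub["is_case"].to_numpy(bool)
        in_unit = sub["sample_id"].isin(carriers).to_numpy()
        a = int((in_unit & is_case).sum())
        m = int(in_unit.sum())
        n1 = int(is_case.sum())
        n2 = int(len(sub) - n1)
        tables.append((a, m, n1, n2))
    return tables


def cmh_exact(unit: LocusUnit, samples: pd.DataFrame) -> CmhResult:
    """Exact CMH test of a locus unit against the stratified cohort."""
    return cmh_exact_tables(_unit_tables(unit, samples), unit.unit_id, unit.state)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def clump_units(
    calls: pd.DataFrame,
    bundle,
    samples: pd.DataFrame,
    mode: str = "gene",
    state: str = "del",
) -> List[LocusUnit]:
    """Clump the filtered callset of one state into locus test units.

    Gene mode merges neighboring genes when over 50% of the CNVs
    overlapping either gene overlap both (Jaccard of their call sets
    > 0.5), iterated to a fixed point. Breakpoint mode merges adjacent
    probes into maximal runs under the same >50% sharing rule.
    Deterministic: ties broken by genomic coordinate.
    """
    sub = calls[calls["state"] == state].reset_index(drop=True)
    if mode == "gene":
        return _clump_genes(sub, bundle.genes, state)
    if mode == "breakpoint":
        return _clump_breakpoints(sub, bundle.probes, state)
    raise ValueError(f"unknown clumping mode {mode!r}")


def _clump_genes(calls: pd.DataFrame, genes: pd.DataFrame, state: str) -> List[LocusUnit]:
    ov = gene_overlaps(calls, genes)
    if len(ov) == 0:
        return []
    gene_calls: Dict[str, set] = {
        g: set(grp["call_idx"]) for g, grp in ov.groupby("gene_id")
    }
    ginfo = genes.set_index("gene_id")
    # units start as single genes, ordered by genomic coordinate
    order = sorted(gene_calls, key=lambda g: (ginfo.at[g, "chrom"], int(ginfo.at[g, "start"]), g))
    units: List[Tuple[List[str], set]] = [([g], set(gene_calls[g])) for g in order]
    changed = True
    while changed:
        changed = False
        call_to_units: Dict[int, List[int]] = {}
        for ui, (_, cs) in enumerate(units):
            for c in cs:
                call_to_units.setdefault(c, []).append(ui)
        merged_into: Dict[int, int] = {}

        def find(ui: int) -> int:
            while ui in merged_into:
                ui = merged_into[ui]
            return ui

        pairs = sorted({tuple(sorted((a, b))) for us in call_to_units.values()
                        for a in us for b in us if a != b})
        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            if _jaccard(units[ra][1], units[rb][1]) > 0.5:
                lo, hi = (ra, rb) if ra < rb else (rb, ra)
                units[lo] = (units[lo][0] + units[hi][0], units[lo][1] | units[hi][1])
                merged_into[hi] = lo
                changed = True
        units = [u for ui, u in enumerate(units) if ui not in merged_into]
    out = []
    sid = calls["sample_id"].to_numpy()
    for k, (members, cs) in enumerate(units):
        members = sorted(members, key=lambda g: (ginfo.at[g, "chrom"], int(ginfo.at[g, "start"])))
        chrom = str(ginfo.at[members[0], "chrom"])
        start = int(min(ginfo.at[g, "start"] for g in members))
        end = int(max(ginfo.at[g, "end"] for g in members))
        carriers = tuple(sorted(set(sid[sorted(cs)])))
        out.append(LocusUnit(f"{state}_gene_{chrom}_{start}", state, chrom, start, end,
                             tuple(members), carriers, "gene"))
    out.sort(key=lambda u: (u.chrom, u.start, u.end))
    return out


def _clump_breakpoints(calls: pd.DataFrame, probes: Dict[str, np.ndarray], state: str) -> List[LocusUnit]:
    out = []
    sid_all = calls["sample_id"].to_numpy()
    for chrom in sorted(calls["chrom"].unique()):
        pos = probes.get(str(chrom))
        if pos is None or pos.size == 0:
            raise ValueError(f"probe map missing for chromosome {chrom}")
        grp = calls[calls["chrom"] == chrom]
        gi = grp.index.to_numpy()
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        events: Dict[int, List[Tuple[int, int]]] = {}
        for ci, l, h in zip(gi, lo, hi):
            if h > l:
                events.setdefault(l, []).append((ci, +1))
                events.setdefault(h, []).append((ci, -1))
        if not events:
            continue
        boundaries = sorted(events)
        active: set = set()
        runs: List[Tuple[int, int, set]] = []  # (probe_lo, probe_hi, call set)
        prev_set: Optional[set] = None
        cur_lo = None
        cur_calls: set = set()
        for bi, b in enumerate(boundaries):
            for ci, delta in events[b]:
                if delta > 0:
                    active.add(ci)
                else:
                    active.discard(ci)
            nxt = boundaries[bi + 1] if bi + 1 < len(boundaries) else pos.size
            if not active:
                if cur_lo is not None:
                    runs.append((cur_lo, b, cur_calls))
                    cur_lo, cur_calls, prev_set = None, set(), None
                continue
            seg_set = set(active)
            if cur_lo is None:
                cur_lo, cur_calls, prev_set = b, set(seg_set), seg_set
            else:
                if _jaccard(prev_set, seg_set) > 0.5:
                    cur_calls |= seg_set
                    prev_set = seg_set
                else:
                    runs.append((cur_lo, b, cur_calls))
                    cur_lo, cur_calls, prev_set = b, set(seg_set), seg_set
            del nxt
        if cur_lo is not None:
            runs.append((cur_lo, boundaries[-1] + 1, cur_calls))
        for plo, phi, cs in runs:
            phi_idx = min(phi, pos.size) - 1
            start = int(pos[plo])
            end = int(pos[phi_idx]) + 1
            carriers = tuple(sorted(set(sid_all[sorted(cs)])))
            out.append(LocusUnit(f"{state}_bp_{chrom}_{start}", state, str(chrom), start, end,
                                 (f"probes_{plo}_{phi}",), carriers, "breakpoint"))
    out.sort(key=lambda u: (u.chrom, u.start, u.end))
    return out


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

class _PermEngine:
    """Shared within-stratum label permutation for a set of units."""

    def __init__(self, units: Sequence[LocusUnit], samples: pd.DataFrame,
                 n_perm: int, rng: np.random.Generator):
        self.units = list(units)
        self.n_perm = n_perm
        strata = []
        for stratum in STRATA_ORDER:
            sub = samples[samples["stratum"] == stratum]
            if len(sub) == 0:
                continue
            pos = {s: i for i, s in enumerate(sub["sample_id"])}
            is_case = sub["is_case"].to_numpy(bool)
            labels = np.tile(is_case.astype(np.int8)[:, None], (1, n_perm))
            labels = rng.permuted(labels, axis=0)
            strata.append((pos, is_case, labels))
        self.strata = strata
        # observed case-carrier totals and permuted totals per unit
        self.t_obs = np.zeros(len(self.units), dtype=np.int64)
        self.t_perm = np.zeros((len(self.units), n_perm), dtype=np.int64)
        self.m_total = np.zeros(len(self.units), dtype=np.int64)
        self.tables: List[List[Tuple[int, int, int, int]]] = []
        for ui, unit in enumerate(self.units):
            tabs = []
            for pos, is_case, labels in strata:
                idx = np.array([pos[s] for s in unit.carriers if s in pos], dtype=np.int64)
                m = idx.size
                a = int(is_case[idx].sum()) if m else 0
                n1 = int(is_case.sum())
                n2 = int(is_case.size - n1)
                tabs.append((a, m, n1, n2))
                self.t_obs[ui] += a
                self.m_total[ui] += m
                if m:
                    self.t_perm[ui] += labels[idx].sum(axis=0)
            self.tables.append(tabs)

    def pvalue_tables(self, mid_p: bool) -> Tuple[np.ndarray, np.ndarray]:
        """(observed p, permuted p matrix) per unit via lookup tables."""
        p_obs = np.ones(len(self.units))
        p_perm = np.ones((len(self.units), self.n_perm))
        for ui, tabs in enumerate(self.tables):
            if self.m_total[ui] == 0:
                continue
            tmin, coeffs = _convolve_tables(tabs)
            _, p_all, midp_all = _pmf_and_pvalues(coeffs)
            table = midp_all if mid_p else p_all
            p_obs[ui] = table[self.t_obs[ui] - tmin]
            p_perm[ui] = table[self.t_perm[ui] - tmin]
        return p_obs, p_perm


def permutation_lambda(
    units: Sequence[LocusUnit],
    samples: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    mid_p: bool = True,
    min_carriers: int = 2,
) -> InflationResult:
    """Permutation-based genomic inflation factor for a set of units.

    lambda = median(observed chi2) / median(pooled permuted chi2) where
    chi2 are 1-df quantiles of the per-unit exact P values under the
    observed labels and under within-stratum case/control permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null median")
    rng = np.random.default_rng(seed)
    eng = _PermEngine(units, samples, n_perm, rng)
    incl = eng.m_total >= min_carriers
    if not incl.any():
        return InflationResult(np.nan, n_perm, 0, note="no units with enough carriers")
    p_obs, p_perm = eng.pvalue_tables(mid_p)
    chi_obs = stats.chi2.isf(np.clip(p_obs[incl], 1e-300, 1.0), 1)
    chi_perm = stats.chi2.isf(np.clip(p_perm[incl].ravel(), 1e-300, 1.0), 1)
    denom = float(np.median(chi_perm))
    lam = float(np.median(chi_obs) / denom) if denom > 0 else np.nan
    return InflationResult(lam, n_perm, int(incl.sum()))


def exclude_inflation_clusters(
    units: Sequence[LocusUnit],
    samples: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    lambda_threshold: float = 1.05,
    mid_p: bool = True,
    min_carriers: int = 2,
    max_excluded: int = 20,
    concentration_datasets: int = 2,
    min_cluster_carriers: int = 3,
    candidate_p: float = 0.1,
) -> Tuple[List[str], InflationResult]:
    """Exclude batch-artifact units and recompute the bin lambda.

    Mirrors a manual inspection for dataset-specific call pileups in two
    phases. Phase 1 excludes every unit whose carriers are concentrated
    in at most ``concentration_datasets`` datasets, all of one phenotype
    class, at least ``min_cluster_carriers`` strong, and whose exact
    mid-P falls below ``candidate_p``: such pileups are the signature of
    a batch artifact regardless of the bin-level lambda, which (being a
    median ratio over tens of units) moves by less than its own
    Monte-Carlo spread when only a few loci are contaminated. Phase 2,
    while lambda still exceeds ``lambda_threshold`` and concentrated
    units remain, greedily drops the unit whose removal most reduces
    lambda (warning note set when lambda stays high with no qualifying
    unit left).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null median")
    rng = np.random.default_rng(seed)
    eng = _PermEngine(units, samples, n_perm, rng)
    p_obs, p_perm = eng.pvalue_tables(mid_p)
    chi_obs = stats.chi2.isf(np.clip(p_obs, 1e-300, 1.0), 1)
    chi_perm = stats.chi2.isf(np.clip(p_perm, 1e-300, 1.0), 1)
    sample_info = samples.set_index("sample_id")[["dataset", "is_case"]]

    def _lam(mask: np.ndarray) -> float:
        use = mask & (eng.m_total >= min_carriers)
        if not use.any():
            return np.nan
        denom = float(np.median(chi_perm[use].ravel()))
        return float(np.median(chi_obs[use]) / denom) if denom > 0 else np.nan

    def _concentrated(unit: LocusUnit) -> bool:
        if len(unit.carriers) < min_cluster_carriers:
            return False
        info = sample_info.loc[list(unit.carriers)]
        return info["dataset"].nunique() <= concentration_datasets and info["is_case"].nunique() == 1

    active = np.ones(len(eng.units), dtype=bool)
    excluded: List[str] = []
    # phase 1: deterministic pileup screen, most significant first
    flagged = sorted(
        (ui for ui in range(len(eng.units))
         if p_obs[ui] < candidate_p and _concentrated(eng.units[ui])),
        key=lambda ui: (p_obs[ui], eng.units[ui].unit_id),
    )
    for ui in flagged[:max_excluded]:
        active[ui] = False
        excluded.append(eng.units[ui].unit_id)
    # phase 2: lambda-gated greedy cleanup
    note = ""
    while len(excluded) < max_excluded:
        lam = _lam(active)
        if not np.isfinite(lam) or lam <= lambda_threshold:
            break
        best_ui, best_lam = None, lam
        for ui in np.flatnonzero(active):
            if not _concentrated(eng.units[ui]):
                continue
            trial = active.copy()
            trial[ui] = False
            l2 = _lam(trial)
            if np.isfinite(l2) and l2 < best_lam - 1e-12:
                best_ui, best_lam = ui, l2
        if best_ui is None:
            note = "lambda above threshold but no qualifying cluster unit remains"
            warnings.warn(note)
            break
        active[best_ui] = False
        excluded.append(eng.units[best_ui].unit_id)
    final = InflationResult(_lam(active), n_perm, int((active & (eng.m_total >= min_carriers)).sum()),
                            excluded_loci=list(excluded), note=note)
    return excluded, final


def size_bin_lambda(
    calls: pd.DataFrame,
    bundle,
    samples: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    state: str = "del",
    mode: str = "breakpoint",
    bins: Sequence[Tuple[int, Optional[int]]] = ((30_000, 100_000), (100_000, 500_000),
                                                 (500_000, 1_000_000), (1_000_000, None)),
    min_carriers: int = 2,
) -> Tuple[Dict[str, InflationResult], Dict[str, List[LocusUnit]]]:
    """Per-size-bin inflation estimates (batch-effect screening).

    Calls of one state are binned by length, clumped into units within
    each bin, and a permutation lambda computed per bin. Returns the
    per-bin results and the unit lists (for subsequent exclusion).
    """
    results: Dict[str, InflationResult] = {}
    units_by_bin: Dict[str, List[LocusUnit]] = {}
    length = (calls["end"] - calls["start"]).to_numpy()
    for lo, hi in bins:
        lab = f"{lo // 1000}kb-{hi // 1000 if hi else 'inf'}kb"
        sub = calls[(length >= lo) & (length < (hi or np.iinfo(np.int64).max))].reset_index(drop=True)
        units = clump_units(sub, bundle, samples, mode, state)
        units_by_bin[lab] = units
        if units:
            results[lab] = permutation_lambda(units, samples, n_perm, seed=seed, min_carriers=min_carriers)
        else:
            results[lab] = InflationResult(np.nan, n_perm, 0, note="no units in bin")
    return results, units_by_bin


def recurrence_test(
    units: Sequence[LocusUnit],
    samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_case_carriers: int = 2,
    case_only: bool = False,
    state: str = "del",
) -> RecurrenceResult:
    """Permutation test for non-random recurrence of case deletions.

    Statistic: number of units with at least ``min_case_carriers`` case
    carriers (optionally requiring zero control carriers). The null
    permutes case/control labels within strata; empirical
    P = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed)
    eng = _PermEngine(units, samples, n_perm, rng)
    obs_case = eng.t_obs
    obs_ctrl = eng.m_total - eng.t_obs
    if case_only:
        observed = int(((obs_case >= min_case_carriers) & (obs_ctrl == 0)).sum())
        perm_ctrl = eng.m_total[:, None] - eng.t_perm
        perm_stat = ((eng.t_perm >= min_case_carriers) & (perm_ctrl == 0)).sum(axis=0)
    else:
        observed = int((obs_case >= min_case_carriers).sum())
        perm_stat = (eng.t_perm >= min_case_carriers).sum(axis=0)
    p = float((1 + int((perm_stat >= observed).sum())) / (1 + n_perm))
    return RecurrenceResult(observed, p, n_perm, float(perm_stat.mean()), int(perm_stat.max()), state)


def units_results_frame(results: Sequence[CmhResult], units: Sequence[LocusUnit]) -> pd.DataFrame:
    """Summary-statistics table: unit, span, per-stratum counts, OR, P, q."""
    by_id = {u.unit_id: u for u in units}
    q = bh_fdr([r.p for r in results])
    rows = []
    for r, qv in zip(results, q):
        u = by_id[r.unit_id]
        row = {
            "unit_id": r.unit_id, "state": r.state, "chrom": u.chrom, "start": u.start,
            "end": u.end, "members": ",".join(u.members), "n_carriers": r.n_carriers,
            "or_cmh": r.or_cmh, "p": r.p, "mid_p": r.mid_p, "bh_q": qv,
        }
        for name, (a, m, n1, n2) in zip(STRATA_ORDER, r.tables):
            row[f"{name}_case_carriers"] = a
            row[f"{name}_carriers"] = m
        rows.append(row)
    return pd.DataFrame(rows)
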