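"""Post-calling filter cascade producing the analysis-ready rare callset.

Order (first triggered reason wins, matching the cascade):

1. locus exclusion by fractional overlap (>30% of CNV bases) with
   telomere/centromere margins, polyN, segmental duplications and
   repeats; any overlap at all with Ig/TCR gene regions or EBV-LCL
   artifact loci;
2. external SV frequency (matched record at >=1% in any population);
3. cohort frequency (locus carrier frequency >=1% combined or in any
   single input dataset, loci defined by >=50% reciprocal overlap and
   same copy state);
4. BAF copy-state validation (deletions must lack a heterozygous band;
   duplications must show bands near 1/3 and 2/3).

The BAF rule is a concrete re-specification of the intensity-based
validation idea used with array CNV calls; thresholds are exposed in
:class:`~cnvburden.config.FilterConfig` and documented as an
interpretation, not a reimplementation of any specific tool.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import FilterConfig
from .intervals import GenomeIntervals, reciprocal_overlap
from .io_formats import AnnotationBundle

__all__ = [
    "overlap_fraction",
    "apply_locus_filters",
    "cluster_loci",
    "cohort_frequency_filter",
    "external_frequency_filter",
    "baf_validate",
    "baf_validate_calls",
    "run_filter_cascade",
    "CASCADE_TRACKS",
]

CASCADE_TRACKS = (
    "telomere_margin",
    "centromere_margin",
    "polyN",
    "segdup",
    "repeat",
    "ig_tcr",
    "ebv_artifact",
)


def overlap_fraction(calls, track: GenomeIntervals) -> np.ndarray:
    """Fraction of each call's bases covered by a (merged) track."""
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame(
            [(calls.chrom, calls.start, calls.end)], columns=["chrom", "start", "end"]
        )
    cov = track.coverage_frame(calls)
    length = (calls["end"] - calls["start"]).to_numpy()
    return cov / length


def apply_locus_filters(
    calls: pd.DataFrame, bundle: AnnotationBundle, config: FilterConfig = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls overlapping excluded loci; first-triggered reason logged."""
    config = config or FilterConfig()
    reasons = np.full(len(calls), "", dtype=object)
    for name in CASCADE_TRACKS:
        frac = overlap_fraction(calls, bundle.tracks[name])
        if name in config.any_overlap_tracks:
            hit = frac > 0.0
        else:
            hit = frac > config.overlap_threshold
        reasons = np.where((reasons == "") & hit, name, reasons)
    removed_mask = reasons != ""
    kept = calls[~removed_mask].reset_index(drop=True)
    removed = calls[removed_mask].copy()
    removed["reason"] = reasons[removed_mask]
    return kept, removed.reset_index(drop=True)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller root wins
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def cluster_loci(calls: pd.DataFrame, reciprocal: float = 0.5) -> np.ndarray:
    """Single-linkage clustering of calls into loci.

    Two calls belong to the same locus when they share the same
    chromosome and copy state and have >= ``reciprocal`` reciprocal
    overlap (transitively). Returns an integer locus label per call,
    deterministic under input reordering (labels follow genomic order).
    """
    n = len(calls)
    uf = _UnionFind(n)
    idx = np.arange(n)
    chrom = calls["chrom"].to_numpy()
    state = calls["state"].to_numpy()
    start = calls["start"].to_numpy()
    end = calls["end"].to_numpy()
    key = pd.Series(chrom).astype(str) + "|" + pd.Series(state).astype(str)
    for _, grp_idx in pd.Series(idx).groupby(key.to_numpy()):
        g = grp_idx.to_numpy()
        order = g[np.lexsort((end[g], start[g]))]
        s, e = start[order], end[order]
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                if s[j] >= e[i]:
                    break
                ov = min(e[i], e[j]) - max(s[i], s[j])
                if ov <= 0:
                    continue
                if ov >= reciprocal * max(e[i] - s[i], e[j] - s[j]):
                    uf.union(int(order[i]), int(order[j]))
    roots = np.array([uf.find(i) for i in range(n)])
    # relabel roots in genomic order for determinism
    order = np.lexsort((start, pd.factorize(pd.Series(chrom).astype(str) + state, sort=True)[0]))
    labels = {}
    out = np.empty(n, dtype=np.int64)
    for i in order:
        r = roots[i]
        if r not in labels:
            labels[r] = len(labels)
    for i in range(n):
        out[i] = labels[roots[i]]
    return out


def cohort_frequency_filter(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    config: FilterConfig = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls at loci with carrier frequency >= threshold.

    Frequency is evaluated in the full combined cohort and within each
    input dataset separately; violating either removes every call at
    the locus.
    """
    config = config or FilterConfig()
    if len(calls) == 0:
        return calls.reset_index(drop=True), calls.assign(reason=pd.Series(dtype=object))
    labels = cluster_loci(calls, config.reciprocal_overlap_for_freq)
    n_total = len(samples)
    ds_sizes = samples.groupby("dataset").size()
    sample_ds = samples.set_index("sample_id")["dataset"]

    work = calls[["sample_id"]].copy()
    work["locus"] = labels
    work["dataset"] = work["sample_id"].map(sample_ds)
    reasons = {}
    for locus, grp in work.groupby("locus"):
        carriers = grp.drop_duplicates("sample_id")
        if len(carriers) / n_total >= config.freq_threshold:
            reasons[locus] = "cohort_freq"
            continue
        per_ds = carriers.groupby("dataset").size()
        for ds, k in per_ds.items():
            if k / ds_sizes[ds] >= config.freq_threshold:
                reasons[locus] = "dataset_freq"
                break
    removed_mask = np.array([labels[i] in reasons for i in range(len(calls))])
    kept = calls[~removed_mask].reset_index(drop=True)
    removed = calls[removed_mask].copy()
    removed["reason"] = [reasons[l] for l in labels[removed_mask]]
    return kept, removed.reset_index(drop=True)


def external_frequency_filter(
    calls: pd.DataFrame,
    sv_track: pd.DataFrame,
    config: FilterConfig = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls matching an external SV record common in any population.

    A match is >=50% reciprocal overlap with the same copy state; the
    record disqualifies the call when its frequency is >= the threshold
    in the global column or any subpopulation column.
    """
    config = config or FilterConfig()
    freq_cols = [c for c in sv_track.columns if c.startswith("freq_")]
    if not freq_cols:
        raise ValueError("SV frequency track has no freq_* columns")
    if len(calls) == 0:
        return calls.reset_index(drop=True), calls.assign(reason=pd.Series(dtype=object))
    calls = calls.reset_index(drop=True)
    sv = sv_track.copy()
    sv["_common"] = (sv[freq_cols].to_numpy(float) >= config.freq_threshold).any(axis=1)
    sv = sv[sv["_common"]]
    removed_mask = np.zeros(len(calls), dtype=bool)
    for (chrom, state), grp in calls.groupby(["chrom", "state"], sort=False):
        rec = sv[(sv["chrom"] == chrom) & (sv["state"] == state)]
        if len(rec) == 0:
            continue
        ro = reciprocal_overlap(
            grp["start"].to_numpy()[:, None],
            grp["end"].to_numpy()[:, None],
            rec["start"].to_numpy()[None, :],
            rec["end"].to_numpy()[None, :],
        )
        hit = (ro >= config.reciprocal_overlap_for_freq).any(axis=1)
        removed_mask[grp.index.to_numpy()[hit]] = True
    kept = calls[~removed_mask].reset_index(drop=True)
    removed = calls[removed_mask].copy()
    removed["reason"] = "external_freq"
    return kept, removed.reset_index(drop=True)


def baf_validate(baf_values, state: str, config: FilterConfig = None) -> str:
    """Validate one call's copy state against its probe BAF distribution.

    Returns ``"accept"``, ``"reject"`` or ``"insufficient"`` (treated
    as accept downstream). Deletions are rejected when more than 10% of
    probes sit in the heterozygous band [0.25, 0.75]; duplications are
    accepted when at least half of the informative probes (BAF in
    (0.15, 0.85)) fall within +/-0.09 of 1/3 or 2/3.
    """
    config = config or FilterConfig()
    vals = np.asarray(baf_values, dtype=float)
    if vals.size == 0:
        raise ValueError("call has zero probes with BAF values")
    if state == "del":
        if vals.size < config.min_informative_probes:
            return "insufficient"
        lo, hi = config.baf_het_band
        het_frac = np.mean((vals >= lo) & (vals <= hi))
        return "reject" if het_frac > config.baf_max_het_fraction_del else "accept"
    if state == "dup":
        lo, hi = config.baf_dup_informative_range
        inf = vals[(vals > lo) & (vals < hi)]
        if inf.size < config.min_informative_probes:
            return "insufficient"
        w = config.baf_dup_band_halfwidth
        near = np.zeros(inf.size, dtype=bool)
        for c in config.baf_dup_band_centers:
            near |= np.abs(inf - c) <= w
        return "accept" if near.mean() >= config.baf_dup_min_band_fraction else "reject"
    raise ValueError(f"unknown copy state {state!r}")


def baf_validate_calls(
    calls: pd.DataFrame, baf: pd.DataFrame, config: FilterConfig = None
) -> pd.Series:
    """Vectorized BAF validation for a calls frame against a probe table."""
    config = config or FilterConfig()
    if len(calls) == 0:
        return pd.Series(dtype=object)
    sample_codes, sample_uniq = pd.factorize(
        pd.concat([baf["sample_id"], calls["sample_id"]], ignore_index=True)
    )
    chrom_codes, chrom_uniq = pd.factorize(
        pd.concat([baf["chrom"], calls["chrom"]], ignore_index=True)
    )
    nb = len(baf)
    b_key = (sample_codes[:nb].astype(np.int64) * len(chrom_uniq) + chrom_codes[:nb]) << np.int64(33)
    b_key = b_key | baf["pos"].to_numpy(np.int64)
    order = np.argsort(b_key, kind="stable")
    b_key = b_key[order]
    vals = baf["baf"].to_numpy(float)[order]

    lo_het, hi_het = config.baf_het_band
    het = ((vals >= lo_het) & (vals <= hi_het)).astype(np.int64)
    lo_inf, hi_inf = config.baf_dup_informative_range
    informative = ((vals > lo_inf) & (vals < hi_inf)).astype(np.int64)
    w = config.baf_dup_band_halfwidth
    near = np.zeros(vals.size, dtype=np.int64)
    for c in config.baf_dup_band_centers:
        near |= (np.abs(vals - c) <= w).astype(np.int64)
    near &= informative
    cum_het = np.concatenate(([0], np.cumsum(het)))
    cum_inf = np.concatenate(([0], np.cumsum(informative)))
    cum_near = np.concatenate(([0], np.cumsum(near)))

    c_code = (sample_codes[nb:].astype(np.int64) * len(chrom_uniq) + chrom_codes[nb:]) << np.int64(33)
    k_lo = c_code | calls["start"].to_numpy(np.int64)
    k_hi = c_code | calls["end"].to_numpy(np.int64)
    lo = np.searchsorted(b_key, k_lo, side="left")
    hi = np.searchsorted(b_key, k_hi, side="left")
    n_tot = hi - lo
    if (n_tot == 0).any():
        bad = calls[n_tot == 0].iloc[0]
        raise ValueError(
            f"no BAF probes for call {bad['sample_id']} {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    n_het = cum_het[hi] - cum_het[lo]
    n_inf = cum_inf[hi] - cum_inf[lo]
    n_near = cum_near[hi] - cum_near[lo]

    status = np.empty(len(calls), dtype=object)
    is_del = (calls["state"] == "del").to_numpy()
    ins_del = is_del & (n_tot < config.min_informative_probes)
    ins_dup = ~is_del & (n_inf < config.min_informative_probes)
    status[ins_del | ins_dup] = "insufficient"
    rej_del = is_del & ~ins_del & (n_het / np.maximum(n_tot, 1) > config.baf_max_het_fraction_del)
    acc_del = is_del & ~ins_del & ~rej_del
    frac_near = n_near / np.maximum(n_inf, 1)
    acc_dup = ~is_del & ~ins_dup & (frac_near >= config.baf_dup_min_band_fraction)
    rej_dup = ~is_del & ~ins_dup & ~acc_dup
    status[rej_del | rej_dup] = "reject"
    status[acc_del | acc_dup] = "accept"
    return pd.Series(status, index=calls.index)


def run_filter_cascade(
    calls: pd.DataFrame,
    bundle: AnnotationBundle,
    samples: pd.DataFrame,
    baf: Optional[pd.DataFrame] = None,
    config: FilterConfig = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full filter cascade; returns (kept, removal log).

    Each removed call carries exactly one reason, the first triggered
    in cascade order. The BAF step is skipped when no probe table is
    supplied; "insufficient" validations are treated as accepts.
    """
    config = config or FilterConfig()
    kept, removed1 = apply_locus_filters(calls, bundle, config)
    parts = [removed1]
    if bundle.sv_freq is not None and len(bundle.sv_freq):
        kept, removed2 = external_frequency_filter(kept, bundle.sv_freq, config)
        parts.append(removed2)
    kept, removed3 = cohort_frequency_filter(kept, samples, config)
    parts.append(removed3)
    if baf is not None and len(baf):
        status = baf_validate_calls(kept, baf, config)
        rej = (status == "reject").to_numpy()
        removed4 = kept[rej].copy()
        removed4["reason"] = "baf_reject"
        kept = kept[~rej].reset_index(drop=True)
        parts.append(removed4)
    log = pd.concat([p for p in parts if len(p)], ignore_index=True) if any(len(p) for p in parts) else (
        calls.iloc[0:0].assign(reason=pd.Series(dtype=object))
    )
    return kept.reset_index(drop=True), log
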