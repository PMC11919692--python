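"""Consensus CNV calls from two callers, call qualification and sample QC.

The consensus rule: two calls from the same sample with the same copy
state whose overlap is at least 50% of the shorter call are paired
(greedily, by descending overlap length) and the interval intersection
is emitted with probe support recounted on the probe map. Calls seen by
only one caller are dropped.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import QcThresholds
from .io_formats import CALL_COLUMNS, validate_calls

__all__ = ["consensus_calls", "qualify_calls", "prune_samples"]


def _count_probes(probes: Dict[str, np.ndarray], chroms, starts, ends) -> np.ndarray:
    out = np.zeros(len(chroms), dtype=np.int64)
    chroms = np.asarray(chroms)
    for c in np.unique(chroms):
        if c not in probes:
            raise ValueError(f"probe map missing for chromosome {c}")
        pos = probes[str(c)]
        m = chroms == c
        out[m] = np.searchsorted(pos, ends[m], side="left") - np.searchsorted(pos, starts[m], side="left")
    return out


def consensus_calls(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    probes: Dict[str, np.ndarray],
    min_overlap_of_shorter: float = 0.5,
) -> pd.DataFrame:
    """Intersect two callsets into consensus calls.

    Pairing is greedy by descending overlap length within each
    (sample, chromosome, copy state) group, with deterministic
    coordinate tie-breaks; each parent call is used at most once.
    """
    validate_calls(calls_a)
    validate_calls(calls_b)
    if len(calls_a) == 0 or len(calls_b) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)

    def _prep(df):
        key = df["sample_id"].astype(str) + "|" + df["chrom"].astype(str) + "|" + df["state"].astype(str)
        order = np.lexsort((df["start"].to_numpy(), key.to_numpy()))
        return df.iloc[order].reset_index(drop=True), key.to_numpy()[order]

    a, key_a = _prep(calls_a)
    b, key_b = _prep(calls_b)
    # group boundaries per key in each frame
    bounds_a = _group_bounds(key_a)
    bounds_b = _group_bounds(key_b)

    a_start = a["start"].to_numpy()
    a_end = a["end"].to_numpy()
    a_cn = a["cn"].to_numpy()
    b_start = b["start"].to_numpy()
    b_end = b["end"].to_numpy()
    b_cn = b["cn"].to_numpy()

    rows = []
    for key, (alo, ahi) in bounds_a.items():
        if key not in bounds_b:
            continue
        blo, bhi = bounds_b[key]
        pairs = []
        for i in range(alo, ahi):
            for j in range(blo, bhi):
                ov = min(a_end[i], b_end[j]) - max(a_start[i], b_start[j])
                if ov <= 0:
                    continue
                shorter = min(a_end[i] - a_start[i], b_end[j] - b_start[j])
                if ov >= min_overlap_of_shorter * shorter:
                    pairs.append((-ov, a_start[i], b_start[j], i, j))
        pairs.sort()
        used_a, used_b = set(), set()
        sample_id, chrom, state = key.split("|")
        for _, _, _, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            cs = max(a_start[i], b_start[j])
            ce = min(a_end[i], b_end[j])
            if ce <= cs:
                continue
            cn = int(a_cn[i]) if a_cn[i] == b_cn[j] else (1 if state == "del" else 3)
            rows.append((sample_id, chrom, cs, ce, state, cn))

    if not rows:
        return pd.DataFrame(columns=CALL_COLUMNS)
    out = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "state", "cn"])
    out["n_probes"] = _count_probes(probes, out["chrom"].to_numpy(), out["start"].to_numpy(), out["end"].to_numpy())
    out = out[out["n_probes"] >= 1].reset_index(drop=True)
    out["caller"] = "consensus"
    out = out.sort_values(["sample_id", "chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return out[CALL_COLUMNS]


def _group_bounds(sorted_keys: np.ndarray) -> Dict[str, Tuple[int, int]]:
    uniq, first = np.unique(sorted_keys, return_index=True)
    order = np.argsort(first)
    uniq, first = uniq[order], first[order]
    bounds = {}
    for i, k in enumerate(uniq):
        hi = first[i + 1] if i + 1 < len(first) else len(sorted_keys)
        bounds[str(k)] = (int(first[i]), int(hi))
    return bounds


def qualify_calls(calls: pd.DataFrame, thresholds: QcThresholds = None) -> pd.DataFrame:
    """Retain calls with length >= min_length and n_probes >= min_probes."""
    thresholds = thresholds or QcThresholds()
    length = calls["end"] - calls["start"]
    keep = (length >= thresholds.min_length) & (calls["n_probes"] >= thresholds.min_probes)
    return calls[keep].reset_index(drop=True)


def prune_samples(
    samples: pd.DataFrame,
    raw_calls: pd.DataFrame,
    thresholds: QcThresholds = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove poor-quality samples by intensity metrics and raw call load.

    Per dataset and per metric (LRRSD, absWF, BAF drift) a single-pass
    mean +/- ``sd_multiplier`` x SD rule flags outliers; zero-variance
    datasets flag none. Then samples exceeding the raw CNV basepair or
    raw call-count caps are removed cohort-wide. The removal log has one
    row per (sample, triggered reason).
    """
    thresholds = thresholds or QcThresholds()
    log_rows = []

    for ds, grp in samples.groupby("dataset", sort=True):
        for metric, reason in (("lrrsd", "lrrsd_sd"), ("abswf", "abswf_sd"), ("baf_drift", "baf_drift_sd")):
            vals = grp[metric].to_numpy(float)
            if len(vals) < 2:
                continue
            mu = vals.mean()
            sd = vals.std(ddof=1)
            if sd == 0.0:
                continue
            out = np.abs(vals - mu) > thresholds.sd_multiplier * sd
            for sid, v in zip(grp["sample_id"].to_numpy()[out], vals[out]):
                log_rows.append((sid, ds, reason, float(v)))

    per_sample = raw_calls.assign(bp=raw_calls["end"] - raw_calls["start"]).groupby("sample_id").agg(
        n_calls=("bp", "size"), total_bp=("bp", "sum")
    )
    counts = per_sample["n_calls"].astype(float).reindex(samples["sample_id"]).fillna(0.0).to_numpy()
    bps = per_sample["total_bp"].astype(float).reindex(samples["sample_id"]).fillna(0.0).to_numpy()
    ds_arr = samples["dataset"].to_numpy()
    sid_arr = samples["sample_id"].to_numpy()
    for i in np.flatnonzero(bps > thresholds.max_raw_bp):
        log_rows.append((sid_arr[i], ds_arr[i], "raw_call_bp", float(bps[i])))
    for i in np.flatnonzero(counts > thresholds.max_raw_calls):
        log_rows.append((sid_arr[i], ds_arr[i], "raw_call_count", float(counts[i])))

    log = pd.DataFrame(log_rows, columns=["sample_id", "dataset", "reason", "value"])
    log = log.sort_values(["sample_id", "reason"], kind="stable").reset_index(drop=True)
    removed = set(log["sample_id"])
    kept = samples[~samples["sample_id"].isin(removed)].reset_index(drop=True)
    return kept, log
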