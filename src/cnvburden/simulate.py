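"""Synthetic cohort generator: genome, annotations, samples, two-caller CNV calls.

The generator emulates a two-country (SWE/NOR) case/control genotype-array
cohort: several genotyping datasets, rare CNV loci (>=30 kb, <1% carrier
frequency) called independently by two callers with boundary jitter and
dropout, a planted case excess concentrated in deletions of
loss-of-function-intolerant (pLI > 0.5) genes, intensity-metric outlier
samples, and optional dataset-specific small-deletion artifact pileups.
Every emitted caller call traces back to a truth record, so downstream
stages can be validated against a known ground truth.

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.SeedSequence`` children, so identical configs reproduce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .intervals import GenomeIntervals, IntervalSet
from .io_formats import (
    AnnotationBundle,
    CALL_COLUMNS,
    write_baf,
    write_penncnv,
    write_quantisnp,
    write_samples,
    write_tracks,
)

__all__ = [
    "TruthTable",
    "SimulatedCohort",
    "simulate_annotations",
    "simulate_cohort",
    "simulate_calls",
    "simulate_all",
    "write_inputs",
    "STRATA",
]

STRATA = (("SWE", "M"), ("SWE", "F"), ("NOR", "M"), ("NOR", "F"))

_STAGE_ANNOT, _STAGE_COHORT, _STAGE_CALLS, _STAGE_CLINICAL = 1, 2, 3, 4


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def null_sim_config(seed: int, n_cases: int = 1000, n_controls: int = 1000, **overrides) -> SimConfig:
    """A strictly null cohort configuration for type-I calibration.

    All planted odds ratios are 1, artifact clusters are off, and the
    case shift on LRRSD is zeroed (with the call-rate/LRRSD coupling
    active, a case-shifted LRRSD would be a mediated case effect on
    call counts, i.e. not a null).
    """
    kw = dict(
        seed=seed, n_cases=n_cases, n_controls=n_controls,
        planted_or_del_pli=1.0, planted_or_dup=1.0,
        artifact_clusters=0, lrrsd_case_shift=0.0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class TruthTable:
    """Ground truth: per-sample true CNVs and per-locus planted effects.

    ``calls`` has one row per (locus, carrier) plus rows for injected
    outlier-noise calls and per-caller false positives; flags
    ``planted_risk``, ``artifact``, ``noise`` and ``false_positive``
    identify each origin. ``loci`` records every generated locus with
    its frequency class and planted odds ratio.
    """

    loci: pd.DataFrame
    calls: pd.DataFrame

    def planted_carrier_counts(self, state: Optional[str] = None) -> pd.Series:
        sel = self.calls[self.calls["planted_risk"]]
        if state is not None:
            sel = sel[sel["state"] == state]
        return sel.groupby("sample_id")["locus_id"].nunique()


@dataclass
class SimulatedCohort:
    config: SimConfig
    samples: pd.DataFrame
    bundle: AnnotationBundle
    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    baf: pd.DataFrame
    truth: TruthTable


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng, chrom_size: int, lengths: np.ndarray) -> np.ndarray:
    """Place intervals of given lengths without overlap; returns starts."""
    lengths = np.asarray(lengths, dtype=np.int64)
    free = chrom_size - lengths.sum()
    if free <= lengths.size:
        raise ValueError("chromosome too small for requested gene load")
    gaps = rng.multinomial(free - lengths.size, np.full(lengths.size + 1, 1.0 / (lengths.size + 1)))
    starts = np.empty(lengths.size, dtype=np.int64)
    pos = 0
    for i in range(lengths.size):
        pos += gaps[i] + 1
        starts[i] = pos
        pos += lengths[i]
    return starts


def _random_track(rng, chrom_sizes, n_per_chrom_mean, len_lo, len_hi) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        n = rng.poisson(n_per_chrom_mean)
        for _ in range(n):
            ln = int(rng.uniform(len_lo, len_hi))
            start = int(rng.integers(0, max(size - ln, 1)))
            rows.append((chrom, start, start + ln))
    if not rows:
        # guarantee every track is non-empty so schema checks are exercised
        chrom, size = next(iter(chrom_sizes.items()))
        ln = int((len_lo + len_hi) // 2)
        rows.append((chrom, size // 3, size // 3 + ln))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_annotations(config: SimConfig, margin_bp: int = 500_000) -> AnnotationBundle:
    """Generate the annotation bundle: tracks, genes, constraint, probes."""
    config.validate()
    rng = _rng(config, _STAGE_ANNOT)
    chrom_sizes = {str(k): int(v) for k, v in config.chrom_sizes.items()}
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)

    # probe map: roughly exponential inter-probe spacing
    probes: Dict[str, np.ndarray] = {}
    for c, size in chrom_sizes.items():
        n_expect = int(size / config.probe_spacing_bp * 1.2) + 10
        gaps = rng.exponential(config.probe_spacing_bp, size=n_expect)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        probes[c] = pos[pos < size]

    # genes: non-overlapping, allocated across chromosomes by size
    n_per_chrom = np.maximum(1, np.round(config.n_genes * sizes / sizes.sum()).astype(int))
    gene_rows = []
    gid = 0
    for c, n_g in zip(chroms, n_per_chrom):
        lengths = np.clip(
            rng.lognormal(config.gene_length_mu, config.gene_length_sigma, n_g), 5_000, 500_000
        ).astype(np.int64)
        starts = _place_nonoverlapping(rng, chrom_sizes[c], lengths)
        for s, ln in zip(starts, lengths):
            gene_rows.append((f"G{gid:05d}", c, int(s), int(s + ln)))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    n_genes = len(genes)

    # constraint-model probabilities: bimodal pLI, pNull concentrated in
    # low-pLI genes, with pli + pnull <= 1
    high = rng.random(n_genes) < 0.25
    pli = np.where(high, rng.beta(5, 1, n_genes), rng.beta(1, 8, n_genes))
    pnull = (1.0 - pli) * rng.beta(4, 2, n_genes)
    genes["pli"] = np.round(pli, 6)
    genes["pnull"] = np.round(pnull, 6)
    genes["haplosensitive"] = (pli > 0.85) | (rng.random(n_genes) < 0.02)
    genes["triplosensitive"] = rng.random(n_genes) < 0.03

    # genesets: NDD flags (pLI-weighted draw) plus random pathway-style sets
    n_ndd = int(np.ceil(config.ndd_fraction * n_genes))
    w = pli + 0.05
    ndd_idx = rng.choice(n_genes, size=n_ndd, replace=False, p=w / w.sum())
    kendall_idx = rng.choice(ndd_idx, size=max(1, n_ndd // 2), replace=False)
    memberships = [set() for _ in range(n_genes)]
    for i in ndd_idx:
        memberships[i].add("NDD_fu")
    for i in kendall_idx:
        memberships[i].add("NDD_kendall")
    pathway_ids = [f"GO_{i:03d}" for i in range(12)] + [f"GTEX_brain_{i}" for i in range(3)]
    for ps in pathway_ids:
        size_ps = max(3, int(rng.uniform(0.03, 0.10) * n_genes))
        for i in rng.choice(n_genes, size=size_ps, replace=False):
            memberships[i].add(ps)
    genes["genesets"] = [",".join(sorted(m)) for m in memberships]

    # exclusion tracks
    tracks: Dict[str, GenomeIntervals] = {}
    telo, centro = [], []
    for c, size in chrom_sizes.items():
        m = min(margin_bp, size // 4)
        telo.append((c, 0, m))
        telo.append((c, size - m, size))
        centro.append((c, size // 2 - m, size // 2 + m))
    tracks["telomere_margin"] = GenomeIntervals.from_frame(
        pd.DataFrame(telo, columns=["chrom", "start", "end"])
    )
    tracks["centromere_margin"] = GenomeIntervals.from_frame(
        pd.DataFrame(centro, columns=["chrom", "start", "end"])
    )
    tracks["segdup"] = GenomeIntervals.from_frame(_random_track(rng, chrom_sizes, 3, 50_000, 300_000))
    tracks["repeat"] = GenomeIntervals.from_frame(_random_track(rng, chrom_sizes, 20, 2_000, 30_000))
    tracks["polyN"] = GenomeIntervals.from_frame(_random_track(rng, chrom_sizes, 2, 10_000, 100_000))
    tracks["ig_tcr"] = GenomeIntervals.from_frame(_random_track(rng, chrom_sizes, 0.4, 50_000, 150_000))
    tracks["ebv_artifact"] = GenomeIntervals.from_frame(_random_track(rng, chrom_sizes, 0.4, 40_000, 120_000))

    # per-window constraint scores: base Gaussian + pLI-weighted gene bonus
    constraint: Dict[str, tuple] = {}
    w_bp = int(config.constraint_window_bp)
    for ci, c in enumerate(chroms):
        size = chrom_sizes[c]
        n_w = size // w_bp
        starts = np.arange(n_w, dtype=np.int64) * w_bp
        ends = starts + w_bp
        scores = rng.normal(config.constraint_mean, 1.0, n_w)
        if config.constraint_gene_bonus != 0.0:
            gsub = genes[genes["chrom"] == c]
            g_starts = gsub["start"].to_numpy()
            g_ends = gsub["end"].to_numpy()
            g_pli = gsub["pli"].to_numpy()
            if g_starts.size:
                # window midpoint inside gene (genes are non-overlapping, sorted)
                mids = starts + w_bp // 2
                j = np.searchsorted(g_starts, mids, side="right") - 1
                j = np.clip(j, 0, g_starts.size - 1)
                inside = (mids >= g_starts[j]) & (mids < g_ends[j])
                scores[inside] += config.constraint_gene_bonus * g_pli[j[inside]]
        constraint[c] = (starts, ends, scores)

    # external SV frequency track (gnomAD-like stand-in)
    sv_rows = []
    pop_cols = ["freq_global", "freq_pop1", "freq_pop2", "freq_pop3"]
    for i in range(config.n_sv_track_records):
        ci = rng.integers(0, len(chroms))
        c = chroms[ci]
        ln = int(rng.uniform(30_000, 400_000))
        start = int(rng.integers(0, max(chrom_sizes[c] - ln, 1)))
        state = "del" if rng.random() < 0.5 else "dup"
        if rng.random() < 0.33:
            fg = rng.uniform(0.01, 0.08)
        else:
            fg = rng.uniform(1e-4, 0.009)
        freqs = fg * np.exp(rng.normal(0.0, 0.3, 3))
        sv_rows.append((c, start, start + ln, state, fg, *np.clip(freqs, 0, 0.5)))
    sv_freq = pd.DataFrame(sv_rows, columns=["chrom", "start", "end", "state", *pop_cols[:1], *pop_cols[1:]])

    geneset_ids = tuple(sorted({g for gs in genes["genesets"] for g in str(gs).split(",") if g}))
    bundle = AnnotationBundle(
        chrom_sizes=chrom_sizes,
        tracks=tracks,
        genes=genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True),
        constraint=constraint,
        probes=probes,
        sv_freq=sv_freq,
        geneset_ids=geneset_ids,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    raw = n * probs
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the sample sheet (no CNV-dependent fields yet).

    Cases and controls are allocated deterministically across the four
    country x sex strata by largest-remainder apportionment; a stratum
    that receives zero samples in either phenotype group is a
    configuration error.
    """
    config.validate()
    rng = _rng(config, _STAGE_COHORT)
    k = config.n_datasets
    ds_names = [f"D{i + 1}" for i in range(k)]
    n_swe_ds = max(1, int(np.ceil(k * config.swe_fraction)))
    ds_country = {d: ("SWE" if i < n_swe_ds else "NOR") for i, d in enumerate(ds_names)}

    rows = []
    for is_case, n_grp, female_rate in (
        (True, config.n_cases, config.case_female_rate),
        (False, config.n_controls, config.control_female_rate),
    ):
        probs = []
        for country, sex in STRATA:
            p_country = config.swe_fraction if country == "SWE" else 1.0 - config.swe_fraction
            p_sex = female_rate if sex == "F" else 1.0 - female_rate
            probs.append(p_country * p_sex)
        counts = _largest_remainder(n_grp, np.array(probs))
        if (counts == 0).any():
            empty = [f"{c}_{s}" for (c, s), n in zip(STRATA, counts) if n == 0]
            raise ValueError(f"zero {'cases' if is_case else 'controls'} in strata {empty}; "
                             "increase sample size or adjust composition")
        for (country, sex), n_cs in zip(STRATA, counts):
            ds_pool = [d for d in ds_names if ds_country[d] == country]
            if not ds_pool:
                ds_pool = ds_names
            w = rng.dirichlet(np.full(len(ds_pool), 2.0))
            ds_assign = rng.choice(len(ds_pool), size=n_cs, p=w)
            for j in range(n_cs):
                rows.append((is_case, country, sex, ds_pool[ds_assign[j]]))

    samples = pd.DataFrame(rows, columns=["is_case", "country", "sex", "dataset"])
    n = len(samples)
    samples.insert(0, "sample_id", [f"S{i:06d}" for i in range(n)])

    pcs = rng.normal(0.0, 1.0, size=(n, 20))
    is_swe = (samples["country"] == "SWE").to_numpy()
    pcs[:, 4] += np.where(is_swe, config.pc5_country_shift / 2, -config.pc5_country_shift / 2)
    ds_offsets = {d: rng.normal(0.0, config.pc7_dataset_sd) for d in ds_names}
    pcs[:, 6] += samples["dataset"].map(ds_offsets).to_numpy()
    for i in range(20):
        samples[f"pc{i + 1}"] = np.round(pcs[:, i], 8)

    is_case_arr = samples["is_case"].to_numpy()
    lrrsd = rng.lognormal(config.lrrsd_mu + config.lrrsd_case_shift * is_case_arr, config.lrrsd_sigma, n)
    abswf = rng.lognormal(config.abswf_mu, config.abswf_sigma, n)
    baf_drift = rng.lognormal(config.baf_drift_mu, config.baf_drift_sigma, n)
    is_outlier = rng.random(n) < config.outlier_fraction
    lrrsd = np.where(is_outlier, lrrsd * config.outlier_lrrsd_factor, lrrsd)
    abswf = np.where(is_outlier, abswf * 2.0, abswf)
    samples["lrrsd"] = np.round(lrrsd, 8)
    samples["abswf"] = np.round(abswf, 8)
    samples["baf_drift"] = np.round(baf_drift, 10)
    samples["is_outlier"] = is_outlier

    for col in ("prs_height", "prs_ocd", "prs_xdx"):
        samples[col] = np.round(rng.normal(0.0, 1.0, n), 8)

    # clinical fields are filled in after carrier status is known
    for flag in config.comorbid_base_rates:
        samples[f"comorbid_{flag}"] = False
    samples["ybocs_pre"] = np.nan
    samples["ybocs_post"] = np.nan
    samples["has_clinical"] = False
    samples["stratum"] = samples["country"] + "_" + samples["sex"]
    return samples


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

_FREQ_CLASS_MEANS = {"singleton": None, "rare": (2e-4, 1e-3), "low": (1e-3, 9.5e-3), "common": (1e-2, 5e-2)}


def _avoids_exclusion(bundle: AnnotationBundle, chrom: str, start: int, end: int) -> bool:
    return all(bundle.tracks[t].get(chrom).coverage(start, end)[0] == 0 for t in bundle.tracks)


def simulate_calls(
    config: SimConfig, samples: pd.DataFrame, bundle: AnnotationBundle
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate truth CNVs and the two jittered caller callsets.

    Returns ``(calls_a, calls_b, baf, truth)`` where ``calls_a`` is the
    PennCNV-style callset, ``calls_b`` the QuantiSNP-like callset, and
    ``baf`` per-probe BAF/LRR values covering every emitted call region.
    """
    config.validate()
    rng = _rng(config, _STAGE_CALLS)
    chroms = list(bundle.chrom_sizes)
    for c in chroms:
        if c not in bundle.probes or bundle.probes[c].size == 0:
            raise ValueError(f"probe map missing for chromosome {c}")
    sizes = np.array([bundle.chrom_sizes[c] for c in chroms], dtype=np.int64)
    p_chrom = sizes / sizes.sum()
    n = len(samples)
    is_case = samples["is_case"].to_numpy()
    sample_ids = samples["sample_id"].to_numpy()

    # ---- background locus pool ----
    spec = config.freq_spectrum
    class_names = ["singleton", "rare", "low", "common"]
    weights = np.array([spec.get(c, 0.0) for c in class_names])
    mean_f = (
        weights[0] * (1.0 / n)
        + weights[1] * np.mean(_FREQ_CLASS_MEANS["rare"])
        + weights[2] * np.mean(_FREQ_CLASS_MEANS["low"])
        + weights[3] * np.mean(_FREQ_CLASS_MEANS["common"])
    )
    n_loci = max(1, int(np.ceil(config.background_cnv_rate / max(mean_f, 1e-12))))

    loci_rows = []  # locus_id, chrom, start, end, state, class, freq, planted_or, planted, artifact
    cls_draw = rng.choice(4, size=n_loci, p=weights)
    chrom_draw = rng.choice(len(chroms), size=n_loci, p=p_chrom)
    lengths = np.clip(rng.lognormal(np.log(70_000), 0.8, n_loci), 10_000, 3_000_000).astype(np.int64)
    states = np.where(rng.random(n_loci) < 0.5, "del", "dup")
    for i in range(n_loci):
        c = chroms[chrom_draw[i]]
        ln = int(min(lengths[i], bundle.chrom_sizes[c] - 2))
        start = int(rng.integers(0, bundle.chrom_sizes[c] - ln))
        cname = class_names[cls_draw[i]]
        if cname == "singleton":
            f = 1.0 / n
        else:
            lo, hi = _FREQ_CLASS_MEANS[cname]
            f = rng.uniform(lo, hi)
        loci_rows.append((f"L{i:05d}", c, start, start + ln, states[i], cname, f, 1.0, False, False))

    # ---- planted risk loci ----
    genes = bundle.genes
    next_id = n_loci

    def _plant(gene_rows: pd.DataFrame, n_pl: int, state: str, theta: float, tag: str):
        nonlocal next_id
        if n_pl == 0:
            return
        if len(gene_rows) == 0:
            raise ValueError(f"no eligible genes in annotation for planted {tag} loci")
        pick = rng.choice(len(gene_rows), size=min(n_pl, len(gene_rows)), replace=False)
        for j in pick:
            g = gene_rows.iloc[j]
            pad_l = int(rng.uniform(10_000, 50_000))
            pad_r = int(rng.uniform(10_000, 50_000))
            start = max(0, int(g["start"]) - pad_l)
            end = min(bundle.chrom_sizes[g["chrom"]], int(g["end"]) + pad_r)
            f = rng.uniform(*config.planted_freq_range)
            loci_rows.append((f"P{next_id:05d}", g["chrom"], start, end, state, "planted", f, theta, True, False))
            next_id += 1

    _plant(genes[genes["pli"] > 0.5], config.n_planted_del_loci, "del", config.planted_or_del_pli, "deletion")
    _plant(genes, config.n_planted_dup_loci, "dup", config.planted_or_dup, "duplication")

    # ---- artifact clusters: small deletions confined to one dataset ----
    artifact_loci = []
    if config.artifact_clusters > 0:
        ds_names = sorted(samples["dataset"].unique())
        if config.artifact_dataset is not None:
            cluster_ds = [config.artifact_dataset] * config.artifact_clusters
        elif config.artifact_all_one_dataset:
            # batch artifacts concentrate in the largest genotyping batch
            d = samples["dataset"].value_counts().sort_index().idxmax()
            cluster_ds = [str(d)] * config.artifact_clusters
        else:
            cluster_ds = [ds_names[int(rng.integers(0, len(ds_names)))] for _ in range(config.artifact_clusters)]
        base = config.artifact_calls_total // config.artifact_clusters
        extra = config.artifact_calls_total - base * config.artifact_clusters
        for ci in range(config.artifact_clusters):
            n_carriers = base + (1 if ci < extra else 0)
            for _ in range(200):
                c = chroms[int(rng.choice(len(chroms), p=p_chrom))]
                ln = int(rng.uniform(30_000, 100_000))
                start = int(rng.integers(0, bundle.chrom_sizes[c] - ln))
                if _avoids_exclusion(bundle, c, start, start + ln):
                    break
            loci_rows.append((f"A{next_id:05d}", c, start, start + ln, "del", "artifact", np.nan, 1.0, False, True))
            artifact_loci.append((f"A{next_id:05d}", cluster_ds[ci], n_carriers))
            next_id += 1

    loci = pd.DataFrame(
        loci_rows,
        columns=["locus_id", "chrom", "start", "end", "state", "freq_class", "freq", "planted_or", "planted_risk", "artifact"],
    )

    # ---- carrier assignment ----
    # technical covariates modulate the background call rate (PC7 batch
    # structure and log-LRRSD noise coupling); normalized to mean 1 so the
    # cohort-level rate stays at background_cnv_rate
    log_mult = (
        config.pc7_callrate_beta * samples["pc7"].to_numpy(float)
        + config.lrrsd_callrate_beta * (np.log(samples["lrrsd"].to_numpy(float)) - config.lrrsd_mu)
    )
    rate_mult = np.exp(log_mult)
    rate_mult /= rate_mult.mean()
    max_rare_carriers = max(1, int(np.ceil(0.01 * n)) - 1)
    call_sample_idx = []
    call_locus_idx = []
    artifact_by_locus = {lid: (ds, nc) for lid, ds, nc in artifact_loci}
    ds_arr = samples["dataset"].to_numpy()
    for li, row in enumerate(loci.itertuples(index=False)):
        if row.artifact:
            ds, nc = artifact_by_locus[row.locus_id]
            in_ds = np.flatnonzero(ds_arr == ds)
            if in_ds.size == 0:
                raise ValueError(f"artifact dataset {ds} has no samples")
            # all carriers from the dataset's majority phenotype class
            cls_case = is_case[in_ds].sum() >= (~is_case[in_ds]).sum()
            pool = in_ds[is_case[in_ds] == cls_case]
            carriers = rng.choice(pool, size=min(nc, pool.size), replace=False)
        elif row.freq_class == "singleton":
            carriers = rng.integers(0, n, size=1)
        else:
            f = row.freq
            theta = row.planted_or
            p_ctrl = f
            p_case = theta * f / (1.0 - f + theta * f)
            p = np.where(is_case, p_case, p_ctrl)
            if not row.planted_risk:
                p = np.clip(p * rate_mult, 0.0, 0.5)
            carriers = np.flatnonzero(rng.random(n) < p)
            if row.freq_class in ("rare", "low") and carriers.size > max_rare_carriers:
                carriers = rng.choice(carriers, size=max_rare_carriers, replace=False)
        call_sample_idx.append(carriers)
        call_locus_idx.append(np.full(carriers.size, li, dtype=np.int64))

    sample_idx = np.concatenate(call_sample_idx) if call_sample_idx else np.empty(0, dtype=np.int64)
    locus_idx = np.concatenate(call_locus_idx) if call_locus_idx else np.empty(0, dtype=np.int64)

    truth_calls = pd.DataFrame(
        {
            "sample_id": sample_ids[sample_idx],
            "locus_id": loci["locus_id"].to_numpy()[locus_idx],
            "chrom": loci["chrom"].to_numpy()[locus_idx],
            "start": loci["start"].to_numpy()[locus_idx],
            "end": loci["end"].to_numpy()[locus_idx],
            "state": loci["state"].to_numpy()[locus_idx],
            "planted_risk": loci["planted_risk"].to_numpy()[locus_idx],
            "artifact": loci["artifact"].to_numpy()[locus_idx],
        }
    )
    truth_calls["noise"] = False
    truth_calls["false_positive"] = False

    # ---- outlier noise calls ----
    noise_rows = []
    out_idx = np.flatnonzero(samples["is_outlier"].to_numpy())
    for si in out_idx:
        n_extra = rng.poisson(config.outlier_extra_calls)
        for _ in range(n_extra):
            c = chroms[int(rng.choice(len(chroms), p=p_chrom))]
            ln = int(rng.uniform(10_000, 80_000))
            start = int(rng.integers(0, bundle.chrom_sizes[c] - ln))
            st = "del" if rng.random() < 0.5 else "dup"
            noise_rows.append((sample_ids[si], "noise", c, start, start + ln, st, False, False, True, False))
    if noise_rows:
        truth_calls = pd.concat(
            [truth_calls, pd.DataFrame(noise_rows, columns=truth_calls.columns)], ignore_index=True
        )

    # copy numbers: occasional homozygous deletions / double duplications
    st = truth_calls["state"].to_numpy()
    cn = np.where(st == "del", 1, 3)
    hom = rng.random(len(truth_calls)) < 0.05
    cn = np.where(hom & (st == "del"), 0, cn)
    cn = np.where(hom & (st == "dup"), 4, cn)
    truth_calls["cn"] = cn

    # ---- false positives (single-caller by construction) ----
    fp_frames = []
    for caller in ("A", "B"):
        n_fp = rng.poisson(config.fp_rate * n)
        if n_fp == 0:
            continue
        si = rng.integers(0, n, size=n_fp)
        ci = rng.choice(len(chroms), size=n_fp, p=p_chrom)
        ln = rng.uniform(10_000, 200_000, size=n_fp).astype(np.int64)
        st_fp = np.where(rng.random(n_fp) < 0.5, "del", "dup")
        starts = np.array(
            [rng.integers(0, bundle.chrom_sizes[chroms[c]] - l) for c, l in zip(ci, ln)], dtype=np.int64
        )
        fp_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[si],
                    "locus_id": [f"FP_{caller}_{i}" for i in range(n_fp)],
                    "chrom": [chroms[c] for c in ci],
                    "start": starts,
                    "end": starts + ln,
                    "state": st_fp,
                    "planted_risk": False,
                    "artifact": False,
                    "noise": False,
                    "false_positive": True,
                    "cn": np.where(st_fp == "del", 1, 3),
                    "fp_caller": caller,
                }
            )
        )
    truth_calls["fp_caller"] = ""
    if fp_frames:
        truth_calls = pd.concat([truth_calls] + fp_frames, ignore_index=True)

    truth_calls = truth_calls.sort_values(
        ["sample_id", "chrom", "start", "end", "locus_id"], kind="stable"
    ).reset_index(drop=True)

    # ---- caller emission with jitter and dropout ----
    emitted = {}
    m = len(truth_calls)
    t_start = truth_calls["start"].to_numpy()
    t_end = truth_calls["end"].to_numpy()
    t_chrom = truth_calls["chrom"].to_numpy()
    chrom_size_arr = truth_calls["chrom"].map(bundle.chrom_sizes).to_numpy(np.int64)
    fp_caller = truth_calls["fp_caller"].to_numpy()
    region_lo = t_start.copy()
    region_hi = t_end.copy()
    for caller in ("A", "B"):
        keep = rng.random(m) >= config.caller_dropout
        keep &= (fp_caller == "") | (fp_caller == caller)
        js = np.round(rng.normal(0.0, config.caller_jitter_bp, m)).astype(np.int64)
        je = np.round(rng.normal(0.0, config.caller_jitter_bp, m)).astype(np.int64)
        cs = np.clip(t_start + js, 0, chrom_size_arr - 2)
        ce = np.clip(t_end + je, 1, chrom_size_arr - 1)
        ce = np.maximum(ce, cs + 1_000)
        region_lo = np.minimum(region_lo, np.where(keep, cs, region_lo))
        region_hi = np.maximum(region_hi, np.where(keep, ce, region_hi))
        # recount probes on jittered coordinates
        n_probes = np.zeros(m, dtype=np.int64)
        for c in chroms:
            msk = t_chrom == c
            pos = bundle.probes[c]
            n_probes[msk] = np.searchsorted(pos, ce[msk], side="left") - np.searchsorted(pos, cs[msk], side="left")
        keep &= n_probes >= 1
        emitted[caller] = pd.DataFrame(
            {
                "sample_id": truth_calls["sample_id"].to_numpy()[keep],
                "chrom": t_chrom[keep],
                "start": cs[keep],
                "end": ce[keep],
                "state": truth_calls["state"].to_numpy()[keep],
                "cn": truth_calls["cn"].to_numpy()[keep],
                "n_probes": n_probes[keep],
                "caller": caller,
                "truth_row": np.flatnonzero(keep),
            }
        )
        truth_calls[f"emitted_{caller}"] = keep

    # ---- per-probe BAF/LRR over every emitted call region ----
    emitted_any = truth_calls["emitted_A"].to_numpy() | truth_calls["emitted_B"].to_numpy()
    lrrsd_map = samples.set_index("sample_id")["lrrsd"]
    baf_parts = []
    for c in chroms:
        msk = emitted_any & (t_chrom == c)
        if not msk.any():
            continue
        pos = bundle.probes[c]
        lo = np.searchsorted(pos, region_lo[msk], side="left")
        hi = np.searchsorted(pos, region_hi[msk], side="left")
        counts = hi - lo
        good = counts > 0
        lo, hi, counts = lo[good], hi[good], counts[good]
        rows_idx = np.flatnonzero(msk)[good]
        total = int(counts.sum())
        if total == 0:
            continue
        start_rep = np.repeat(lo, counts)
        offs = np.arange(total) - np.repeat(np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
        p_idx = start_rep + offs
        row_rep = np.repeat(rows_idx, counts)
        cn_rep = truth_calls["cn"].to_numpy()[row_rep]
        is_fp = truth_calls["false_positive"].to_numpy()[row_rep]
        baf = _draw_baf(rng, cn_rep, is_fp, config.baf_noise_sd)
        state_rep = truth_calls["state"].to_numpy()[row_rep]
        shift = np.where(is_fp, 0.0, np.where(state_rep == "del", config.lrr_del_shift, config.lrr_dup_shift))
        sample_rep = truth_calls["sample_id"].to_numpy()[row_rep]
        sd = lrrsd_map.reindex(sample_rep).to_numpy()
        lrr = rng.normal(shift, sd)
        baf_parts.append(
            pd.DataFrame(
                {"sample_id": sample_rep, "chrom": c, "pos": pos[p_idx], "baf": np.round(baf, 5),
                 "lrr": np.round(lrr, 5)}
            )
        )
    baf_df = (
        pd.concat(baf_parts, ignore_index=True)
        if baf_parts
        else pd.DataFrame(columns=["sample_id", "chrom", "pos", "baf", "lrr"])
    )
    baf_df = baf_df.drop_duplicates(["sample_id", "chrom", "pos"]).sort_values(
        ["sample_id", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    calls_a = emitted["A"].drop(columns="truth_row").sort_values(
        ["sample_id", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)[CALL_COLUMNS]
    calls_b = emitted["B"].drop(columns="truth_row").sort_values(
        ["sample_id", "chrom", "start"], kind="stable"
    ).reset_index(drop=True)[CALL_COLUMNS]
    truth = TruthTable(loci=loci, calls=truth_calls)
    return calls_a, calls_b, baf_df, truth


def _draw_baf(rng, cn: np.ndarray, is_fp: np.ndarray, noise_sd: float) -> np.ndarray:
    """Per-probe BAF draws given copy number (FP calls are copy-neutral)."""
    n = cn.size
    out = np.empty(n, dtype=float)
    u = rng.random(n)
    # deletion (CN 0/1): homozygous bands only
    mask = ~is_fp & (cn <= 1)
    out[mask] = np.where(u[mask] < 0.5, 0.0, 1.0)
    # CN=3: bands at 0, 1/3, 2/3, 1 (binomial(3, 1/2) genotypes)
    mask = ~is_fp & (cn == 3)
    b = np.searchsorted(np.cumsum([1 / 8, 3 / 8, 3 / 8, 1 / 8]), u[mask], side="right")
    out[mask] = np.array([0.0, 1 / 3, 2 / 3, 1.0])[np.clip(b, 0, 3)]
    # CN=4: bands at 0, 1/4, 1/2, 3/4, 1
    mask = ~is_fp & (cn == 4)
    b = np.searchsorted(np.cumsum([1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16]), u[mask], side="right")
    out[mask] = np.array([0.0, 0.25, 0.5, 0.75, 1.0])[np.clip(b, 0, 4)]
    # copy-neutral false positives: het band present
    b = np.searchsorted(np.cumsum([0.3, 0.4, 0.3]), u[is_fp], side="right")
    out[is_fp] = np.array([0.0, 0.5, 1.0])[np.clip(b, 0, 2)]
    return np.clip(out + rng.normal(0.0, noise_sd, n), 0.0, 1.0)


# ---------------------------------------------------------------------------
# clinical / PRS planting (needs carrier status)
# ---------------------------------------------------------------------------

def _true_carriers(truth: TruthTable, bundle: AnnotationBundle, state: str, gene_mask: pd.Series) -> set:
    """Samples whose true (non-noise, non-FP) CNVs of ``state`` hit a masked gene."""
    genes = bundle.genes[gene_mask.to_numpy()]
    if len(genes) == 0:
        return set()
    tr = truth.calls
    tr = tr[(tr["state"] == state) & ~tr["noise"] & ~tr["false_positive"]]
    carriers = set()
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for c, grp in tr.groupby("chrom"):
        g = by_chrom.get(c)
        if g is None:
            continue
        iv = IntervalSet(g["start"].to_numpy(), g["end"].to_numpy())
        hit = iv.overlaps(grp["start"].to_numpy(), grp["end"].to_numpy())
        carriers.update(grp["sample_id"].to_numpy()[hit])
    return carriers


def deleterious_true_carriers(truth: TruthTable, bundle: AnnotationBundle, state: str = "del") -> set:
    """Carriers of 'deleterious' CNVs: pLI>0.995 or NDD-geneset genes."""
    g = bundle.genes
    mask = (g["pli"] > 0.995) | g["genesets"].str.contains("NDD_fu") | g["genesets"].str.contains("NDD_kendall")
    return _true_carriers(truth, bundle, state, mask)


def assign_clinical(
    config: SimConfig, samples: pd.DataFrame, truth: TruthTable, bundle: AnnotationBundle
) -> pd.DataFrame:
    """Fill clinical fields and apply the PRS carrier shift in place."""
    rng = _rng(config, _STAGE_CLINICAL)
    samples = samples.copy()
    g = bundle.genes
    ndd_mask = g["genesets"].str.contains("NDD_fu") | g["genesets"].str.contains("NDD_kendall")
    ndd_dup_carriers = _true_carriers(truth, bundle, "dup", ndd_mask)
    ndd_del_carriers = _true_carriers(truth, bundle, "del", ndd_mask)
    del_carriers = deleterious_true_carriers(truth, bundle, "del")

    sid = samples["sample_id"]
    is_case = samples["is_case"].to_numpy()
    # PRS shift for deleterious-deletion carriers
    shift = sid.isin(del_carriers).to_numpy() * config.prs_carrier_shift
    samples["prs_xdx"] = np.round(samples["prs_xdx"].to_numpy() + shift, 8)

    # clinical subset: Swedish cases (detailed phenotyping arm)
    eligible = is_case & (samples["country"] == "SWE").to_numpy()
    n_clin = int(round(config.clinical_fraction * is_case.sum()))
    elig_idx = np.flatnonzero(eligible)
    chosen = elig_idx[: n_clin] if elig_idx.size <= n_clin else rng.choice(elig_idx, size=n_clin, replace=False)
    has_clin = np.zeros(len(samples), dtype=bool)
    has_clin[chosen] = True
    samples["has_clinical"] = has_clin

    is_dup_carrier = sid.isin(ndd_dup_carriers).to_numpy()
    for flag, base in config.comorbid_base_rates.items():
        rate = np.full(len(samples), base)
        if flag in config.comorbid_carrier_rates:
            rate = np.where(is_dup_carrier, config.comorbid_carrier_rates[flag], rate)
        samples[f"comorbid_{flag}"] = has_clin & (rng.random(len(samples)) < rate)

    pre = np.clip(np.round(rng.normal(config.ybocs_pre_mean, config.ybocs_pre_sd, len(samples))), 16, 40)
    is_del_carrier = sid.isin(ndd_del_carriers).to_numpy()
    mu = np.where(is_del_carrier, config.improvement_ndd_del_carrier, config.improvement_noncarrier)
    impr = np.clip(rng.normal(mu, config.improvement_sd), -0.5, 1.0)
    post = np.clip(np.round(pre * (1.0 - impr)), 0, 40)
    samples["ybocs_pre"] = np.where(has_clin, pre, np.nan)
    samples["ybocs_post"] = np.where(has_clin, post, np.nan)
    return samples


def simulate_all(config: SimConfig) -> SimulatedCohort:
    """Run the full generator: annotations, cohort, calls, clinical fields."""
    bundle = simulate_annotations(config)
    samples = simulate_cohort(config)
    calls_a, calls_b, baf, truth = simulate_calls(config, samples, bundle)
    samples = assign_clinical(config, samples, truth, bundle)
    return SimulatedCohort(config, samples, bundle, calls_a, calls_b, baf, truth)


def write_inputs(sim: SimulatedCohort, outdir) -> None:
    """Write every pipeline input file for a simulated cohort."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_penncnv(sim.calls_a, os.path.join(outdir, "calls_a.penncnv.txt"))
    write_quantisnp(sim.calls_b, os.path.join(outdir, "calls_b.tsv"))
    write_samples(sim.samples, os.path.join(outdir, "samples.tsv"))
    write_baf(sim.baf, os.path.join(outdir, "baf.tsv"))
    write_tracks(sim.bundle, os.path.join(outdir, "tracks"))
    truth = {
        "config": dataclasses.asdict(sim.config),
        "loci": sim.truth.loci.to_dict(orient="records"),
        "calls": sim.truth.calls.to_dict(orient="records"),
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, sort_keys=True, default=str)
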