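"""Shared fixtures: a tiny hand-built annotation bundle, sample frames and
the constructed 12-call filter-cascade fixture with planted removal reasons."""

import numpy as np
import pandas as pd
import pytest

from cnvburden.intervals import GenomeIntervals
from cnvburden.io_formats import AnnotationBundle


def make_track(rows):
    return GenomeIntervals.from_frame(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture
def tiny_bundle():
    """Two-chromosome bundle with known tracks, genes, constraint, probes."""
    chrom_sizes = {"chr1": 10_000_000, "chr2": 8_000_000}
    tracks = {
        "telomere_margin": make_track([("chr1", 0, 500_000), ("chr1", 9_500_000, 10_000_000),
                                       ("chr2", 0, 500_000), ("chr2", 7_500_000, 8_000_000)]),
        "centromere_margin": make_track([("chr1", 4_500_000, 5_500_000), ("chr2", 3_500_000, 4_500_000)]),
        "polyN": make_track([("chr1", 6_000_000, 6_050_000)]),
        "segdup": make_track([("chr1", 2_000_000, 2_200_000)]),
        "repeat": make_track([("chr1", 3_000_000, 3_020_000), ("chr2", 2_000_000, 2_030_000)]),
        "ig_tcr": make_track([("chr2", 5_000_000, 5_100_000)]),
        "ebv_artifact": make_track([("chr2", 6_000_000, 6_080_000)]),
    }
    genes = pd.DataFrame(
        [
            ("G1", "chr1", 1_000_000, 1_060_000, 0.99, 0.0, True, False, "NDD_fu"),
            ("G2", "chr1", 1_200_000, 1_250_000, 0.6, 0.1, False, False, ""),
            ("G3", "chr1", 7_000_000, 7_080_000, 0.05, 0.8, False, False, ""),
            ("G4", "chr2", 1_000_000, 1_040_000, 0.999, 0.0, True, True, "NDD_fu,NDD_kendall"),
            ("G5", "chr2", 2_500_000, 2_560_000, 0.3, 0.4, False, False, "GO_001"),
        ],
        columns=["gene_id", "chrom", "start", "end", "pli", "pnull",
                 "haplosensitive", "triplosensitive", "genesets"],
    )
    constraint = {}
    for c, size in chrom_sizes.items():
        n = size // 1000
        starts = np.arange(n, dtype=np.int64) * 1000
        scores = np.zeros(n)
        constraint[c] = (starts, starts + 1000, scores)
    probes = {c: np.arange(0, size, 2000, dtype=np.int64) for c, size in chrom_sizes.items()}
    sv_freq = pd.DataFrame(
        [
            ("chr1", 8_000_000, 8_100_000, "del", 0.009, 0.015, 0.004),
            ("chr1", 8_500_000, 8_600_000, "dup", 0.009, 0.009, 0.009),
        ],
        columns=["chrom", "start", "end", "state", "freq_global", "freq_pop1", "freq_pop2"],
    )
    bundle = AnnotationBundle(
        chrom_sizes=chrom_sizes, tracks=tracks, genes=genes,
        constraint=constraint, probes=probes, sv_freq=sv_freq,
        geneset_ids=("GO_001", "NDD_fu", "NDD_kendall"),
    )
    bundle.validate()
    return bundle


def make_samples(n=100, n_cases=50, n_datasets=2, seed=0):
    """Simple balanced sample frame with all covariate columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"sample_id": [f"S{i:04d}" for i in range(n)]})
    df["is_case"] = np.arange(n) < n_cases
    df["dataset"] = [f"D{(i % n_datasets) + 1}" for i in range(n)]
    df["country"] = np.where(np.arange(n) % 4 < 2, "SWE", "NOR")
    df["sex"] = np.where(np.arange(n) % 2 == 0, "F", "M")
    df["stratum"] = df["country"] + "_" + df["sex"]
    df["lrrsd"] = rng.lognormal(-2.1, 0.15, n)
    df["abswf"] = rng.lognormal(-5.1, 0.3, n)
    df["baf_drift"] = rng.lognormal(-8.5, 0.4, n)
    for i in range(1, 21):
        df[f"pc{i}"] = rng.normal(0, 1, n)
    return df


@pytest.fixture
def samples100():
    return make_samples()


def cascade_fixture(tiny_bundle):
    """12 constructed calls with one planted removal reason each (or kept).

    Cohort: 300 samples in 2 datasets of 150 (even sample indices are
    dataset D1). Returns (calls, baf, samples, expected reason per row;
    None for kept rows).
    """
    rows = []
    expected = []

    def add(sample, chrom, start, end, state, cn, reason):
        rows.append((sample, chrom, start, end, state, cn, 30, "consensus"))
        expected.append(reason)

    # fractional-overlap track violations (interval fully inside the track)
    add("S0001", "chr1", 100_000, 160_000, "del", 1, "telomere_margin")
    add("S0003", "chr1", 4_600_000, 4_660_000, "dup", 3, "centromere_margin")
    add("S0005", "chr1", 6_000_000, 6_040_000, "del", 1, "polyN")
    add("S0007", "chr1", 2_050_000, 2_110_000, "del", 1, "segdup")
    # ~30.6% repeat overlap: call 98 kb, repeat covers 30 kb of it
    add("S0009", "chr2", 1_999_000, 2_097_000, "dup", 3, "repeat")
    # any-overlap tracks: 1 bp suffices
    add("S0011", "chr2", 5_099_000, 5_160_000, "del", 1, "ig_tcr")
    add("S0013", "chr2", 6_079_000, 6_140_000, "dup", 3, "ebv_artifact")
    # external frequency: matches chr1 del record with subpop 1.5%
    add("S0015", "chr1", 8_000_000, 8_100_000, "del", 1, "external_freq")
    # dataset frequency: two same-locus carriers, both in the 150-sample
    # dataset D1 (1.33% >= 1%) while the combined frequency is 0.67%
    add("S0002", "chr1", 3_500_000, 3_560_000, "del", 1, "dataset_freq")
    add("S0004", "chr1", 3_500_000, 3_560_000, "del", 1, "dataset_freq")
    # BAF-rejected deletion (heterozygous band present)
    add("S0017", "chr2", 2_800_000, 2_860_000, "del", 1, "baf_reject")
    # clean call, kept
    add("S0019", "chr1", 7_800_000, 7_860_000, "dup", 3, None)

    calls = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                        "state", "cn", "n_probes", "caller"])
    # BAF values: clean homozygous for everything except the planted reject
    baf_rows = []
    for r in calls.itertuples(index=False):
        pos = np.arange(r.start, r.end, 2000)
        for i, p in enumerate(pos):
            if r.sample_id == "S0017":
                baf = 0.5 if i % 2 == 0 else 0.0  # 50% het band -> reject
            elif r.state == "del":
                baf = 0.0 if i % 2 == 0 else 1.0
            else:
                baf = 1 / 3 if i % 2 == 0 else 2 / 3
            baf_rows.append((r.sample_id, r.chrom, int(p), baf, 0.0))
    baf = pd.DataFrame(baf_rows, columns=["sample_id", "chrom", "pos", "baf", "lrr"])
    samples = make_samples(300, n_cases=150)
    return calls, baf, samples, expected
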