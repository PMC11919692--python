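"""Readers and writers for every file dialect the pipeline touches.

Internal conventions
--------------------
* Coordinates are 0-based, half-open everywhere inside the package.
  Caller files (PennCNV raw text and the QuantiSNP-like TSV) are 1-based
  inclusive and are converted at this boundary.
* CNV calls travel as a pandas DataFrame with columns
  ``sample_id, chrom, start, end, state, cn, n_probes, caller``
  where ``state`` is ``"del"`` or ``"dup"`` and ``cn`` is the integer
  copy number (0/1 for deletions, 3/4 for duplications).
* Only autosomes are analyzed; sex chromosomes are rejected at read
  time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .intervals import GenomeIntervals

__all__ = [
    "CnvCall",
    "GeneModel",
    "AnnotationBundle",
    "CALL_COLUMNS",
    "TRACK_NAMES",
    "read_penncnv",
    "write_penncnv",
    "read_quantisnp",
    "write_quantisnp",
    "read_samples",
    "write_samples",
    "read_baf",
    "write_baf",
    "read_tracks",
    "write_tracks",
    "write_results",
    "read_results",
    "write_manifest",
    "calls_to_frame",
    "frame_to_calls",
    "validate_calls",
]

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "cn", "n_probes", "caller"]

TRACK_NAMES = (
    "telomere_margin",
    "centromere_margin",
    "polyN",
    "segdup",
    "repeat",
    "ig_tcr",
    "ebv_artifact",
)

_CN_TO_STATE = {0: "del", 1: "del", 3: "dup", 4: "dup"}


@dataclass(frozen=True)
class CnvCall:
    """One CNV in one sample (0-based half-open interval)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str  # "del" | "dup"
    cn: int
    n_probes: int
    caller: str = "consensus"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end <= start for {self.sample_id} {self.chrom}:{self.start}-{self.end}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if _CN_TO_STATE.get(self.cn) != self.state:
            raise ValueError(f"copy number {self.cn} inconsistent with state {self.state!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    pli: float
    pnull: float
    haplosensitive: bool = False
    triplosensitive: bool = False
    genesets: frozenset = frozenset()


@dataclass
class AnnotationBundle:
    """All annotation inputs: exclusion tracks, genes, constraint, probes."""

    chrom_sizes: Dict[str, int]
    tracks: Dict[str, GenomeIntervals]
    genes: pd.DataFrame  # gene_id, chrom, start, end, pli, pnull, haplosensitive, triplosensitive, genesets
    constraint: Dict[str, tuple]  # chrom -> (starts, ends, scores) arrays
    probes: Dict[str, np.ndarray]  # chrom -> sorted positions
    sv_freq: Optional[pd.DataFrame] = None  # chrom, start, end, state, freq_*
    geneset_ids: tuple = ()

    def validate(self) -> None:
        for name in TRACK_NAMES:
            if name not in self.tracks:
                raise ValueError(f"missing annotation track: {name}")
        for name, track in self.tracks.items():
            for chrom, iv in track.by_chrom.items():
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"track {name} on unknown chromosome {chrom}")
                if iv.starts.size and (iv.starts[0] < 0 or iv.ends[-1] > self.chrom_sizes[chrom]):
                    raise ValueError(f"track {name} out of bounds on {chrom}")
        g = self.genes
        if g["gene_id"].duplicated().any():
            dupes = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicated gene ids: {dupes[:5]}")
        bad = g[(g["pli"] < 0) | (g["pli"] > 1) | (g["pnull"] < 0) | (g["pnull"] > 1)]
        if len(bad):
            raise ValueError(f"pLI/pNull outside [0,1] for genes {bad['gene_id'].tolist()[:5]}")
        if ((g["pli"] + g["pnull"]) > 1.0 + 1e-6).any():
            raise ValueError("pli + pnull > 1 for some genes")


# ---------------------------------------------------------------------------
# caller call files
# ---------------------------------------------------------------------------

def _check_autosome(chrom: str, where: str) -> None:
    tail = chrom[3:] if chrom.startswith("chr") else chrom
    if not tail.isdigit():
        raise ValueError(f"{where}: non-autosomal chromosome {chrom!r} (autosomes only)")


def read_penncnv(path) -> pd.DataFrame:
    """Parse PennCNV rawcnv-style text into a calls frame.

    Line format (1-based inclusive coordinates)::

        chr1:10001-40000 numsnp=20 length=30000 state2,cn=1 SAMPLE [extras...]
    """
    rows: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                if len(tokens) < 5:
                    raise ValueError("expected >= 5 whitespace-separated fields")
                loc, numsnp_tok, length_tok, state_tok, sample_id = tokens[:5]
                chrom, span = loc.split(":")
                start_s, end_s = span.split("-")
                start1, end1 = int(start_s), int(end_s)
                if not numsnp_tok.startswith("numsnp="):
                    raise ValueError(f"bad numsnp token {numsnp_tok!r}")
                n_probes = int(numsnp_tok[len("numsnp="):])
                if not length_tok.startswith("length="):
                    raise ValueError(f"bad length token {length_tok!r}")
                state_part, cn_part = state_tok.split(",")
                if not state_part.startswith("state") or not cn_part.startswith("cn="):
                    raise ValueError(f"bad state token {state_tok!r}")
                cn = int(cn_part[len("cn="):])
                if cn not in _CN_TO_STATE:
                    raise ValueError(f"copy number {cn} is not a CNV state (cn=2 is neutral)")
                _check_autosome(chrom, "penncnv")
                if end1 < start1:
                    raise ValueError("end < start")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PennCNV line: {exc}") from None
            rows.append((sample_id, chrom, start1 - 1, end1, _CN_TO_STATE[cn], cn, n_probes, "A"))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_penncnv(calls: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            state_code = {0: 1, 1: 2, 3: 5, 4: 6}[int(row.cn)]
            fh.write(
                f"{row.chrom}:{row.start + 1}-{row.end} numsnp={row.n_probes} "
                f"length={row.end - row.start} state{state_code},cn={row.cn} {row.sample_id}\n"
            )


_QSNP_COLS = ["sample_id", "chrom", "start", "end", "n_probes", "copy_number", "log_bayes_factor"]


def read_quantisnp(path) -> pd.DataFrame:
    """Read the QuantiSNP-like TSV dialect (1-based inclusive coordinates).

    Columns: sample_id, chrom, start, end, n_probes, copy_number,
    log_bayes_factor.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = set(_QSNP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_cn = ~df["copy_number"].isin(list(_CN_TO_STATE))
    if bad_cn.any():
        i = int(np.flatnonzero(bad_cn.to_numpy())[0])
        raise ValueError(f"{path}: row {i + 2}: copy number {df['copy_number'].iloc[i]} is not a CNV state")
    for c in df["chrom"].unique():
        _check_autosome(str(c), "quantisnp")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
            "state": df["copy_number"].map(_CN_TO_STATE),
            "cn": df["copy_number"].astype(int),
            "n_probes": df["n_probes"].astype(int),
            "caller": "B",
        }
    )
    if (out["end"] <= out["start"]).any():
        raise ValueError(f"{path}: degenerate interval (end <= start)")
    return out


def write_quantisnp(calls: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": calls["sample_id"],
            "chrom": calls["chrom"],
            "start": calls["start"] + 1,
            "end": calls["end"],
            "n_probes": calls["n_probes"],
            "copy_number": calls["cn"],
            "log_bayes_factor": calls.get("log_bayes_factor", pd.Series(10.0, index=calls.index)),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"calls frame missing columns {sorted(missing)}")
    if (calls["end"] <= calls["start"]).any():
        raise ValueError("degenerate call interval (end <= start)")
    if (calls["n_probes"] < 1).any():
        raise ValueError("calls with n_probes < 1")
    mism = calls["state"] != calls["cn"].map(_CN_TO_STATE)
    if mism.any():
        raise ValueError("copy state inconsistent with copy number")
    return calls


def calls_to_frame(calls: List[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.chrom, c.start, c.end, c.state, c.cn, c.n_probes, c.caller) for c in calls],
        columns=CALL_COLUMNS,
    )


def frame_to_calls(frame: pd.DataFrame) -> List[CnvCall]:
    return [
        CnvCall(r.sample_id, r.chrom, int(r.start), int(r.end), r.state, int(r.cn), int(r.n_probes), r.caller)
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# sample sheet and probe-level BAF/LRR
# ---------------------------------------------------------------------------

def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset": str})
    required = {"sample_id", "is_case", "dataset", "country", "sex", "lrrsd", "abswf", "baf_drift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["is_case"] = df["is_case"].astype(bool)
    bad = ~df["country"].isin(["SWE", "NOR"])
    if bad.any():
        raise ValueError(f"{path}: unknown country values {df.loc[bad, 'country'].unique().tolist()}")
    bad = ~df["sex"].isin(["M", "F"])
    if bad.any():
        raise ValueError(f"{path}: unknown sex values {df.loc[bad, 'sex'].unique().tolist()}")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_baf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = {"sample_id", "chrom", "pos", "baf", "lrr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: BAF table missing columns {sorted(missing)}")
    return df


def write_baf(baf: pd.DataFrame, path) -> None:
    baf.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

def _read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative BED coordinate")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: degenerate BED interval")
    return df


def _write_bed(df: pd.DataFrame, path, name_col: Optional[str] = None) -> None:
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_tracks(directory) -> AnnotationBundle:
    """Load an annotation directory into an :class:`AnnotationBundle`.

    Expects ``<track>.bed`` for each exclusion track, ``genes.tsv``,
    ``constraint.bedGraph``, ``probes.tsv``, ``chrom_sizes.tsv`` and
    optionally ``sv_freq.tsv``. Overlapping intervals within a track are
    merged; everything is schema-validated.
    """
    directory = str(directory)
    missing = []
    paths = {}
    for name in TRACK_NAMES:
        p = os.path.join(directory, f"{name}.bed")
        if not os.path.exists(p):
            missing.append(f"{name}.bed")
        paths[name] = p
    for fname in ("genes.tsv", "constraint.bedGraph", "probes.tsv", "chrom_sizes.tsv"):
        if not os.path.exists(os.path.join(directory, fname)):
            missing.append(fname)
    if missing:
        raise FileNotFoundError(f"annotation directory {directory} missing: {missing}")

    chrom_sizes = {}
    cs = pd.read_csv(os.path.join(directory, "chrom_sizes.tsv"), sep="\t",
                     header=None, names=["chrom", "size"], dtype={0: str})
    for r in cs.itertuples(index=False):
        chrom_sizes[str(r.chrom)] = int(r.size)

    tracks = {name: GenomeIntervals.from_frame(_read_bed(paths[name])) for name in TRACK_NAMES}

    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t", dtype={"chrom": str, "gene_id": str})
    required = {"gene_id", "chrom", "start", "end", "pli", "pnull", "haplosensitive", "triplosensitive", "genesets"}
    miss = required - set(genes.columns)
    if miss:
        raise ValueError(f"genes.tsv missing columns {sorted(miss)}")
    genes["genesets"] = genes["genesets"].fillna("")
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    cons = pd.read_csv(os.path.join(directory, "constraint.bedGraph"), sep="\t",
                       header=None, names=["chrom", "start", "end", "score"], dtype={0: str})
    constraint = {}
    for c, grp in cons.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="stable")
        constraint[str(c)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["score"].to_numpy(float),
        )

    pr = pd.read_csv(os.path.join(directory, "probes.tsv"), sep="\t", dtype={"chrom": str})
    probes = {str(c): np.sort(g["pos"].to_numpy(np.int64)) for c, g in pr.groupby("chrom", sort=True)}

    sv_path = os.path.join(directory, "sv_freq.tsv")
    sv_freq = None
    if os.path.exists(sv_path):
        sv_freq = pd.read_csv(sv_path, sep="\t", dtype={"chrom": str})

    geneset_ids = sorted({g for gs in genes["genesets"] for g in str(gs).split(",") if g})
    bundle = AnnotationBundle(chrom_sizes=chrom_sizes, tracks=tracks, genes=genes,
                              constraint=constraint, probes=probes, sv_freq=sv_freq,
                              geneset_ids=tuple(geneset_ids))
    bundle.validate()
    return bundle


def write_tracks(bundle: AnnotationBundle, directory) -> None:
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    pd.DataFrame(sorted(bundle.chrom_sizes.items()), columns=["chrom", "size"]).to_csv(
        os.path.join(directory, "chrom_sizes.tsv"), sep="\t", index=False, header=False
    )
    for name in TRACK_NAMES:
        _write_bed(bundle.tracks[name].to_frame(), os.path.join(directory, f"{name}.bed"))
    bundle.genes.to_csv(os.path.join(directory, "genes.tsv"), sep="\t", index=False, float_format="%.8g")
    rows = []
    for c in sorted(bundle.constraint):
        s, e, sc = bundle.constraint[c]
        rows.append(pd.DataFrame({"chrom": c, "start": s, "end": e, "score": np.round(sc, 4)}))
    pd.concat(rows, ignore_index=True).to_csv(
        os.path.join(directory, "constraint.bedGraph"), sep="\t", index=False, header=False
    )
    pd.concat(
        [pd.DataFrame({"chrom": c, "pos": bundle.probes[c]}) for c in sorted(bundle.probes)],
        ignore_index=True,
    ).to_csv(os.path.join(directory, "probes.tsv"), sep="\t", index=False)
    if bundle.sv_freq is not None:
        bundle.sv_freq.to_csv(os.path.join(directory, "sv_freq.tsv"), sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(results, path) -> None:
    """Write a results table (DataFrame or list of dataclasses) as TSV.

    Floats use 12 significant digits so that a read/write round trip is
    value-preserving at that precision.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in results])
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, seed: int, config=None, extra: Optional[dict] = None) -> None:
    """JSON run manifest: seed, config hash, package version."""
    from . import __version__

    payload = {"seed": int(seed), "package_version": __version__}
    if config is not None:
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        payload["config"] = cfg
        payload["config_sha256"] = hashlib.sha256(blob).hexdigest()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
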