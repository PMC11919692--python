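"""Configuration objects for simulation, QC, filtering and power analysis.

Defaults encode the cohort conditions the pipeline is designed around: a
two-country case/control array cohort of ~2.2k cases / ~3.6k controls in
>=4 genotyping datasets, CNVs >=30 kb spanning >=15 probes, cohort
frequency <1%, and a case excess concentrated in deletions of
loss-of-function-intolerant (high-pLI) genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

__all__ = ["SimConfig", "QcThresholds", "FilterConfig", "PowerConfig", "load_config", "dump_config"]


def _default_chrom_sizes() -> Dict[str, int]:
    # six synthetic autosomes, ~285 Mb total
    return {
        "chr1": 60_000_000,
        "chr2": 55_000_000,
        "chr3": 50_000_000,
        "chr4": 45_000_000,
        "chr5": 40_000_000,
        "chr6": 35_000_000,
    }


def _default_freq_spectrum() -> Dict[str, float]:
    # mixture weights over carrier-frequency classes of background CNV loci
    return {"singleton": 0.45, "rare": 0.35, "low": 0.18, "common": 0.02}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``planted_or_del_pli`` / ``planted_or_dup`` are per-carrier
    case/control odds ratios for the planted risk loci (deletions in
    pLI>0.5 genes; coding duplications). Setting both to 1.0 yields a
    null cohort.
    """

    seed: int = 0
    n_cases: int = 2248
    n_controls: int = 3608
    n_datasets: int = 4
    chrom_sizes: Dict[str, int] = field(default_factory=_default_chrom_sizes)
    probe_spacing_bp: float = 2000.0
    background_cnv_rate: float = 1.3
    freq_spectrum: Dict[str, float] = field(default_factory=_default_freq_spectrum)
    planted_or_del_pli: float = 4.0
    planted_or_dup: float = 1.3
    n_planted_del_loci: int = 15
    n_planted_dup_loci: int = 10
    planted_freq_range: tuple = (0.0005, 0.003)
    caller_jitter_bp: float = 4000.0
    caller_dropout: float = 0.05
    fp_rate: float = 0.10  # false-positive calls per sample per caller
    outlier_fraction: float = 0.02
    artifact_clusters: int = 3
    artifact_calls_total: int = 19
    artifact_dataset: Optional[str] = None  # None -> random dataset per cluster
    artifact_all_one_dataset: bool = True

    # cohort composition
    swe_fraction: float = 0.7
    case_female_rate: float = 0.63
    control_female_rate: float = 0.70

    # intensity metric distributions (log-normal location/scale; plausible
    # stand-ins -- the source data's QC-metric distributions are not published)
    lrrsd_mu: float = -2.12  # median ~0.12
    lrrsd_sigma: float = 0.18
    abswf_mu: float = -5.12  # median ~0.006
    abswf_sigma: float = 0.35
    baf_drift_mu: float = -8.52  # median ~2e-4
    baf_drift_sigma: float = 0.45
    lrrsd_case_shift: float = 0.06  # multiplicative log-shift in cases
    outlier_lrrsd_factor: float = 2.5
    outlier_extra_calls: float = 30.0  # Poisson mean of extra noise calls

    # covariate structure
    pc5_country_shift: float = 1.5
    pc7_dataset_sd: float = 0.6
    pc7_callrate_beta: float = 0.10
    lrrsd_callrate_beta: float = 1.5

    # annotation generation
    n_genes: int = 400
    gene_length_mu: float = 11.0  # log-scale, median ~60 kb
    gene_length_sigma: float = 0.5
    ndd_fraction: float = 0.05
    constraint_window_bp: int = 1000
    constraint_mean: float = 0.5
    constraint_gene_bonus: float = 3.0
    n_sv_track_records: int = 60

    # per-probe signal model
    baf_noise_sd: float = 0.03
    lrr_del_shift: float = -0.45
    lrr_dup_shift: float = 0.30

    # clinical / PRS planting
    prs_carrier_shift: float = -0.45
    comorbid_base_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "asd": 0.08,
            "adhd": 0.12,
            "tics": 0.06,
            "scz": 0.01,
            "bd": 0.02,
            "ed": 0.05,
        }
    )
    comorbid_carrier_rates: Dict[str, float] = field(default_factory=lambda: {"asd": 0.50})
    ybocs_pre_mean: float = 27.0
    ybocs_pre_sd: float = 4.5
    improvement_noncarrier: float = 0.47
    improvement_ndd_del_carrier: float = 0.16
    improvement_sd: float = 0.30
    clinical_fraction: float = 0.72  # fraction of cases with clinical data

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_datasets < 2:
            raise ValueError("n_datasets must be >= 2")
        for name in ("caller_dropout", "outlier_fraction", "swe_fraction",
                     "case_female_rate", "control_female_rate", "clinical_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_or_del_pli <= 0 or self.planted_or_dup <= 0:
            raise ValueError("planted odds ratios must be > 0")
        if abs(sum(self.freq_spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("freq_spectrum weights must sum to 1")
        if any(w < 0 for w in self.freq_spectrum.values()):
            raise ValueError("freq_spectrum weights must be nonnegative")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be set")


@dataclass
class QcThresholds:
    """Sample- and call-level QC thresholds."""

    sd_multiplier: float = 3.0
    lrrsd_cap: float = 0.2
    abswf_cap: float = 0.02
    baf_drift_cap: float = 0.001
    max_raw_bp: int = 20_000_000
    max_raw_calls: int = 20
    min_probes: int = 15
    min_length: int = 30_000

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class FilterConfig:
    """Post-calling filter cascade thresholds."""

    overlap_threshold: float = 0.30  # strict > removal on fractional tracks
    freq_threshold: float = 0.01  # strict <1% required to keep
    margin_bp: int = 500_000
    reciprocal_overlap_for_freq: float = 0.50
    any_overlap_tracks: tuple = ("ig_tcr", "ebv_artifact")
    baf_het_band: tuple = (0.25, 0.75)
    baf_max_het_fraction_del: float = 0.10
    baf_dup_band_centers: tuple = (1.0 / 3.0, 2.0 / 3.0)
    baf_dup_band_halfwidth: float = 0.09
    baf_dup_informative_range: tuple = (0.15, 0.85)
    baf_dup_min_band_fraction: float = 0.50
    min_informative_probes: int = 5

    def validate(self) -> None:
        for name in ("overlap_threshold", "freq_threshold", "reciprocal_overlap_for_freq"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.margin_bp <= 0:
            raise ValueError("margin_bp must be positive")


@dataclass
class PowerConfig:
    """Case/control power-analysis grid for rare carrier tests."""

    prevalence: float = 0.01
    n_cases: int = 2248
    n_controls: int = 3608
    n_tests: int = 20_000
    alpha_family: float = 0.05
    target_power: float = 0.80
    freq_grid: tuple = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2)
    rr_grid: tuple = (1.5, 2.0, 2.5, 3.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    rr_max: float = 1e4

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if any(not 0.0 < f < 0.5 for f in self.freq_grid):
            raise ValueError("frequencies must be in (0, 0.5)")
        if any(r <= 1.0 for r in self.rr_grid):
            raise ValueError("relative risks must be > 1")


_CONFIG_TYPES = {
    "sim": SimConfig,
    "qc": QcThresholds,
    "filter": FilterConfig,
    "power": PowerConfig,
}


def load_config(path, kind: str = "sim"):
    """Load a YAML config file into the dataclass named by ``kind``."""
    cls = _CONFIG_TYPES[kind]
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {kind} config keys: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(getattr(cls(), f.name, None), tuple):
            data[f.name] = tuple(data[f.name])
    obj = cls(**data)
    obj.validate()
    return obj


def dump_config(obj, path) -> None:
    def _clean(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        return v

    data = {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
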