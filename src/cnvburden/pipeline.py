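"""End-to-end pipeline: simulation/inputs -> QC -> filters -> association.

This module glues the stages together for replicate-based calibration
runs and the command-line interface. Each stage remains independently
usable; :func:`run_pipeline` is a convenience for the common path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .burden import (
    BurdenResult,
    carriers_of,
    fit_burden,
    partition_metrics,
    select_covariates,
)
from .callset import consensus_calls, prune_samples, qualify_calls
from .config import FilterConfig, QcThresholds, SimConfig
from .filters import run_filter_cascade
from .io_formats import AnnotationBundle
from .locus_assoc import (
    InflationResult,
    LocusUnit,
    RecurrenceResult,
    clump_units,
    permutation_lambda,
    recurrence_test,
)
from .simulate import SimulatedCohort, simulate_all

__all__ = ["PipelineResult", "run_pipeline", "prepare_callset", "deleterious_called_carriers"]


@dataclass
class PipelineResult:
    samples: pd.DataFrame  # retained samples
    kept_calls: pd.DataFrame  # analysis-ready rare callset
    raw_counts: pd.Series  # per-sample consensus (pre-filter) call counts
    covariates: tuple
    burden: Dict[str, BurdenResult] = field(default_factory=dict)
    units_del: List[LocusUnit] = field(default_factory=list)
    units_dup: List[LocusUnit] = field(default_factory=list)
    inflation_del: Optional[InflationResult] = None
    inflation_dup: Optional[InflationResult] = None
    recurrence: Optional[RecurrenceResult] = None
    prune_log: Optional[pd.DataFrame] = None
    filter_log: Optional[pd.DataFrame] = None
    metrics: Optional[pd.DataFrame] = None


def prepare_callset(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    samples: pd.DataFrame,
    bundle: AnnotationBundle,
    baf: Optional[pd.DataFrame] = None,
    qc: Optional[QcThresholds] = None,
    filt: Optional[FilterConfig] = None,
):
    """Consensus -> sample pruning -> qualification -> filter cascade.

    Returns (kept_samples, kept_calls, raw_counts, prune_log, filter_log).
    Raw call load for pruning and covariate screening is the consensus
    callset before size/probe qualification.
    """
    qc = qc or QcThresholds()
    consensus = consensus_calls(calls_a, calls_b, bundle.probes)
    kept_samples, prune_log = prune_samples(samples, consensus, qc)
    consensus = consensus[consensus["sample_id"].isin(set(kept_samples["sample_id"]))].reset_index(drop=True)
    raw_counts = consensus.groupby("sample_id").size().astype(float)
    qualified = qualify_calls(consensus, qc)
    kept_calls, filter_log = run_filter_cascade(qualified, bundle, kept_samples, baf, filt)
    return kept_samples, kept_calls, raw_counts, prune_log, filter_log


def deleterious_called_carriers(calls: pd.DataFrame, bundle: AnnotationBundle, state: str = "del") -> set:
    """Carriers (from the filtered callset) of pLI>0.995 or NDD-gene CNVs."""
    g = bundle.genes
    mask = (
        (g["pli"] > 0.995)
        | g["genesets"].str.contains("NDD_fu", regex=False)
        | g["genesets"].str.contains("NDD_kendall", regex=False)
    )
    return carriers_of(calls, g, mask.to_numpy(), state)


def run_pipeline(
    config: Optional[SimConfig] = None,
    sim: Optional[SimulatedCohort] = None,
    n_perm_lambda: int = 100,
    n_perm_recurrence: int = 200,
    perm_seed: int = 0,
    burden_metrics: tuple = ("cnv_count",),
    with_locus_tests: bool = True,
    clump_mode: str = "gene",
) -> PipelineResult:
    """Simulate (or take a simulated cohort) and run the full analysis."""
    if sim is None:
        if config is None:
            raise ValueError("provide a SimConfig or a SimulatedCohort")
        sim = simulate_all(config)
    kept_samples, kept_calls, raw_counts, prune_log, filter_log = prepare_callset(
        sim.calls_a, sim.calls_b, sim.samples, sim.bundle, sim.baf
    )
    covset = select_covariates(kept_samples, raw_counts)
    covariates = covset.all
    metrics = partition_metrics(
        kept_calls, sim.bundle, kept_samples,
        partitions=("total", "state", "bp", "coding", "pli"),
    )
    burden_results: Dict[str, BurdenResult] = {}
    for name in burden_metrics:
        if name not in metrics.columns:
            continue
        try:
            burden_results[name] = fit_burden(kept_samples, metrics[name], covariates, name=name)
        except ValueError:
            continue
    result = PipelineResult(
        samples=kept_samples, kept_calls=kept_calls, raw_counts=raw_counts,
        covariates=covariates, burden=burden_results, prune_log=prune_log,
        filter_log=filter_log, metrics=metrics,
    )
    if with_locus_tests:
        result.units_del = clump_units(kept_calls, sim.bundle, kept_samples, clump_mode, "del")
        result.units_dup = clump_units(kept_calls, sim.bundle, kept_samples, clump_mode, "dup")
        if result.units_del:
            result.inflation_del = permutation_lambda(
                result.units_del, kept_samples, n_perm_lambda, seed=perm_seed
            )
            result.recurrence = recurrence_test(
                result.units_del, kept_samples, n_perm_recurrence, seed=perm_seed + 1
            )
        if result.units_dup:
            result.inflation_dup = permutation_lambda(
                result.units_dup, kept_samples, n_perm_lambda, seed=perm_seed + 2
            )
    return result
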