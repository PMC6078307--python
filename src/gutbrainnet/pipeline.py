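"""End-to-end pipeline: simulate -> connectomes -> metrics -> screen
-> tripartite network.

The in-memory flow used by both the CLI and the statistical
experiments.  One global seed is expanded into per-stage child
generators so stages can be rerun independently with stable results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import (VariableBlock, assemble_results_table,
                          block_correlations)
from .config import PipelineConfig
from .connectome import anatomical_network, functional_network
from .graph_metrics import metrics_table, metrics_to_block
from .synthetic_data import (CLINICAL, METABOLITES, generate_fiber_counts,
                             generate_subjects, generate_timeseries)
from .tripartite import (build_network, classify_effects,
                         metabolite_first_neighbors)


@dataclass
class Cohort:
    subjects: pd.DataFrame
    regions: pd.DataFrame
    timeseries: dict[str, np.ndarray]
    fiber_counts: dict[str, np.ndarray]
    volumes: np.ndarray


@dataclass
class PipelineResult:
    cohort: Cohort
    functional: dict
    anatomical: dict
    metrics: pd.DataFrame
    brain_block: pd.DataFrame
    records: pd.DataFrame
    results_table: pd.DataFrame
    network: "object"
    first_neighbors: "object"
    effects: pd.DataFrame
    config: PipelineConfig = field(repr=False, default=None)


def simulate_cohort(config: PipelineConfig) -> Cohort:
    spec = config.cohort
    regions = spec.regions()
    subjects = generate_subjects(spec)
    ts = generate_timeseries(subjects, regions, spec)
    fibers, volumes = generate_fiber_counts(subjects, regions, spec)
    return Cohort(subjects, regions, ts, fibers, volumes)


def build_connectomes(cohort: Cohort, config: PipelineConfig):
    """Functional + anatomical matrices; the configured number of
    anatomical scans (last subject ids) is excluded, mirroring a
    failed-quality-control scan."""
    labels = list(cohort.regions["label"])
    functional = {
        sid: functional_network(X, config.z_threshold, labels, sid)
        for sid, X in cohort.timeseries.items()}
    excluded = set(cohort.subjects["subject_id"].iloc[
        len(cohort.subjects) - config.cohort.dti_excluded:]) \
        if config.cohort.dti_excluded else set()
    anatomical = {
        sid: anatomical_network(C, cohort.volumes, config.anat_norm,
                                labels, sid)
        for sid, C in cohort.fiber_counts.items() if sid not in excluded}
    return functional, anatomical


def make_blocks(cohort: Cohort, brain_block: pd.DataFrame,
                config: PipelineConfig):
    subj = cohort.subjects.set_index("subject_id")
    blocks = [
        VariableBlock("metabolite", subj[list(METABOLITES)]),
        VariableBlock("clinical", subj[list(CLINICAL)]),
        VariableBlock("brain", brain_block.reindex(subj.index)),
    ]
    covariates = subj[list(config.covariates)]
    return blocks, covariates


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cohort = simulate_cohort(config)
    functional, anatomical = build_connectomes(cohort, config)
    metrics = metrics_table(functional, anatomical, cohort.regions,
                            distance=config.distance,
                            binary_degree=config.binary_degree)
    brain_block = metrics_to_block(metrics)
    blocks, covariates = make_blocks(cohort, brain_block, config)
    records = block_correlations(blocks, covariates, config.family_key)
    results = assemble_results_table(records)
    net = build_network(records, config.threshold_mode, config.alpha)
    fn = metabolite_first_neighbors(net)
    effects = classify_effects(fn)
    return PipelineResult(cohort, functional, anatomical, metrics,
                          brain_block, records, results, net, fn,
                          effects, config)


def run_association_only(config: PipelineConfig,
                         brain_block: pd.DataFrame) -> pd.DataFrame:
    """Screen a directly generated brain block (calibration studies).

    Skips the imaging simulation entirely; used when the study design
    plants exact metric-level correlations.
    """
    spec = config.cohort
    subjects = generate_subjects(spec)
    subj = subjects.set_index("subject_id")
    blocks = [
        VariableBlock("metabolite", subj[list(METABOLITES)]),
        VariableBlock("clinical", subj[list(CLINICAL)]),
        VariableBlock("brain", brain_block.set_index("subject_id")
                      if "subject_id" in brain_block else brain_block),
    ]
    covariates = subj[list(config.covariates)]
    return block_correlations(blocks, covariates, config.family_key)
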