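"""End-to-end orchestration: simulate -> methylome -> annotation -> DMR ->
expression -> integration, with recovery scoring against the planted truth."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation, dmr, expression, integration, methylome
from .simulate import (CONTRASTS, STAGES, SimulatedDataset, SimulationConfig,
                       simulate_dataset)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    matrix: methylome.MethylationMatrix
    feature_index: annotation.FeatureIndex
    site_labels: pd.Series
    dmrs: dict                      # contrast -> records frame
    dmr_summaries: dict
    tpm: pd.DataFrame
    deg_results: dict               # contrast -> DegResult
    deg_union: pd.Index
    peak_stages: pd.DataFrame
    soft_clusters: expression.SoftClustering | None
    strata: pd.Series
    metagene: integration.MetageneProfile
    promoter_levels: pd.DataFrame
    correlations: pd.DataFrame
    pngs: pd.Index
    dm_degs: pd.Index
    dm_deg_clusters: pd.Series | None
    recovery: dict = field(default_factory=dict)


def build_matrix(dataset: SimulatedDataset,
                 min_coverage: int = 5) -> methylome.MethylationMatrix:
    """Cytosine reports -> filtered, merged methylation matrix."""
    singles = {s: methylome.compute_levels(df, min_coverage=min_coverage)
               for s, df in dataset.reports.items()}
    return methylome.merge_samples(singles, dataset.design)


def run_pipeline(config: SimulationConfig | None = None,
                 min_coverage: int = 5, diff_cutoff: float = 0.25,
                 q_cutoff: float = 0.05, window: int = 1000,
                 png_cutoff: float = integration.PNG_CUTOFF,
                 soft_cluster_c: int = 6,
                 dm_deg_clusters_k: int = 6,
                 strata_stage: str = STAGES[0]) -> PipelineResult:
    """Run the full analysis on a fresh simulated dataset.

    Genomic windows on the synthetic mini-genome follow the generator's
    scaled promoter width (ground truth records it); the metagene flank is
    twice that width.
    """
    config = config or SimulationConfig()
    ds = simulate_dataset(config)
    pw = ds.truth.promoter_window
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chromosomes)}

    matrix = build_matrix(ds, min_coverage=min_coverage)
    index = annotation.build_feature_index(ds.genes, ds.cgis,
                                           promoter_window=pw,
                                           chrom_sizes=chrom_sizes)
    labels = annotation.assign_sites(matrix, index)

    dmrs, summaries = {}, {}
    for contrast in CONTRASTS:
        records, summary = dmr.call_dmrs(
            matrix, contrast, window=window, step=window,
            diff_cutoff=diff_cutoff, q_cutoff=q_cutoff,
            chrom_sizes=chrom_sizes)
        dmrs[contrast] = records
        summaries[contrast] = summary

    tpm = expression.counts_to_tpm(ds.counts, ds.lengths)
    expressed = expression.define_expressed(tpm)
    deg_results = {c: expression.deg_test(ds.counts.loc[expressed], ds.design, c)
                   for c in CONTRASTS}
    deg_union = pd.Index(sorted(set().union(*(r.degs for r in deg_results.values()))),
                         name="gene_id")
    peaks = expression.assign_peak_stage(deg_union, tpm, ds.design)
    soft = None
    if len(deg_union) >= soft_cluster_c:
        traj = expression.stage_means(tpm.loc[deg_union], ds.design)
        soft = expression.soft_cluster(traj, c=soft_cluster_c,
                                       seed=config.seed)

    strata = integration.expression_strata(tpm.loc[expressed], ds.design,
                                           stage=strata_stage)
    metagene = integration.metagene_profile(matrix, ds.genes, strata,
                                            flank=2 * pw)
    promoter = integration.promoter_methylation(matrix, ds.genes,
                                                promoter_window=pw)
    records = integration.correlate_genes(promoter, tpm.loc[expressed])
    pngs = integration.identify_pngs(records, cutoff=png_cutoff)
    dm_degs = integration.identify_dm_degs(pngs, deg_union)
    dd_clusters = None
    if len(dm_degs) >= dm_deg_clusters_k:
        dd_clusters = integration.cluster_dm_degs(
            expression.stage_means(tpm.loc[dm_degs], ds.design),
            k=dm_deg_clusters_k)

    recovery = integration.evaluate_recovery(deg_union, dm_degs, dmrs, ds.truth)
    # planted-DEG power at the planted fold change: a planted gene counts as
    # detected when it is flagged in a contrast where its trajectory moves
    recovery["deg_power"] = planted_deg_power(deg_results, ds.truth)

    return PipelineResult(
        dataset=ds, matrix=matrix, feature_index=index, site_labels=labels,
        dmrs=dmrs, dmr_summaries=summaries, tpm=tpm, deg_results=deg_results,
        deg_union=deg_union, peak_stages=peaks, soft_clusters=soft,
        strata=strata, metagene=metagene, promoter_levels=promoter,
        correlations=records, pngs=pngs, dm_degs=dm_degs,
        dm_deg_clusters=dd_clusters, recovery=recovery)


def planted_deg_power(deg_results: dict, truth) -> float:
    """Fraction of planted DEGs flagged in a contrast where they change.

    A plain planted DEG peaking at stage s truly changes in every successive
    contrast that borders s; a planted DM-DEG changes in both contrasts.
    Power counts a gene as recovered if it is flagged in all its true
    contrasts.
    """
    dmdeg_ids = set(truth.planted_dmdegs["gene_id"])
    n = 0
    hit = 0
    flagged = {c: set(r.degs) for c, r in deg_results.items()}
    for r in truth.planted_degs.itertuples():
        contrasts = [c for c in flagged if r.gene_id in dmdeg_ids
                     or r.peak_stage in c]
        if not contrasts:
            continue
        n += 1
        if all(r.gene_id in flagged[c] for c in contrasts):
            hit += 1
    return hit / n if n else float("nan")
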