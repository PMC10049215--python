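"""Joint methylome–transcriptome analysis.

Links promoter methylation to expression: metagene methylation profiles
stratified by expression tertile (20 upstream + 100 gene-body + 20
downstream bins), per-gene pooled promoter methylation, Pearson correlation
of promoter methylation with expression across the staged samples,
promoter-negative genes (PNGs, r < -0.475), their intersection with the DEG
set (DM-DEGs), hierarchical clustering of DM-DEG trajectories, and recovery
scoring against planted simulation truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import stage_means

logger = logging.getLogger(__name__)

PNG_CUTOFF = -0.475
N_FLANK_BINS = 20
N_BODY_BINS = 100
N_BINS = 2 * N_FLANK_BINS + N_BODY_BINS


def expression_strata(tpm: pd.DataFrame, design: pd.DataFrame, stage: str,
                      n_strata: int = 3) -> pd.Series:
    """Tertile split of genes by stage-mean TPM: low / medium / high.

    Rank-based (ties broken by rank order, then gene id), so the groups
    partition the genes deterministically into near-equal thirds.
    """
    if n_strata != 3:
        raise ValueError("three strata (low/medium/high) are supported")
    sm = stage_means(tpm, design)[stage].sort_index()
    order = sm.rank(method="first").to_numpy() - 1
    n = len(sm)
    bounds = np.floor(order * n_strata / n).astype(int)
    names = np.array(["low", "medium", "high"])
    return pd.Series(names[bounds], index=sm.index, name="stratum")


@dataclass
class MetageneProfile:
    """Mean methylation over 140 ordered metagene bins per stratum and sample.

    Bins 0–19 cover the upstream flank (5' of the TSS), 20–119 the gene body
    in transcription direction, 120–139 the downstream flank. ``values`` is
    indexed by (stratum, sample); bins with no covered CpG are NaN.
    """

    values: pd.DataFrame     # (stratum, sample) x bin
    n_sites: pd.DataFrame    # contributing defined levels per bin
    flank: int
    n_genes_profiled: int
    n_genes_empty: int       # genes without any covered CpG in their span


def _metagene_bins(pos: np.ndarray, start: int, end: int, strand: str,
                   flank: int) -> np.ndarray:
    """Bin index (0..139) per position, -1 outside the profiled span.

    Flank bins are fixed-width (``flank / 20`` bp); body bins span
    ``length / 100`` bp each, so short genes use fractional bin widths.
    """
    length = end - start + 1
    flank_bin = flank / N_FLANK_BINS
    out = np.full(len(pos), -1, dtype=int)

    in_body = (pos >= start) & (pos <= end)
    offset = np.where(strand == "+", pos - start, end - pos)
    body_bin = np.minimum((offset * N_BODY_BINS) // length, N_BODY_BINS - 1)
    out[in_body] = N_FLANK_BINS + body_bin[in_body]

    if strand == "+":
        up = (pos < start) & (pos >= start - flank)
        dist_up = start - pos          # 1..flank
        down = (pos > end) & (pos <= end + flank)
        dist_down = pos - end
    else:
        up = (pos > end) & (pos <= end + flank)
        dist_up = pos - end
        down = (pos < start) & (pos >= start - flank)
        dist_down = start - pos
    up_bin = N_FLANK_BINS - 1 - ((dist_up - 1) // flank_bin).astype(int)
    out[up] = up_bin[up]
    down_bin = ((dist_down - 1) // flank_bin).astype(int)
    out[down] = N_FLANK_BINS + N_BODY_BINS + down_bin[down]
    return out


def metagene_profile(matrix, genes: pd.DataFrame, strata: pd.Series,
                     flank: int = 5000) -> MetageneProfile:
    """Stratified metagene methylation profile.

    Every retained CpG inside a gene's profiled span contributes its level
    to exactly one bin of that gene (a site overlapping several genes'
    spans is counted once per gene). Returns per-stratum, per-sample mean
    levels over the 140 bins.
    """
    samples = matrix.samples
    strata = strata.dropna()
    level = matrix.level
    idx = level.index
    chrom_vals = idx.get_level_values("chrom").to_numpy()
    pos_vals = idx.get_level_values("pos").to_numpy()
    by_chrom = {c: np.flatnonzero(chrom_vals == c)
                for c in pd.unique(chrom_vals)}

    strata_names = ["low", "medium", "high"]
    sums = {(st, s): np.zeros(N_BINS) for st in strata_names for s in samples}
    cnts = {(st, s): np.zeros(N_BINS, dtype=int) for st in strata_names
            for s in samples}
    lv = level.to_numpy()
    col_of = {s: i for i, s in enumerate(samples)}

    n_profiled = n_empty = 0
    gsub = genes[genes["gene_id"].isin(strata.index)]
    for g in gsub.itertuples():
        st = strata[g.gene_id]
        ixs = by_chrom.get(g.chrom)
        if ixs is None:
            continue
        pos = pos_vals[ixs]
        lo = np.searchsorted(pos, g.start - flank, side="left")
        hi = np.searchsorted(pos, g.end + flank, side="right")
        if hi <= lo:
            n_empty += 1
            continue
        sel = ixs[lo:hi]
        bins = _metagene_bins(pos_vals[sel], g.start, g.end, g.strand, flank)
        valid = bins >= 0
        sel, bins = sel[valid], bins[valid]
        if not len(sel):
            n_empty += 1
            continue
        n_profiled += 1
        for s in samples:
            vals = lv[sel, col_of[s]]
            ok = ~np.isnan(vals)
            if ok.any():
                np.add.at(sums[(st, s)], bins[ok], vals[ok])
                np.add.at(cnts[(st, s)], bins[ok], 1)

    rows_v, rows_n, keys = [], [], []
    for st in strata_names:
        for s in samples:
            cnt = cnts[(st, s)]
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, sums[(st, s)] / np.maximum(cnt, 1),
                                np.nan)
            rows_v.append(mean)
            rows_n.append(cnt)
            keys.append((st, s))
    mi = pd.MultiIndex.from_tuples(keys, names=["stratum", "sample"])
    return MetageneProfile(
        values=pd.DataFrame(rows_v, index=mi, columns=range(N_BINS)),
        n_sites=pd.DataFrame(rows_n, index=mi, columns=range(N_BINS)),
        flank=flank, n_genes_profiled=n_profiled, n_genes_empty=n_empty)


def promoter_methylation(matrix, genes: pd.DataFrame,
                         promoter_window: int = 3000,
                         min_sites: int = 3) -> pd.DataFrame:
    """Pooled promoter methylation per gene and sample.

    Coverage-weighted: sum of methylated reads over the sum of all reads at
    retained sites within TSS +/- ``promoter_window``. Genes with fewer than
    ``min_sites`` retained CpGs in the window are NaN throughout (excluded
    from downstream correlation).
    """
    idx = matrix.level.index
    chrom_vals = idx.get_level_values("chrom").to_numpy()
    pos_vals = idx.get_level_values("pos").to_numpy()
    by_chrom = {c: np.flatnonzero(chrom_vals == c)
                for c in pd.unique(chrom_vals)}
    meth = matrix.meth.to_numpy()
    cov = matrix.coverage.to_numpy()

    rows = np.full((len(genes), len(matrix.samples)), np.nan)
    for i, g in enumerate(genes.itertuples()):
        ixs = by_chrom.get(g.chrom)
        if ixs is None:
            continue
        pos = pos_vals[ixs]
        lo = np.searchsorted(pos, g.tss - promoter_window, side="left")
        hi = np.searchsorted(pos, g.tss + promoter_window, side="right")
        sel = ixs[lo:hi]
        if len(sel) < min_sites:
            continue
        c = np.nansum(cov[sel], axis=0)
        m = np.nansum(meth[sel], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[i] = np.where(c > 0, m / np.maximum(c, 1), np.nan)
    return pd.DataFrame(rows, index=pd.Index(genes["gene_id"], name="gene_id"),
                        columns=matrix.samples)


def correlate_genes(promoter: pd.DataFrame, expression: pd.DataFrame,
                    design: pd.DataFrame | None = None,
                    unit: str = "samples", min_points: int = 3,
                    log_expression: bool = True) -> pd.DataFrame:
    """Pearson correlation of promoter methylation with expression per gene.

    ``unit='samples'`` pairs the per-sample values (default, n = number of
    samples); ``unit='stage_means'`` first averages within stages (requires
    ``design``). Expression is log2(TPM + 1) unless ``log_expression`` is
    off. Genes with fewer than ``min_points`` complete pairs or zero
    variance on either axis are excluded (counted in ``.attrs``).
    """
    common_genes = promoter.index.intersection(expression.index)
    expr = expression.loc[common_genes]
    prom = promoter.loc[common_genes]
    if set(prom.columns) != set(expr.columns):
        raise ValueError("promoter and expression sample sets differ")
    expr = expr[prom.columns]
    if log_expression:
        expr = np.log2(expr + 1.0)
    if unit == "stage_means":
        if design is None:
            raise ValueError("stage_means unit requires a design table")
        prom = _stage_mean_frame(prom, design)
        expr = _stage_mean_frame(expr, design)
    elif unit != "samples":
        raise ValueError(f"unknown correlation unit {unit!r}")

    records = []
    n_excluded = 0
    P, E = prom.to_numpy(), expr.to_numpy()
    for i, gene in enumerate(prom.index):
        x, y = P[i], E[i]
        ok = ~np.isnan(x) & ~np.isnan(y)
        n = int(ok.sum())
        if n < min_points or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            n_excluded += 1
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        records.append((gene, r, n))
    out = pd.DataFrame(records, columns=["gene_id", "pearson_r", "n_points"]) \
        .set_index("gene_id")
    out.attrs["n_excluded"] = n_excluded
    return out


def _stage_mean_frame(df: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    groups = {}
    for s in pd.unique(design["stage"]):
        cols = [c for c in df.columns if design.loc[c, "stage"] == s]
        groups[s] = df[cols].mean(axis=1)
    return pd.DataFrame(groups)


def identify_pngs(records: pd.DataFrame, cutoff: float = PNG_CUTOFF) -> pd.Index:
    """Promoter-negative genes: strictly r < cutoff (r == cutoff excluded)."""
    return records.index[records["pearson_r"] < cutoff]


def identify_dm_degs(pngs, degs) -> pd.Index:
    """DM-DEGs = PNGs that are also DEGs (exact set intersection)."""
    return pd.Index(sorted(set(pngs) & set(degs)), name="gene_id")


def cluster_dm_degs(traj: pd.DataFrame, k: int = 6) -> pd.Series:
    """Hierarchical clustering of z-scored stage trajectories into C1..Ck.

    Agglomerative, Euclidean distance, average linkage. Cluster names are
    ordered by the cluster mean trajectory (lexicographic over stages) so
    labels are stable under gene-order permutation.
    """
    from sklearn.cluster import AgglomerativeClustering

    if k > len(traj):
        raise ValueError(f"cannot form {k} clusters from {len(traj)} genes")
    sd = traj.std(axis=1, ddof=0).replace(0, 1.0)
    z = traj.sub(traj.mean(axis=1), axis=0).div(sd, axis=0)
    model = AgglomerativeClustering(n_clusters=k, metric="euclidean",
                                    linkage="average")
    raw = model.fit_predict(z.to_numpy())
    means = {lab: tuple(np.round(z.to_numpy()[raw == lab].mean(axis=0), 9))
             for lab in range(k)}
    order = sorted(means, key=lambda lab: means[lab])
    rename = {lab: f"C{i + 1}" for i, lab in enumerate(order)}
    return pd.Series([rename[lab] for lab in raw], index=traj.index,
                     name="cluster")


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def _prf(n_true_pos: int, n_pred: int, n_truth: int) -> dict:
    precision = n_true_pos / n_pred if n_pred else 0.0
    recall = n_true_pos / n_truth if n_truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_predicted": n_pred, "n_truth": n_truth,
            "empty_prediction": n_pred == 0}


def evaluate_recovery(predicted_degs, predicted_dmdegs,
                      predicted_dmrs: dict, truth) -> dict:
    """Precision/recall/F1 of predictions against planted truth.

    Gene sets match by identity; DMRs by >= 50% reciprocal overlap within
    the matching stage contrast, with direction accuracy reported over the
    matched regions.
    """
    out = {}
    truth_degs = set(truth.planted_degs["gene_id"])
    out["deg"] = _prf(len(set(predicted_degs) & truth_degs),
                      len(set(predicted_degs)), len(truth_degs))
    truth_dmdegs = set(truth.planted_dmdegs["gene_id"])
    out["dmdeg"] = _prf(len(set(predicted_dmdegs) & truth_dmdegs),
                        len(set(predicted_dmdegs)), len(truth_dmdegs))

    n_truth = len(truth.planted_dmrs)
    n_pred = sum(len(df) for df in predicted_dmrs.values())
    matched_truth = 0
    matched_pred = 0
    direction_ok = 0
    for contrast, called in predicted_dmrs.items():
        sub = truth.planted_dmrs[
            (truth.planted_dmrs["stage_a"] == contrast[0])
            & (truth.planted_dmrs["stage_b"] == contrast[1])]
        for t in sub.itertuples():
            hits = [
                (j, _reciprocal_overlap(t.start, t.end, c.start, c.end))
                for j, c in enumerate(called.itertuples())
                if c.chrom == t.chrom]
            hits = [(j, o) for j, o in hits if o >= 0.5]
            if hits:
                j, _ = max(hits, key=lambda h: h[1])
                matched_truth += 1
                if called.iloc[j]["direction"] == t.direction:
                    direction_ok += 1
        # precision counts every planted differential interval of this
        # contrast as truth: explicit DMRs plus DM-DEG promoters (whose
        # methylation steps at every successive stage by construction)
        truth_ivs = [(t.chrom, t.start, t.end) for t in sub.itertuples()]
        truth_ivs += [(t.chrom, t.promoter_start, t.promoter_end)
                      for t in truth.planted_dmdegs.itertuples()]
        for c in called.itertuples():
            if any(ch == c.chrom and s <= c.end and e >= c.start
                   for ch, s, e in truth_ivs):
                matched_pred += 1
    dmr = _prf(matched_truth, n_pred, n_truth)
    dmr["precision"] = matched_pred / n_pred if n_pred else 0.0
    dmr["f1"] = (2 * dmr["precision"] * dmr["recall"]
                 / (dmr["precision"] + dmr["recall"])
                 if dmr["precision"] + dmr["recall"] else 0.0)
    dmr["direction_accuracy"] = (direction_ok / matched_truth
                                 if matched_truth else 0.0)
    out["dmr"] = dmr
    return out
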