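"""Windowed differential-methylation calling between two stages.

The genome is tiled (1 kb non-overlapping windows by default); within each
tile the methylated/unmethylated read counts are pooled over CpG sites and
replicates per stage, and the pooled 2x2 table is tested with a two-sided
conditional exact (Fisher) test. Benjamini–Hochberg correction runs across
all tested tiles; tiles passing both the methylation-difference and q-value
cutoffs are emitted, and adjacent significant tiles of equal direction are
merged into single regions. ``hyper``/``hypo`` describes the second stage
relative to the first.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DmrCallSummary:
    """Bookkeeping from one calling run."""

    n_tiles_tested: int
    n_tiles_skipped: int
    n_significant_tiles: int


def tile_genome(chrom_sizes: dict[str, int], window: int = 1000,
                step: int = 1000) -> pd.DataFrame:
    """Non-overlapping (or stepped) tiles covering each chromosome.

    1-based inclusive; the last partial tile is kept. ``step > window``
    leaves gaps, which is flagged in the log.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if step > window:
        logger.warning("step %d > window %d: tiles leave gaps", step, window)
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(1, size + 1, step):
            rows.append((chrom, start, min(start + window - 1, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_tile(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int):
    """Two-sided conditional exact test of pooled counts in one tile.

    Returns ``(meth_diff, p_value)`` where ``meth_diff`` is the pooled
    methylation proportion of group B minus group A.
    """
    tot_a = meth_a + unmeth_a
    tot_b = meth_b + unmeth_b
    if tot_a == 0 or tot_b == 0:
        raise ValueError("each group needs at least one read")
    diff = meth_b / tot_b - meth_a / tot_a
    _, p = stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]],
                              alternative="two-sided")
    return diff, float(p)


def call_dmrs(matrix, contrast: tuple[str, str], window: int = 1000,
              step: int = 1000, diff_cutoff: float = 0.25,
              q_cutoff: float = 0.05, min_cpg: int = 3,
              chrom_sizes: dict | None = None):
    """Call DMRs between two stages over genome tiles.

    ``contrast = (A, B)``; effects are reported for B relative to A. A tile
    is tested when at least ``min_cpg`` sites have a defined level in at
    least one sample of each group. Returns ``(records, summary)`` where
    records carry chrom, start, end, n_cpg, group means, meth_diff, p, q
    and direction.
    """
    stage_a, stage_b = contrast
    design = matrix.design
    known = set(design["stage"])
    for s in (stage_a, stage_b):
        if s not in known:
            raise ValueError(f"stage {s!r} not present in design")
    samples_a = design.index[design["stage"] == stage_a]
    samples_b = design.index[design["stage"] == stage_b]

    idx = matrix.level.index
    chrom = idx.get_level_values("chrom").to_numpy()
    pos = idx.get_level_values("pos").to_numpy()
    tile_start = (pos - 1) // step * step + 1

    def _group(samples):
        defined = matrix.level[samples].notna().any(axis=1).to_numpy()
        meth = matrix.meth[samples].sum(axis=1).to_numpy()
        cov = matrix.coverage[samples].sum(axis=1).to_numpy()
        return defined, meth, cov

    def_a, meth_a, cov_a = _group(samples_a)
    def_b, meth_b, cov_b = _group(samples_b)
    eligible = def_a & def_b

    per_site = pd.DataFrame({
        "chrom": chrom, "tile_start": tile_start, "eligible": eligible,
        "meth_a": np.where(eligible, meth_a, 0.0),
        "cov_a": np.where(eligible, cov_a, 0.0),
        "meth_b": np.where(eligible, meth_b, 0.0),
        "cov_b": np.where(eligible, cov_b, 0.0),
    })
    tiles = per_site.groupby(["chrom", "tile_start"], sort=True).agg(
        n_cpg=("eligible", "sum"), meth_a=("meth_a", "sum"),
        cov_a=("cov_a", "sum"), meth_b=("meth_b", "sum"),
        cov_b=("cov_b", "sum")).reset_index()
    testable = (tiles["n_cpg"] >= min_cpg) & (tiles["cov_a"] > 0) \
        & (tiles["cov_b"] > 0)
    skipped = int((~testable).sum())
    tiles = tiles[testable].reset_index(drop=True)

    diffs = np.empty(len(tiles))
    pvals = np.empty(len(tiles))
    for i, r in enumerate(tiles.itertuples()):
        diffs[i], pvals[i] = test_tile(int(r.meth_a), int(r.cov_a - r.meth_a),
                                       int(r.meth_b), int(r.cov_b - r.meth_b))
    tiles["mean_level_a"] = tiles["meth_a"] / tiles["cov_a"]
    tiles["mean_level_b"] = tiles["meth_b"] / tiles["cov_b"]
    tiles["meth_diff"] = diffs
    tiles["p_value"] = pvals
    if len(tiles):
        tiles["q_value"] = multipletests(pvals, method="fdr_bh")[1]
    else:
        tiles["q_value"] = np.array([], dtype=float)

    sig = tiles[(tiles["meth_diff"].abs() >= diff_cutoff)
                & (tiles["q_value"] <= q_cutoff)].copy()
    sig["start"] = sig["tile_start"].astype(int)
    sig["end"] = (sig["tile_start"] + window - 1).astype(int)
    if chrom_sizes:
        sig["end"] = np.minimum(sig["end"],
                                sig["chrom"].map(chrom_sizes).fillna(np.inf))
        sig["end"] = sig["end"].astype(int)
    sig["direction"] = np.where(sig["meth_diff"] > 0, "hyper", "hypo")

    records = merge_adjacent(sig)
    summary = DmrCallSummary(n_tiles_tested=len(tiles),
                             n_tiles_skipped=skipped,
                             n_significant_tiles=len(sig))
    return records, summary


RECORD_COLUMNS = ["chrom", "start", "end", "n_cpg", "mean_level_a",
                  "mean_level_b", "meth_diff", "p_value", "q_value",
                  "direction"]


def merge_adjacent(sig: pd.DataFrame) -> pd.DataFrame:
    """Merge book-ended significant tiles of equal direction; idempotent.

    Pooled counts are re-aggregated so merged means and meth_diff stay exact;
    p and q of a merged record are the minima over its tiles.
    """
    if not len(sig):
        return pd.DataFrame(columns=RECORD_COLUMNS)
    sig = sig.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None
    for r in sig.itertuples():
        if cur is not None and r.chrom == cur["chrom"] \
                and r.direction == cur["direction"] \
                and r.start == cur["end"] + 1:
            cur["end"] = r.end
            for k in ("n_cpg", "meth_a", "cov_a", "meth_b", "cov_b"):
                cur[k] += getattr(r, k)
            cur["p_value"] = min(cur["p_value"], r.p_value)
            cur["q_value"] = min(cur["q_value"], r.q_value)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": r.chrom, "start": r.start, "end": r.end,
                   "n_cpg": r.n_cpg, "meth_a": r.meth_a, "cov_a": r.cov_a,
                   "meth_b": r.meth_b, "cov_b": r.cov_b,
                   "p_value": r.p_value, "q_value": r.q_value,
                   "direction": r.direction}
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows)
    out["mean_level_a"] = out["meth_a"] / out["cov_a"]
    out["mean_level_b"] = out["meth_b"] / out["cov_b"]
    out["meth_diff"] = out["mean_level_b"] - out["mean_level_a"]
    out["n_cpg"] = out["n_cpg"].astype(int)
    # carry pooled counts so a second merge pass reproduces the same records
    return out[RECORD_COLUMNS + ["meth_a", "cov_a", "meth_b", "cov_b"]]


def dmr_feature_distribution(dmrs: pd.DataFrame, index) -> tuple[pd.Series, pd.Series]:
    """Fraction of DMRs per primary feature, and counts per chromosome."""
    if not len(dmrs):
        return pd.Series(dtype=float), pd.Series(dtype=int)
    feats = [index.primary_label_region(r.chrom, r.start, r.end)
             for r in dmrs.itertuples()]
    frac = pd.Series(feats).value_counts(normalize=True).sort_index()
    per_chrom = dmrs["chrom"].value_counts().sort_index()
    return frac, per_chrom


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6+ (name = direction, score = -10*log10 q, capped)."""
    if not len(dmrs):
        pd.DataFrame(columns=range(7)).to_csv(path, sep="\t", header=False,
                                              index=False)
        return
    q = np.clip(dmrs["q_value"].to_numpy(), 1e-100, 1.0)
    out = pd.DataFrame({
        "chrom": dmrs["chrom"], "start": dmrs["start"] - 1, "end": dmrs["end"],
        "name": dmrs["direction"], "score": np.round(-10 * np.log10(q), 2),
        "strand": ".", "meth_diff": dmrs["meth_diff"].round(4),
    })
    out.to_csv(path, sep="\t", header=False, index=False)
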