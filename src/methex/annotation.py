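"""Genomic feature index: promoters, gene features, CGI shores/shelves.

Builds labelled interval sets from gene and CpG-island annotations and
assigns a single primary feature to any position or region through a fixed
precedence (CGI > shore > shelf > promoter > UTRs > exon > intron > gene
body > distal intergenic). All in-memory coordinates are 1-based inclusive;
BED I/O converts at the boundary.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_PRECEDENCE = ("cgi", "cgi_shore", "cgi_shelf", "promoter",
                      "utr5", "utr3", "exon", "intron", "gene_body",
                      "distal_intergenic")
SHORE_WIDTH = 2000
SHELF_WIDTH = 2000


def _merge_intervals(starts, ends):
    """Sort and merge possibly-overlapping 1-based inclusive intervals."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="mergesort")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= me[-1] + 1:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.array(ms), np.array(me)


class FeatureIndex:
    """Interval lookup over labelled genomic features.

    ``intervals[label][chrom] = (starts, ends)`` with merged, sorted,
    1-based inclusive intervals. Positions on chromosomes the index does not
    know cannot be assigned; everything else falls through to
    ``distal_intergenic``.
    """

    def __init__(self, intervals: dict, chroms: set, promoter_window: int):
        self.intervals = intervals
        self.chroms = set(chroms)
        self.promoter_window = promoter_window

    def labels_present(self):
        return [f for f in FEATURE_PRECEDENCE
                if f == "distal_intergenic" or f in self.intervals]

    def _member(self, label: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        per = self.intervals.get(label, {})
        if chrom not in per:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = per[chrom]
        ix = np.searchsorted(starts, pos, side="right") - 1
        return (ix >= 0) & (pos <= ends[np.clip(ix, 0, None)])

    def primary_labels(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Primary feature per position via precedence; None if chrom unknown."""
        pos = np.asarray(pos)
        if chrom not in self.chroms:
            return np.full(len(pos), None, dtype=object)
        out = np.full(len(pos), "distal_intergenic", dtype=object)
        unassigned = np.ones(len(pos), dtype=bool)
        for label in FEATURE_PRECEDENCE[:-1]:
            if label not in self.intervals or not unassigned.any():
                continue
            hit = self._member(label, chrom, pos) & unassigned
            out[hit] = label
            unassigned &= ~hit
        return out

    def _overlaps(self, label: str, chrom: str, start: int, end: int) -> bool:
        per = self.intervals.get(label, {})
        if chrom not in per:
            return False
        starts, ends = per[chrom]
        ix = np.searchsorted(starts, end, side="right")
        return bool(ix > 0 and ends[: ix].max() >= start)

    def primary_label_region(self, chrom: str, start: int, end: int) -> str:
        """Primary feature of a region = first precedence label it overlaps."""
        for label in FEATURE_PRECEDENCE[:-1]:
            if self._overlaps(label, chrom, start, end):
                return label
        return "distal_intergenic"


def build_feature_index(genes: pd.DataFrame, cgis: pd.DataFrame,
                        promoter_window: int = 3000,
                        exons: pd.DataFrame | None = None,
                        chrom_sizes: dict | None = None) -> FeatureIndex:
    """Assemble the labelled interval sets.

    Shores are the 2 kb flanks of each CGI, shelves the next 2 kb beyond;
    promoters span TSS +/- ``promoter_window`` (strand-independent span).
    If an exon table (gene_id, start, end) is supplied, exon and intron
    intervals are derived; UTRs additionally need ``cds_start``/``cds_end``
    columns on ``genes``.
    """
    for df, what in ((genes, "gene"), (cgis, "CGI")):
        if len(df) and (df["start"] > df["end"]).any():
            raise ValueError(f"malformed {what} interval: start > end")
    intervals: dict[str, dict] = {}

    def _add(label, chrom, start, end):
        intervals.setdefault(label, {}).setdefault(chrom, []).append(
            (max(1, int(start)), int(end)))

    for r in cgis.itertuples():
        _add("cgi", r.chrom, r.start, r.end)
        _add("cgi_shore", r.chrom, r.start - SHORE_WIDTH, r.start - 1)
        _add("cgi_shore", r.chrom, r.end + 1, r.end + SHORE_WIDTH)
        _add("cgi_shelf", r.chrom, r.start - SHORE_WIDTH - SHELF_WIDTH,
             r.start - SHORE_WIDTH - 1)
        _add("cgi_shelf", r.chrom, r.end + SHORE_WIDTH + 1,
             r.end + SHORE_WIDTH + SHELF_WIDTH)

    has_cds = len(genes) > 0 and {"cds_start", "cds_end"} <= set(genes.columns)
    for r in genes.itertuples():
        tss = r.start if r.strand == "+" else r.end
        _add("promoter", r.chrom, tss - promoter_window, tss + promoter_window)
        _add("gene_body", r.chrom, r.start, r.end)
        if has_cds and pd.notna(getattr(r, "cds_start", None)):
            if r.strand == "+":
                if r.cds_start > r.start:
                    _add("utr5", r.chrom, r.start, r.cds_start - 1)
                if r.cds_end < r.end:
                    _add("utr3", r.chrom, r.cds_end + 1, r.end)
            else:
                if r.cds_end < r.end:
                    _add("utr5", r.chrom, r.cds_end + 1, r.end)
                if r.cds_start > r.start:
                    _add("utr3", r.chrom, r.start, r.cds_start - 1)
    if exons is not None and len(exons):
        gx = genes.set_index("gene_id")
        for gene_id, sub in exons.groupby("gene_id"):
            g = gx.loc[gene_id]
            if (sub["start"] < g["start"]).any() or (sub["end"] > g["end"]).any():
                raise ValueError(f"exon outside gene span for {gene_id}")
            for r in sub.itertuples():
                _add("exon", g["chrom"], r.start, r.end)
            es, ee = _merge_intervals(sub["start"].to_numpy(),
                                      sub["end"].to_numpy())
            prev = g["start"]
            for a, b in zip(es, ee):
                if a > prev:
                    _add("intron", g["chrom"], prev, a - 1)
                prev = b + 1
            if prev <= g["end"]:
                _add("intron", g["chrom"], prev, g["end"])

    merged = {
        label: {chrom: _merge_intervals([s for s, _ in ivs], [e for _, e in ivs])
                for chrom, ivs in per.items()}
        for label, per in intervals.items()
    }
    chroms = set()
    if chrom_sizes:
        chroms |= set(chrom_sizes)
    chroms |= set(genes["chrom"]) if len(genes) else set()
    chroms |= set(cgis["chrom"]) if len(cgis) else set()
    return FeatureIndex(merged, chroms, promoter_window)


def assign_sites(matrix, index: FeatureIndex) -> pd.Series:
    """Primary feature label per matrix site; unknown chromosomes -> NaN.

    Sites on chromosomes the index does not know are flagged with a warning
    and excluded (NaN label).
    """
    idx = matrix.sites.index
    labels = np.full(len(idx), None, dtype=object)
    chrom_vals = idx.get_level_values("chrom")
    pos_vals = idx.get_level_values("pos").to_numpy()
    n_unknown = 0
    for chrom in pd.unique(chrom_vals):
        m = (chrom_vals == chrom).to_numpy() if hasattr(chrom_vals == chrom, "to_numpy") \
            else np.asarray(chrom_vals == chrom)
        got = index.primary_labels(chrom, pos_vals[m])
        if len(got) and got[0] is None:
            n_unknown += int(m.sum())
        labels[m] = got
    if n_unknown:
        logger.warning("%d sites on chromosomes absent from the feature index "
                       "were excluded", n_unknown)
    return pd.Series(labels, index=idx, name="feature")


def feature_mean_levels(matrix, labels: pd.Series) -> pd.DataFrame:
    """Mean methylation per primary feature and sample (defined levels only).

    Empty feature classes are absent from the result; classes with labels
    but no defined levels yield NaN.
    """
    lv = matrix.level.copy()
    lv["feature"] = labels
    out = lv.dropna(subset=["feature"]).groupby("feature").mean()
    order = [f for f in FEATURE_PRECEDENCE if f in out.index]
    return out.loc[order]


def annotate_region(chrom: str, start: int, end: int, index: FeatureIndex,
                    genes: pd.DataFrame):
    """Primary feature, nearest gene (by TSS) and signed distance to its TSS.

    Distance is 0 when the region contains the TSS; otherwise the gap to the
    nearest region edge, negative when the region lies upstream of the TSS
    in the gene's orientation. Equidistant ties break on gene id order.
    """
    feature = index.primary_label_region(chrom, start, end)
    sub = genes[genes["chrom"] == chrom]
    if not len(sub):
        return feature, None, None
    best = None
    for r in sub.sort_values("gene_id").itertuples():
        if start <= r.tss <= end:
            gap, signed = 0, 0
        elif r.tss > end:
            gap = r.tss - end
            signed = -gap if r.strand == "+" else gap
        else:
            gap = start - r.tss
            signed = gap if r.strand == "+" else -gap
        if best is None or gap < best[0]:
            best = (gap, r.gene_id, signed)
    return feature, best[1], best[2]


def read_genes_bed(path) -> pd.DataFrame:
    """BED6(+length) gene file -> 1-based inclusive gene table."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :7] if df.shape[1] >= 7 else df
    names = ["chrom", "bed_start", "end", "gene_id", "score", "strand",
             "length"][: df.shape[1]]
    df.columns = names
    df["start"] = df["bed_start"] + 1
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df["tes"] = np.where(df["strand"] == "+", df["end"], df["start"])
    if "length" not in df:
        df["length"] = df["end"] - df["start"] + 1
    return df[["gene_id", "chrom", "strand", "start", "end", "tss", "tes",
               "length"]]


def read_cgis_bed(path) -> pd.DataFrame:
    """BED3 CpG-island file -> 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "bed_start", "end"])
    df["start"] = df["bed_start"] + 1
    return df[["chrom", "start", "end"]]
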