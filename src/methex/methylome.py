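"""CpG methylation levels from cytosine reports, and global methylome summaries.

The per-site methylation level is the fraction of reads reporting
methylation, ``C / (C + T)``, computed only at CpG-context sites with at
least ``min_coverage`` (default 5) reads. On top of the filtered matrix the
module provides the standard whole-methylome characterisations: sequence
context composition of methylated cytosines, 20-bin level histograms,
low/medium/high site classification, pairwise sample correlations and PCA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")
REPORT_COLUMNS = ("chrom", "pos", "strand", "count_methylated",
                  "count_unmethylated", "context")


class ReportParseError(ValueError):
    """Malformed cytosine report; the message names the offending line."""


def parse_cytosine_report(path_or_df) -> pd.DataFrame:
    """Parse a Bismark-style cytosine report (TSV, optionally gzipped).

    Expected columns: chrom, 1-based position, strand, methylated read
    count, unmethylated read count, trinucleotide context. Malformed rows
    raise :class:`ReportParseError` naming the 1-based line number.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        df.columns = list(REPORT_COLUMNS)[: len(df.columns)]
    else:
        try:
            df = pd.read_csv(path_or_df, sep="\t", header=None, dtype=str,
                             comment=None)
        except pd.errors.EmptyDataError:
            logger.warning("empty cytosine report: %s", path_or_df)
            return pd.DataFrame(columns=REPORT_COLUMNS).astype(
                {"pos": int, "count_methylated": int, "count_unmethylated": int})
        if df.shape[1] < len(REPORT_COLUMNS):
            raise ReportParseError(
                f"expected >= {len(REPORT_COLUMNS)} tab-separated columns, "
                f"got {df.shape[1]}")
        df = df.iloc[:, : len(REPORT_COLUMNS)]
        df.columns = REPORT_COLUMNS

    def _bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ReportParseError(f"line {line}: {what}")

    pos = pd.to_numeric(df["pos"], errors="coerce")
    _bad(pos.isna() | (pos != pos.round()), "non-integer position")
    _bad(pos < 1, "position must be >= 1")
    for col in ("count_methylated", "count_unmethylated"):
        c = pd.to_numeric(df[col], errors="coerce")
        _bad(c.isna() | (c != c.round()), f"non-integer {col}")
        _bad(c < 0, f"negative {col}")
        df[col] = c.astype(int)
    _bad(~df["strand"].isin(["+", "-"]), "strand must be + or -")
    _bad(~df["context"].isin(CONTEXTS), "unknown context")
    df["pos"] = pos.astype(int)
    return df.reset_index(drop=True)


def context_composition(table: pd.DataFrame, min_meth_reads: int = 1) -> pd.Series:
    """Fraction of methylated cytosine sites per sequence context.

    A site counts as methylated when it carries at least ``min_meth_reads``
    methylated reads — the weakest call; fractions over (CpG, CHG, CHH)
    sum to 1.
    """
    if table.empty:
        raise ValueError("context composition of an empty table is undefined")
    meth = table[table["count_methylated"] >= min_meth_reads]
    counts = meth["context"].value_counts().reindex(CONTEXTS, fill_value=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no methylated cytosines in table")
    return counts / total


def compute_levels(table: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Single-sample methylation levels, C/(C+T), at >= ``min_coverage`` reads.

    Only CpG-context rows are used; sites below the coverage floor are
    dropped. Returns a frame with chrom, pos, strand, meth, coverage, level.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    cpg = table[table["context"] == "CpG"]
    cov = cpg["count_methylated"] + cpg["count_unmethylated"]
    keep = cov >= min_coverage
    out = pd.DataFrame({
        "chrom": cpg.loc[keep, "chrom"],
        "pos": cpg.loc[keep, "pos"],
        "strand": cpg.loc[keep, "strand"],
        "meth": cpg.loc[keep, "count_methylated"],
        "coverage": cov[keep],
    })
    out["level"] = out["meth"] / out["coverage"]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class MethylationMatrix:
    """Sites x samples methylation levels with coverage and raw counts.

    ``level``, ``coverage`` and ``meth`` share a (chrom, pos) MultiIndex
    sorted by position; entries are NaN for samples where the site failed
    the coverage filter. ``design`` maps samples to (stage, replicate).
    """

    sites: pd.DataFrame      # index (chrom, pos); column strand
    level: pd.DataFrame      # levels in [0, 1], NaN where undefined
    coverage: pd.DataFrame
    meth: pd.DataFrame
    design: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.level.columns)

    def subset_region(self, chrom: str, start: int, end: int) -> "MethylationMatrix":
        idx = self.sites.index
        m = (idx.get_level_values("chrom") == chrom) \
            & (idx.get_level_values("pos") >= start) \
            & (idx.get_level_values("pos") <= end)
        return MethylationMatrix(self.sites[m], self.level[m],
                                 self.coverage[m], self.meth[m], self.design)


def merge_samples(samples: dict[str, pd.DataFrame],
                  design: pd.DataFrame) -> MethylationMatrix:
    """Outer-join single-sample level frames into one matrix.

    Missingness per sample is preserved as NaN; the result is sorted by
    (chrom, pos) and is invariant to the input sample order (columns follow
    the design table).
    """
    missing = set(design.index) - set(samples)
    if missing:
        raise ValueError(f"design samples without data: {sorted(missing)}")
    lv, cv, mh, strands = {}, {}, {}, []
    for name in design.index:
        df = samples[name].set_index(["chrom", "pos"])
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate site {dup} in sample {name}")
        lv[name] = df["level"]
        cv[name] = df["coverage"]
        mh[name] = df["meth"]
        strands.append(df["strand"])
    level = pd.DataFrame(lv).sort_index()
    coverage = pd.DataFrame(cv).reindex(level.index)
    meth = pd.DataFrame(mh).reindex(level.index)
    strand = pd.concat(strands).groupby(level=[0, 1]).first().reindex(level.index)
    sites = pd.DataFrame({"strand": strand})
    sites.index.names = ["chrom", "pos"]
    for df in (level, coverage, meth):
        df.index.names = ["chrom", "pos"]
    return MethylationMatrix(sites, level, coverage, meth, design.copy())


def level_histogram(matrix: MethylationMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Per-sample counts of sites in ``n_bins`` equal-width level bins on [0, 1].

    The last bin is closed at 1.0; counts per sample sum to the number of
    defined levels.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    data = {}
    for s in matrix.samples:
        vals = matrix.level[s].dropna().to_numpy()
        data[s], _ = np.histogram(vals, bins=edges)
    labels = [f"({edges[i]:.2f},{edges[i+1]:.2f}]" for i in range(n_bins)]
    labels[0] = f"[0.00,{edges[1]:.2f}]"
    out = pd.DataFrame(data, index=pd.Index(labels, name="bin"))
    out.attrs["edges"] = edges
    return out


def classify_sites(matrix: MethylationMatrix) -> pd.DataFrame:
    """Fractions of sites at low (<=25%), medium (25–75%) and high (>=75%) levels.

    Boundary semantics follow the closed thresholds: 0.25 is low and 0.75 is
    high. Fractions per sample sum to 1 over defined levels.
    """
    rows = {}
    for s in matrix.samples:
        vals = matrix.level[s].dropna().to_numpy()
        n = len(vals)
        if n == 0:
            rows[s] = (np.nan, np.nan, np.nan)
            continue
        low = float((vals <= 0.25).sum()) / n
        high = float((vals >= 0.75).sum()) / n
        rows[s] = (low, 1.0 - low - high, high)
    return pd.DataFrame(rows, index=["low", "medium", "high"]).T


def pairwise_sample_correlation(matrix: MethylationMatrix) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of per-site levels.

    Each entry uses sites defined in both samples; pairs with fewer than two
    common sites are NaN. The diagonal is 1 and the matrix symmetric.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples for pairwise correlation")
    corr = matrix.level.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def methylation_pca(matrix: MethylationMatrix, n_components: int = 2):
    """PCA of samples on complete-case sites (no imputation).

    Returns ``(coordinates, explained_variance_ratio)``; coordinates are a
    samples x components frame. Raises if fewer complete sites than
    components exist.
    """
    from sklearn.decomposition import PCA

    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples for PCA")
    complete = matrix.level.dropna()
    if complete.shape[0] < n_components:
        raise ValueError(
            f"only {complete.shape[0]} complete-case sites for "
            f"{n_components} components")
    X = complete.to_numpy().T  # samples x sites
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(coords, index=matrix.level.columns, columns=cols),
            pd.Series(pca.explained_variance_ratio_, index=cols))


def write_bedgraph(matrix: MethylationMatrix, sample: str, path) -> None:
    """Per-sample levels as bedGraph (0-based half-open at the boundary)."""
    lv = matrix.level[sample].dropna()
    chroms = lv.index.get_level_values("chrom")
    pos = lv.index.get_level_values("pos")
    pd.DataFrame({"chrom": chroms, "start": pos - 1, "end": pos,
                  "value": lv.to_numpy()}).to_csv(path, sep="\t", header=False,
                                                  index=False)
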