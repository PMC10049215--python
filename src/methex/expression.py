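"""TPM normalisation, differential expression and soft trajectory clustering.

Counts are normalised to transcripts-per-kilobase-million (columns sum to
1e6); expressed genes have TPM >= 0.5 in at least one sample. Differential
expression between two stages uses a negative-binomial Wald kernel on
median-of-ratios-normalised counts with moderated method-of-moments
dispersions; a gene is differentially expressed when its BH-adjusted p-value
is < 0.05 and |log2 fold change| >= 1. Stage trajectories of the DEG union
are soft-clustered with fuzzy c-means (six clusters by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STAGE_ORDER = ("p21", "p28", "p35")


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Length-normalised counts rescaled so each sample sums to 1e6."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total expression rate")
    return rate.div(totals, axis=1) * 1e6


def define_expressed(tpm: pd.DataFrame, threshold: float = 0.5) -> pd.Index:
    """Genes with TPM >= threshold in at least one sample."""
    return tpm.index[(tpm >= threshold).any(axis=1)]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors (geometric-mean reference)."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
    finite = np.isfinite(logc).all(axis=1)
    if not finite.any():
        return pd.Series(1.0, index=counts.columns)
    ref = logc[finite].mean(axis=1)
    sf = np.exp(np.median(logc[finite] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


@dataclass
class DegResult:
    """Per-gene differential-expression table for one contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # log2fc, p_value, padj, is_deg per tested gene
    excluded: list = field(default_factory=list)  # all-zero genes

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]


def deg_test(counts: pd.DataFrame, design: pd.DataFrame,
             contrast: tuple[str, str], alpha: float = 0.05,
             lfc_cutoff: float = 1.0, pseudocount: float = 0.5,
             min_dispersion: float = 1e-8,
             dispersion_prior_weight: float = 20.0) -> DegResult:
    """Negative-binomial Wald test between two stages.

    Counts are normalised by median-of-ratios size factors; each gene's
    log2 fold change compares stage means with a pseudocount. The NB
    dispersion is estimated per gene by method of moments, floored at
    ``min_dispersion`` and moderated toward the across-gene mean with
    ``dispersion_prior_weight`` prior observations, which keeps the Wald
    z statistic close to N(0,1) at three replicates per group. All-zero
    genes are excluded from testing.
    """
    stage_a, stage_b = contrast
    for s in contrast:
        if s not in set(design["stage"]):
            raise ValueError(f"stage {s!r} not in design")
    sa = design.index[design["stage"] == stage_a]
    sb = design.index[design["stage"] == stage_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per stage")

    sub = counts[list(sa) + list(sb)]
    excluded = sub.index[(sub == 0).all(axis=1)]
    tested = sub.drop(index=excluded)
    sf = size_factors(sub)
    norm = tested.div(sf, axis=1)

    na, nb = len(sa), len(sb)
    ma = norm[sa].mean(axis=1).to_numpy()
    mb = norm[sb].mean(axis=1).to_numpy()
    va = norm[sa].var(axis=1, ddof=1).to_numpy()
    vb = norm[sb].var(axis=1, ddof=1).to_numpy()

    mu = (na * ma + nb * mb) / (na + nb)
    s2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    disp = np.maximum(disp, min_dispersion)
    disp_global = float(np.mean(disp)) if len(disp) else min_dispersion
    df_g = na + nb - 2
    disp = ((dispersion_prior_weight * disp_global + df_g * disp)
            / (dispersion_prior_weight + df_g))

    pa, pb = ma + pseudocount, mb + pseudocount
    log2fc = np.log2(pb / pa)
    var_a = pa + disp * pa ** 2
    var_b = pb + disp * pb ** 2
    se = np.sqrt(var_a / (na * pa ** 2) + var_b / (nb * pb ** 2))
    z = np.log(pb / pa) / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    table = pd.DataFrame({
        "log2fc": log2fc, "p_value": pvals, "padj": padj,
    }, index=tested.index)
    table["is_deg"] = (table["padj"] < alpha) & (table["log2fc"].abs() >= lfc_cutoff)
    return DegResult(contrast=(stage_a, stage_b), table=table,
                     excluded=list(excluded))


def stage_means(tpm: pd.DataFrame, design: pd.DataFrame,
                stages=STAGE_ORDER) -> pd.DataFrame:
    """Mean TPM per stage (genes x stages)."""
    cols = {}
    for s in stages:
        samples = design.index[design["stage"] == s]
        if len(samples):
            cols[s] = tpm[samples].mean(axis=1)
    return pd.DataFrame(cols)


def assign_peak_stage(deg_ids, tpm: pd.DataFrame, design: pd.DataFrame,
                      stages=STAGE_ORDER) -> pd.DataFrame:
    """Peak stage (argmax of stage-mean TPM) per DEG; ties take the earliest stage."""
    sm = stage_means(tpm.loc[list(deg_ids)], design, stages)
    arr = sm.to_numpy()
    peak_ix = arr.argmax(axis=1)  # argmax returns the first (earliest) maximum
    tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if tie.any():
        logger.info("%d DEGs had tied stage means; earliest stage kept",
                    int(tie.sum()))
    return pd.DataFrame({"peak_stage": [sm.columns[i] for i in peak_ix],
                         "tied": tie}, index=sm.index)


def quartile_classes(tpm: pd.DataFrame, stage: str,
                     design: pd.DataFrame) -> pd.Series:
    """High/medium/low classes by stage-mean TPM quartiles.

    High: TPM >= upper quartile; low: TPM <= lower quartile; medium
    otherwise. Degenerate quartiles (q1 == q3) collapse every gene into
    ``high`` and are logged.
    """
    sm = stage_means(tpm, design)[stage]
    q1, q3 = np.quantile(sm.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        logger.warning("degenerate quartiles at stage %s (q1 == q3 == %g)",
                       stage, q1)
    out = np.where(sm >= q3, "high", np.where(sm <= q1, "low", "medium"))
    return pd.Series(out, index=sm.index, name="class")


@dataclass
class SoftClustering:
    """Fuzzy c-means result on standardised stage trajectories."""

    membership: pd.DataFrame  # genes x clusters, rows sum to 1
    centers: pd.DataFrame     # clusters x stages
    objective: list           # objective value per iteration (non-increasing)
    m: float
    excluded: list            # zero-variance genes left out

    @property
    def hard_labels(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def standardize_trajectories(traj: pd.DataFrame):
    """Z-score rows; zero-variance rows are split off."""
    sd = traj.std(axis=1, ddof=0)
    flat = traj.index[sd == 0]
    kept = traj.drop(index=flat)
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.drop(index=flat), axis=0)
    return z, list(flat)


def soft_cluster(traj: pd.DataFrame, c: int = 6, m: float = 1.25,
                 seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 500) -> SoftClustering:
    """Fuzzy c-means on z-standardised trajectories.

    Alternates the membership update ``u_gk ∝ (1/d_gk^2)^(1/(m-1))`` and the
    weighted center update until the largest center shift falls below
    ``tol`` (or ``max_iter``). Centers are initialised by k-means++-style
    seeded sampling, so a fixed seed reproduces the run exactly.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    z, excluded = standardize_trajectories(traj)
    if excluded:
        logger.info("%d zero-variance genes excluded from clustering",
                    len(excluded))
    X = z.to_numpy(dtype=float)
    n = len(X)
    if n < c:
        raise ValueError(f"cannot form {c} clusters from {n} genes")
    rng = np.random.default_rng(seed)

    # k-means++-style seeding
    centers = np.empty((c, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    for k in range(1, c):
        d2 = np.min(((X[:, None, :] - centers[None, :k, :]) ** 2).sum(-1), axis=1)
        if d2.sum() <= 0:
            centers[k] = X[rng.integers(n)]
        else:
            centers[k] = X[rng.choice(n, p=d2 / d2.sum())]

    expo = 1.0 / (m - 1.0)
    objective = []
    u = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            w = (1.0 / d2) ** expo
        w = np.where(zero, 0.0, w)
        u = np.where(zero.any(axis=1)[:, None],
                     zero / np.maximum(zero.sum(axis=1)[:, None], 1),
                     w / np.maximum(w.sum(axis=1)[:, None], 1e-300))
        objective.append(float((u ** m * d2).sum()))
        um = u ** m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore"):
        w = (1.0 / d2) ** expo
    w = np.where(zero, 0.0, w)
    u = np.where(zero.any(axis=1)[:, None],
                 zero / np.maximum(zero.sum(axis=1)[:, None], 1),
                 w / np.maximum(w.sum(axis=1)[:, None], 1e-300))
    objective.append(float((u ** m * d2).sum()))

    names = [f"cluster{k + 1}" for k in range(c)]
    return SoftClustering(
        membership=pd.DataFrame(u, index=z.index, columns=names),
        centers=pd.DataFrame(centers, index=names, columns=traj.columns),
        objective=objective, m=m, excluded=excluded)
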