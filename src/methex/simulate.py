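"""Synthetic WGBS + RNA-seq dataset generator with planted, exported ground truth.

Builds a miniature genome (a few megabases), a dense gene annotation with
CpG islands at a configurable fraction of promoters, per-sample Bismark-style
cytosine reports, and a negative-binomial read-count matrix for a staged
design (three developmental stages x three replicates by default).

The generator plants three kinds of signal with known truth:

* **DMRs** — 1 kb regions whose true methylation level steps up (hyper) or
  down (hypo) by ``dmr_effect`` between two stages;
* **DEGs** — genes whose expression peaks at one stage with a
  ``dmdeg_lfc`` log2 fold change against the neighbouring stages;
* **DM-DEGs** — genes whose promoter methylation follows per-stage targets
  that decrease (or increase) across stages while expression moves the
  opposite way, i.e. the promoter-methylation-regulated genes the
  integration step is meant to recover.

Everything is driven by a single integer seed; the same seed and config
produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("p21", "p28", "p35")
#: successive stage contrasts (A, B); effects are reported as B relative to A
CONTRASTS = ((STAGES[0], STAGES[1]), (STAGES[1], STAGES[2]))

DEFAULT_DESIGN = tuple((s, r) for s in STAGES for r in (1, 2, 3))

# Beta mixture for true per-site methylation: low mode for promoters/CGIs,
# high mode for gene bodies and intergenic background.
LOW_MODE_MEAN = 0.05
HIGH_MODE_MEAN = 0.8
LOW_MODE_CONC = 10.0
HIGH_MODE_CONC = 20.0  # tight high mode: most gene-body CpGs heavily methylated
PLANTED_SITE_CONC = 50.0  # tight Beta around planted DMR base levels


class SimulationSizeError(ValueError):
    """Genome too small for the requested number of genes."""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named child RNG stream derived from one integer seed."""
    key = zlib.crc32(name.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the standard benchmark: 2 chromosomes x 1 Mb carrying
    2000 genes, 9 samples (3 stages x 3 replicates), ~10 CpG/kb at mean
    10x coverage, 20 planted DMRs (effect 0.4) and 150 planted DM-DEGs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 2000
    n_cpg_per_kb: float = 10.0
    design: tuple = DEFAULT_DESIGN
    mean_coverage: float = 10.0
    dispersion_expression: float = 0.05
    n_deg_per_stage: int = 50
    n_planted_dmr: int = 20
    dmr_length: int = 1000
    dmr_effect: float = 0.4
    n_planted_dmdeg: int = 150
    dmdeg_meth_drop: float = 0.6
    dmdeg_lfc: float = 2.0
    seed: int = 0
    # genome-layout / nuisance knobs (scaled to the miniature genome)
    promoter_window: int = 250
    cgi_promoter_fraction: float = 0.5
    cgi_extra_density: float = 4.0
    noncpg_fraction: float = 0.05
    min_gene_length: int = 300
    max_gene_length: int = 700
    expression_base_mean: float = 200.0
    expression_base_sigma: float = 1.0
    depth_variation: float = 0.2  # +/- range of per-sample library-depth factors

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_cpg_per_kb",
                     "mean_coverage", "dmr_length", "promoter_window",
                     "min_gene_length", "max_gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_deg_per_stage", "n_planted_dmr",
                     "n_planted_dmdeg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.dmr_effect <= 1.0:
            raise ValueError("dmr_effect must lie in (0, 1]")
        if not 0.0 < self.dmdeg_meth_drop <= 1.0:
            raise ValueError("dmdeg_meth_drop must lie in (0, 1]")
        if self.dispersion_expression < 0:
            raise ValueError("dispersion_expression must be >= 0")
        if not 0.0 <= self.noncpg_fraction < 1.0:
            raise ValueError("noncpg_fraction must lie in [0, 1)")
        if not 0.0 <= self.depth_variation < 1.0:
            raise ValueError("depth_variation must lie in [0, 1)")
        if self.min_gene_length > self.max_gene_length:
            raise ValueError("min_gene_length > max_gene_length")
        self.design = tuple((str(s), int(r)) for s, r in self.design)
        unknown = {s for s, _ in self.design} - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in design: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{s}_{r}" for s, r in self.design]

    def design_frame(self) -> pd.DataFrame:
        """Design table: sample id -> (stage, replicate)."""
        return pd.DataFrame(
            {"stage": [s for s, _ in self.design],
             "replicate": [r for _, r in self.design]},
            index=pd.Index(self.sample_ids, name="sample"),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = tuple((s, int(r)) for s, r in d["design"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = [list(x) for x in self.design]
        return d


@dataclass
class GroundTruth:
    """Planted signal: DMR intervals, DEG peak stages, DM-DEG targets.

    Every planted DM-DEG also appears in ``planted_degs``; the promoter
    window used when planting promoter methylation is recorded so the
    evaluation reads promoters at the same width.
    """

    planted_dmrs: pd.DataFrame    # chrom,start,end,direction,stage_a,stage_b
    planted_degs: pd.DataFrame    # gene_id,peak_stage,kind
    planted_dmdegs: pd.DataFrame  # gene_id,target_p21,target_p28,target_p35,expr_direction,peak_stage
    promoter_window: int

    def to_json(self, path) -> None:
        payload = {
            "promoter_window": int(self.promoter_window),
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "planted_degs": self.planted_degs.to_dict(orient="records"),
            "planted_dmdegs": self.planted_dmdegs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_dmrs=pd.DataFrame(
                payload["planted_dmrs"],
                columns=["chrom", "start", "end", "direction", "stage_a", "stage_b"]),
            planted_degs=pd.DataFrame(
                payload["planted_degs"], columns=["gene_id", "peak_stage", "kind"]),
            planted_dmdegs=pd.DataFrame(
                payload["planted_dmdegs"],
                columns=["gene_id", "target_p21", "target_p28", "target_p35",
                         "expr_direction", "peak_stage", "chrom",
                         "promoter_start", "promoter_end"]),
            promoter_window=int(payload["promoter_window"]),
        )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig):
    """Lay out non-overlapping genes on both strands plus CpG islands.

    Each chromosome is divided into equal slots, one gene per slot, placed so
    that the gene's promoter (TSS +/- ``promoter_window``) stays inside its
    slot. A configurable fraction of genes receives a CpG island spanning the
    TSS; one island per chromosome is emitted regardless of gene count.

    Returns ``(genes, cgis)`` data frames (1-based inclusive coordinates).
    """
    rng = _stream(config.seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    nchrom = config.n_chromosomes
    per_chrom = [config.n_genes // nchrom + (1 if i < config.n_genes % nchrom else 0)
                 for i in range(nchrom)]

    pw = config.promoter_window
    rows = []
    gid = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = config.chrom_length // k
        required = max(config.max_gene_length + pw, 2 * pw + 1)
        if slot < required:
            raise SimulationSizeError(
                f"cannot place {config.n_genes} genes on {nchrom} x "
                f"{config.chrom_length} bp: per-gene slot {slot} bp < "
                f"{required} bp needed for a {config.max_gene_length} bp gene "
                f"with a +/-{pw} bp promoter")
        for j in range(k):
            s0 = j * slot  # slot spans [s0+1, s0+slot]
            length = int(rng.integers(config.min_gene_length,
                                      config.max_gene_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start = s0 + pw + 1
                end = start + length - 1
            else:
                end = s0 + slot - pw
                start = end - length + 1
            tss = start if strand == "+" else end
            tes = end if strand == "+" else start
            rows.append((f"g{gid:05d}", chrom, strand, start, end, tss, tes,
                         length, s0 + 1, s0 + slot))
            gid += 1
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss",
                       "tes", "length", "slot_start", "slot_end"])

    cgi_rows = []
    # per-chromosome seed island so islands exist even with no genes
    for chrom in chroms:
        cgi_rows.append((chrom, 101, min(700, config.chrom_length)))
    if len(genes):
        n_cgi = int(round(config.cgi_promoter_fraction * len(genes)))
        chosen = np.sort(rng.choice(len(genes), size=n_cgi, replace=False))
        has_cgi = np.zeros(len(genes), dtype=bool)
        has_cgi[chosen] = True
        for i in chosen:
            g = genes.iloc[i]
            cgi_rows.append((g.chrom, max(1, g.tss - 100),
                             min(config.chrom_length, g.tss + 150)))
        genes["has_cgi"] = has_cgi
    else:
        genes["has_cgi"] = pd.Series(dtype=bool)
    cgis = (pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))
    return genes, cgis


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def plant_truth(genes: pd.DataFrame, config: SimulationConfig) -> GroundTruth:
    """Choose the planted DMR intervals, DEGs and DM-DEGs.

    DM-DEGs are sampled from genes with CpG-island promoters (the class the
    correlation analysis targets, and guaranteed to carry enough promoter
    CpGs); plain DEGs from the remaining genes; DMRs occupy the slots of
    genes that carry no planted expression signal, so the planted categories
    stay disjoint.
    """
    rng = _stream(config.seed, "truth")
    n_deg = 3 * config.n_deg_per_stage
    n_dmdeg = config.n_planted_dmdeg

    cgi_ids = genes.loc[genes["has_cgi"], "gene_id"].to_numpy() if len(genes) else np.array([])
    other_ids = genes.loc[~genes["has_cgi"], "gene_id"].to_numpy() if len(genes) else np.array([])
    if n_dmdeg > len(cgi_ids):
        raise SimulationSizeError(
            f"{n_dmdeg} DM-DEGs requested but only {len(cgi_ids)} genes have "
            f"CpG-island promoters (cgi_promoter_fraction too low)")
    dmdeg_ids = np.sort(rng.choice(cgi_ids, size=n_dmdeg, replace=False))
    pool = np.concatenate([np.setdiff1d(cgi_ids, dmdeg_ids), other_ids])
    if n_deg > len(pool):
        raise SimulationSizeError(
            f"{n_deg} plain DEGs requested but only {len(pool)} genes remain")
    deg_ids = np.sort(rng.choice(pool, size=n_deg, replace=False))

    hi = min(0.9, 0.2 + config.dmdeg_meth_drop)
    lo = max(0.02, hi - config.dmdeg_meth_drop)
    mid = (hi + lo) / 2.0
    gx = genes.set_index("gene_id") if len(genes) else genes
    dmdeg_rows = []
    for i, g in enumerate(dmdeg_ids):
        if i % 2 == 0:  # methylation falls, expression rises
            targets, direction, peak = (hi, mid, lo), "falling", STAGES[2]
        else:           # methylation rises, expression falls
            targets, direction, peak = (lo, mid, hi), "rising", STAGES[0]
        row = gx.loc[g]
        dmdeg_rows.append((g, *targets, direction, peak, row["chrom"],
                           max(1, int(row["tss"]) - config.promoter_window),
                           int(row["tss"]) + config.promoter_window))
    planted_dmdegs = pd.DataFrame(
        dmdeg_rows, columns=["gene_id", "target_p21", "target_p28",
                             "target_p35", "expr_direction", "peak_stage",
                             "chrom", "promoter_start", "promoter_end"])

    deg_rows = [(g, STAGES[i // max(config.n_deg_per_stage, 1)], "deg")
                for i, g in enumerate(deg_ids)]
    deg_rows += [(r.gene_id, r.peak_stage, "dmdeg")
                 for r in planted_dmdegs.itertuples()]
    planted_degs = (pd.DataFrame(deg_rows,
                                 columns=["gene_id", "peak_stage", "kind"])
                    .sort_values("gene_id").reset_index(drop=True))

    planted = set(planted_degs["gene_id"])
    free = genes.loc[~genes["gene_id"].isin(planted)] if len(genes) else genes
    if config.n_planted_dmr > len(free):
        raise SimulationSizeError(
            f"{config.n_planted_dmr} DMRs requested but only {len(free)} "
            f"unplanted gene slots remain")
    dmr_rows = []
    if config.n_planted_dmr:
        picks = np.sort(rng.choice(len(free), size=config.n_planted_dmr,
                                   replace=False))
        for i, ix in enumerate(picks):
            g = free.iloc[ix]
            start = int(g.slot_start)
            end = min(int(g.slot_end), start + config.dmr_length - 1)
            direction = "hyper" if i % 2 == 0 else "hypo"
            stage_a, stage_b = CONTRASTS[(i // 2) % 2]
            dmr_rows.append((g.chrom, start, end, direction, stage_a, stage_b))
    planted_dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "direction",
                           "stage_a", "stage_b"])
    return GroundTruth(planted_dmrs, planted_degs, planted_dmdegs,
                       promoter_window=config.promoter_window)


# ---------------------------------------------------------------------------
# per-gene baselines shared between methylome and expression
# ---------------------------------------------------------------------------

def _gene_baselines(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Baseline expression mean and promoter methylation mean per gene.

    Promoter methylation is anti-coupled to baseline expression rank through
    a sharp sigmoid — highly expressed genes get hypomethylated promoters
    (~0.05), weakly expressed genes nearly fully methylated ones (~0.85),
    with few promoters at intermediate levels, mirroring the empirical
    dichotomy between active CGI promoters and silenced ones. This coupling
    is what gives the metagene profiles their expression-stratified TSS dip.
    """
    rng = _stream(config.seed, "baselines")
    n = len(genes)
    base_mu = rng.lognormal(np.log(config.expression_base_mean),
                            config.expression_base_sigma, size=n)
    if n > 1:
        pct = pd.Series(base_mu).rank(method="first").to_numpy() / n
    else:
        pct = np.ones(n)
    prom_meth = 0.05 + 0.80 / (1.0 + np.exp((pct - 0.35) / 0.07))
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                         "base_mu": base_mu, "prom_meth": prom_meth})


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _interval_lookup(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray):
    """Index of the (sorted, non-overlapping) interval containing each pos, -1 if none."""
    if len(starts) == 0:
        return np.full(len(pos), -1)
    ix = np.searchsorted(starts, pos, side="right") - 1
    ok = (ix >= 0) & (pos <= ends[np.clip(ix, 0, None)])
    return np.where(ok, ix, -1)


def simulate_methylome(genes, cgis, truth: GroundTruth, config: SimulationConfig):
    """Per-sample cytosine report tables with planted methylation signal.

    True per-site levels come from a Beta mixture conditioned on feature
    class (promoter/CGI low, elsewhere high); planted DMR and DM-DEG sites
    get stage-dependent true levels. Observed counts are binomial draws at
    Poisson per-site coverage; a small fraction of CHG/CHH records is mixed
    in so context filtering has work to do. Returns ``{sample_id: DataFrame}``
    with Bismark cytosine-report columns.
    """
    rng = _stream(config.seed, "methylome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    design = config.design_frame()
    pw = truth.promoter_window

    # ---- CpG positions ----------------------------------------------------
    all_chrom, all_pos = [], []
    for chrom in chroms:
        n_base = int(round(config.chrom_length / 1000.0 * config.n_cpg_per_kb))
        pos = rng.choice(config.chrom_length, size=n_base, replace=False) + 1
        extra = []
        sub = cgis[cgis["chrom"] == chrom]
        for r in sub.itertuples():
            span = r.end - r.start + 1
            m = int(round(span / 1000.0 * config.n_cpg_per_kb
                          * (config.cgi_extra_density - 1.0)))
            if m > 0:
                extra.append(rng.integers(r.start, r.end + 1, size=m))
        if extra:
            pos = np.concatenate([pos, *extra])
        pos = np.unique(pos)
        all_chrom.append(np.repeat(chrom, len(pos)))
        all_pos.append(pos)
    chrom_arr = np.concatenate(all_chrom) if all_chrom else np.array([], dtype=object)
    pos_arr = np.concatenate(all_pos) if all_pos else np.array([], dtype=int)
    n_sites = len(pos_arr)

    # ---- true stage-level matrix -----------------------------------------
    base_mean = np.full(n_sites, HIGH_MODE_MEAN)
    base_conc = np.full(n_sites, HIGH_MODE_CONC)
    gene_of_site = np.full(n_sites, -1)  # promoter owner

    baselines = _gene_baselines(genes, config).set_index("gene_id")
    dmdeg_set = set(truth.planted_dmdegs["gene_id"])
    dmdeg_targets = truth.planted_dmdegs.set_index("gene_id")

    for chrom in chroms:
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        pos = pos_arr[mask]
        sub_genes = genes[genes["chrom"] == chrom] if len(genes) else genes
        if len(sub_genes):
            prom = sub_genes.assign(
                ps=np.maximum(1, sub_genes["tss"] - pw),
                pe=sub_genes["tss"] + pw).sort_values("ps")
            hit = _interval_lookup(prom["ps"].to_numpy(), prom["pe"].to_numpy(), pos)
            owner = np.where(hit >= 0, prom.index.to_numpy()[np.clip(hit, 0, None)], -1)
            gene_of_site[mask] = owner
        sub_cgi = cgis[cgis["chrom"] == chrom].sort_values("start")
        in_cgi = _interval_lookup(sub_cgi["start"].to_numpy(),
                                  sub_cgi["end"].to_numpy(), pos) >= 0
        # promoters take their gene's coupled mean; bare CGIs take the low mode
        bm = base_mean[mask]
        bc = base_conc[mask]
        owner = gene_of_site[mask]
        in_prom = owner >= 0
        if in_prom.any():
            gid = genes["gene_id"].to_numpy()[owner[in_prom]]
            bm[in_prom] = baselines.loc[gid, "prom_meth"].to_numpy()
            bc[in_prom] = LOW_MODE_CONC
        bare = in_cgi & ~in_prom
        bm[bare] = LOW_MODE_MEAN
        bc[bare] = LOW_MODE_CONC
        base_mean[mask] = bm
        base_conc[mask] = bc

    mu = rng.beta(base_mean * base_conc, (1.0 - base_mean) * base_conc)
    level = np.repeat(mu[:, None], len(STAGES), axis=1)

    # planted DMRs override whatever sits in their interval
    for r in truth.planted_dmrs.itertuples():
        m = (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr <= r.end)
        k = int(m.sum())
        if k == 0:
            continue
        base = 0.25 if r.direction == "hyper" else 0.75
        mu0 = rng.beta(base * PLANTED_SITE_CONC,
                       (1.0 - base) * PLANTED_SITE_CONC, size=k)
        shift = config.dmr_effect if r.direction == "hyper" else -config.dmr_effect
        sb = STAGES.index(r.stage_b)
        lv = np.repeat(mu0[:, None], len(STAGES), axis=1)
        lv[:, sb:] = np.clip(lv[:, sb:] + shift, 0.01, 0.99)
        level[m] = lv

    # planted DM-DEG promoters follow per-stage targets
    if dmdeg_set:
        owner_gid = np.where(gene_of_site >= 0,
                             genes["gene_id"].to_numpy()[np.clip(gene_of_site, 0, None)],
                             "")
        m = np.isin(owner_gid, list(dmdeg_set))
        idx = np.flatnonzero(m)
        offsets = rng.normal(0.0, 0.03, size=len(idx))
        tgt = dmdeg_targets.loc[
            owner_gid[idx], ["target_p21", "target_p28", "target_p35"]].to_numpy()
        level[idx] = np.clip(tgt + offsets[:, None], 0.01, 0.99)

    # ---- non-CpG records --------------------------------------------------
    f = config.noncpg_fraction
    nc_chrom, nc_pos = [], []
    if f > 0:
        for chrom in chroms:
            k = int((chrom_arr == chrom).sum())
            m = int(round(f / (1.0 - f) * k))
            if m == 0:
                continue
            taken = set(pos_arr[chrom_arr == chrom].tolist())
            cand = rng.choice(config.chrom_length, size=min(2 * m + 10, config.chrom_length),
                              replace=False) + 1
            cand = np.array([p for p in cand if p not in taken])[:m]
            nc_chrom.append(np.repeat(chrom, len(cand)))
            nc_pos.append(np.sort(cand))
    nc_chrom = np.concatenate(nc_chrom) if nc_chrom else np.array([], dtype=object)
    nc_pos = np.concatenate(nc_pos) if nc_pos else np.array([], dtype=int)
    nc_context = np.where(np.arange(len(nc_pos)) % 2 == 0, "CHG", "CHH")
    nc_level = 0.02

    # ---- observed counts per sample --------------------------------------
    reports = {}
    stage_idx = [STAGES.index(s) for s in design["stage"]]
    for sample, sidx in zip(design.index, stage_idx):
        cov = rng.poisson(config.mean_coverage, size=n_sites)
        meth = rng.binomial(cov, level[:, sidx])
        cov_nc = rng.poisson(config.mean_coverage, size=len(nc_pos))
        meth_nc = rng.binomial(cov_nc, nc_level)
        df = pd.DataFrame({
            "chrom": np.concatenate([chrom_arr, nc_chrom]),
            "pos": np.concatenate([pos_arr, nc_pos]).astype(int),
            "strand": "+",
            "count_methylated": np.concatenate([meth, meth_nc]).astype(int),
            "count_unmethylated": np.concatenate([cov - meth, cov_nc - meth_nc]).astype(int),
            "context": np.concatenate([np.repeat("CpG", n_sites), nc_context]),
        }).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        reports[sample] = df
    return reports


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(genes, truth: GroundTruth, config: SimulationConfig):
    """Negative-binomial count matrix with planted stage trajectories.

    Plain planted DEGs have their peak stage elevated by ``2**dmdeg_lfc``;
    planted DM-DEGs follow a monotone geometric trajectory (successive
    log2 fold changes of ``dmdeg_lfc``) whose direction opposes their
    promoter-methylation targets. Returns ``(counts, lengths, design)``.
    """
    rng = _stream(config.seed, "expression")
    design = config.design_frame()
    n = len(genes)
    baselines = _gene_baselines(genes, config)
    base = baselines["base_mu"].to_numpy()

    mult = np.ones((n, len(STAGES)))
    gindex = pd.Index(genes["gene_id"])
    for r in truth.planted_degs.itertuples():
        if r.kind != "deg":
            continue
        i = gindex.get_loc(r.gene_id)
        mult[i, STAGES.index(r.peak_stage)] = 2.0 ** config.dmdeg_lfc
    ramp = 2.0 ** (config.dmdeg_lfc * np.arange(len(STAGES)))
    for r in truth.planted_dmdegs.itertuples():
        i = gindex.get_loc(r.gene_id)
        mult[i] = ramp if r.expr_direction == "falling" else ramp[::-1]

    dv = config.depth_variation
    depth = rng.uniform(1.0 - dv, 1.0 + dv, size=len(design))
    counts = np.empty((n, len(design)), dtype=np.int64)
    disp = config.dispersion_expression
    for j, (sample, row) in enumerate(design.iterrows()):
        mu_s = base * mult[:, STAGES.index(row["stage"])] * depth[j]
        if disp < 1e-8:
            counts[:, j] = rng.poisson(mu_s)
        else:
            nb_n = 1.0 / disp
            counts[:, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_s))
    counts = pd.DataFrame(counts, index=gindex.rename("gene_id"),
                          columns=design.index)
    lengths = pd.Series(genes["length"].to_numpy(), index=gindex.rename("gene_id"),
                        name="length")
    return counts, lengths, design


# ---------------------------------------------------------------------------
# orchestration + writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: pd.DataFrame
    cgis: pd.DataFrame
    truth: GroundTruth
    reports: dict
    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run all three generators under one seed and bundle the results."""
    config = config or SimulationConfig()
    genes, cgis = simulate_annotation(config)
    truth = plant_truth(genes, config)
    reports = simulate_methylome(genes, cgis, truth, config)
    counts, lengths, design = simulate_expression(genes, truth, config)
    return SimulatedDataset(config, genes, cgis, truth, reports, counts,
                            lengths, design)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset as plain-text files (TSV/BED/JSON).

    BED files are 0-based half-open at the boundary; everything in memory is
    1-based inclusive.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, df in ds.reports.items():
        df.to_csv(out / f"{sample}.cytosine_report.tsv", sep="\t",
                  header=False, index=False)
    bed = ds.genes.assign(bed_start=ds.genes["start"] - 1, score=0)
    bed[["chrom", "bed_start", "end", "gene_id", "score", "strand",
         "length"]].to_csv(out / "genes.bed", sep="\t", header=False, index=False)
    cgi = ds.cgis.assign(bed_start=ds.cgis["start"] - 1)
    cgi[["chrom", "bed_start", "end"]].to_csv(out / "cgis.bed", sep="\t",
                                              header=False, index=False)
    ds.counts.to_csv(out / "counts.tsv", sep="\t")
    ds.lengths.to_csv(out / "gene_lengths.tsv", sep="\t")
    ds.design.to_csv(out / "design.tsv", sep="\t")
    ds.truth.to_json(out / "truth.json")
    (out / "config.json").write_text(json.dumps(ds.config.to_dict(), indent=1) + "\n")
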