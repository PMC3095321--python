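"""Seeded synthetic ChIP-Seq dataset generator.

Produces a toy multi-chromosome genome with non-overlapping genes, per-gene
transcript levels spanning expression quintiles, and read sets for four
chromatin samples (H3, H3K4me1, H3K4me2, H3K4me3) plus an input-DNA control
in two conditions (watered / dehydration-stressed), with planted structure:

* H3K4me3: a 5' peak ~300 bp downstream of the TSS, rising exponentially to
  the peak and decaying exponentially toward the 3' end; height saturates
  with transcript level; present on all of the top two expression quintiles,
  most of the third, a minority of the second, and none of the lowest.
* H3K4me1: near-uniform over gene bodies with a 5' elevation confined to the
  *least* expressed genes.
* H3K4me2: flat over gene bodies, independent of expression.
* H3: near-uniform genome-wide with slight genic enrichment and a
  nucleosome-depleted dip immediately upstream of the TSS for the top three
  expression quintiles.

The methylation marks are targeted ChIPs, so their intergenic space is
modelled as a low nonspecific floor plus scattered nonspecific "sticky"
islands whose mass brings the intergenic *mean* coverage up to the configured
background level -- mirroring real data, where the marks are practically
absent between genes yet the run's intergenic mean is a few reads deep, and
where a minority of called peaks is intergenic. Island positions are shared
across marks and conditions (sticky regions are a property of the material,
not the antibody).
* Conditions: a configurable fraction of genes is up-/down-regulated with
  |fold| log-uniform in [4, 150]; their H3K4me3 peak height shifts by an
  amount proportional to log2|fold| (up gains, down loses), H3K4me1 changes
  slightly in the opposite direction, and H3K4me2 does not change. A fraction
  of the up-regulated ("inducible") genes carries a broad H3K4me3 profile
  (3x longer 3' decay) in both conditions.
* Input DNA: flat intensity with sampling noise only.

Reads are drawn by inhomogeneous Poisson sampling: read centers are sampled
from the per-base intensity (in coverage units), so the expected coverage
profile reproduces the planted shapes up to the 35 bp footprint smoothing. A
negative-binomial switch adds overdispersion in the total read count for
robustness testing. Everything is deterministic under a fixed seed.

What this emulates -- and what it does not: coordinates only (no nucleotide
sequence, no mappability structure), single-exon genes (no computation in this
package looks at exon structure), and independent-read Poisson noise (no
duplicate-read artifacts or GC bias).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations_io import (
    ExpressionRecord,
    GeneModel,
    Genome,
    write_expression,
    write_genes,
    write_genome_sizes,
)
from .coverage import ReadAlignment
from .metagene import resample_body

log = logging.getLogger(__name__)

MARKS = ("H3", "H3K4me1", "H3K4me2", "H3K4me3")
CONDITIONS = ("watered", "stressed")
INPUT = "input"
SAMPLES = tuple((m, c) for c in CONDITIONS for m in MARKS + (INPUT,))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset (all tunables, with units)."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 500_000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (800, 3000)  # bp, log-uniform
    min_gap: int = 200  # bp between genes and at chromosome ends
    gap_dirichlet_alpha: float = 0.25  # heavy-tailed intergenic gap sizes

    # expression law: log-normal transcript levels define the quintiles
    expr_log_mean: float = 3.0
    expr_log_sd: float = 1.2

    # differential expression
    frac_up: float = 0.05
    frac_down: float = 0.05
    fold_range: tuple[float, float] = (4.0, 150.0)  # |fold|, log-uniform
    frac_broad: float = 0.5  # fraction of up-regulated genes with broad me3

    # sequencing
    read_length: int = 35
    background: float = 2.5  # intergenic mean coverage; the assay's range is ~1.1-3.25
    nonspecific_rate: float = 0.25  # methylation-ChIP coverage floor off-target
    island_height: float = 10.0  # nonspecific sticky-island coverage
    island_width: int = 350  # bp
    island_margin: int = 100  # bp clearance between an island and any gene
    input_depth_factor: float = 1.0
    negative_binomial: bool = False
    nb_dispersion: float = 20.0  # NB shape for the total read count

    # H3K4me3 shape (coverage units)
    me3_offset: int = 300  # peak position downstream of TSS, bp
    me3_rise: float = 150.0  # 5' exponential rise length, bp
    me3_decay: float = 400.0  # 3' exponential decay length, bp
    broad_decay_mult: float = 3.0
    me3_height_max: float = 9.0  # saturating height = max * level / (level + k)
    me3_level_k: float = 15.0
    me3_quintile_marked: tuple[float, ...] = (0.0, 0.3, 0.8, 1.0, 1.0)
    # response size in mean-coverage units over the gene body per log2 |fold|
    # (peak-height shifts are rescaled by gene length so the planted change in
    # per-gene mean coverage tracks the fold change, not the gene's size)
    me3_response_gain: float = 1.6

    # H3K4me1 shape
    me1_marked: float = 0.89  # among non-silent genes
    me1_body: float = 4.0
    me1_body_log_sd: float = 0.3
    me1_bump: float = 10.0  # 5' elevation at the TSS of low-expressed genes
    me1_bump_decay: float = 250.0
    me1_bump_by_quintile: tuple[float, ...] = (1.0, 0.3, 0.15, 0.05, 0.0)
    me1_up_factor: float = 0.85  # stressed me1 multiplier on up-regulated genes
    me1_down_factor: float = 1.15

    # H3K4me2 shape
    me2_marked: float = 0.93
    me2_body: float = 5.0
    me2_body_log_sd: float = 0.4

    # H3 shape
    h3_genic_gain: float = 0.3  # genic enrichment as a fraction of background
    nfr_depth: float = 0.5  # dip depth as a fraction of background
    nfr_center: int = -150  # bp relative to TSS
    nfr_sd: float = 70.0
    nfr_min_quintile: int = 3  # dip planted on quintiles >= this

    # probability a gene carries no mark at all, per expression quintile
    silent_by_quintile: tuple[float, ...] = (0.35, 0.12, 0.02, 0.005, 0.0)

    def validate(self) -> None:
        for name in ("frac_up", "frac_down", "frac_broad", "me1_marked", "me2_marked"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (lo, hi)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([cfg.seed, stream])


def generate_genome_and_genes(
    cfg: SyntheticConfig,
) -> tuple[Genome, list[GeneModel], pd.DataFrame]:
    """Build the genome, a non-overlapping gene set, and the ground-truth table.

    The truth table records, per gene, its planted expression level and
    quintile, response class (up/down/none), broad-profile flag, and which
    marks it carries.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    genome = Genome({f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chrom)})

    counts = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        counts[i] += 1

    lo, hi = cfg.gene_length_range
    genes: list[GeneModel] = []
    rows = []
    for ci, (chrom, n_c) in enumerate(zip(genome.names, counts)):
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_c)).astype(int)
        needed = int(lengths.sum()) + (n_c + 1) * cfg.min_gap
        if needed > cfg.chrom_len:
            raise ValueError(
                f"cannot pack {n_c} genes (need {needed} bp) into {chrom} "
                f"({cfg.chrom_len} bp); reduce n_genes or gene lengths"
            )
        slack = cfg.chrom_len - needed
        # heavy-tailed gap sizes: most gaps near the minimum, a few large
        frac = rng.dirichlet(np.full(n_c + 1, cfg.gap_dirichlet_alpha))
        extra = np.floor(frac * slack).astype(int)
        extra[-1] += slack - int(extra.sum())
        strands = [str(s) for s in rng.choice(["+", "-"], size=n_c)]
        pos = cfg.min_gap + int(extra[0])
        for gi in range(n_c):
            start, end = pos, pos + int(lengths[gi])
            gene_id = f"S{ci + 1}G{gi + 1:04d}"
            genes.append(GeneModel(gene_id, chrom, start, end, strands[gi]))
            rows.append((gene_id, chrom, start, end, strands[gi], end - start))
            pos = end + cfg.min_gap + int(extra[gi + 1])

    truth = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "length"]
    )
    n = len(truth)

    # transcript levels and expression quintiles (5 = highest)
    levels = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=n)
    truth["level_watered"] = levels
    order = np.argsort(levels, kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base + 1] * rem + [base] * (5 - rem)
    quintile = np.empty(n, dtype=int)
    posn = 0
    for q, size in enumerate(sizes, start=1):
        quintile[order[posn : posn + size]] = q
        posn += size
    truth["quintile"] = quintile

    # response classes: down-regulated genes are drawn from the expressed
    # quintiles (a repressed gene must first be expressed); up-regulated from
    # anywhere else
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    response = np.array(["none"] * n, dtype=object)
    down_pool = np.flatnonzero(quintile >= 3)
    down_idx = rng.choice(down_pool, size=n_down, replace=False)
    response[down_idx] = "down"
    up_pool = np.flatnonzero(response == "none")
    up_idx = rng.choice(up_pool, size=n_up, replace=False)
    response[up_idx] = "up"
    truth["response"] = response

    broad = np.zeros(n, dtype=bool)
    n_broad = int(round(cfg.frac_broad * n_up))
    if n_broad:
        broad[rng.choice(up_idx, size=n_broad, replace=False)] = True
    truth["broad"] = broad

    # mark presence: silent genes (mostly low-expressed) carry nothing;
    # responsive genes always carry me3 so condition shifts are observable
    silent_p = np.asarray(cfg.silent_by_quintile)[quintile - 1]
    silent = (rng.random(n) < silent_p) & (response == "none")
    truth["silent"] = silent
    me3_p = np.asarray(cfg.me3_quintile_marked)[quintile - 1]
    truth["has_me3"] = (~silent) & ((rng.random(n) < me3_p) | (response != "none"))
    truth["has_me1"] = (~silent) & (rng.random(n) < cfg.me1_marked)
    truth["has_me2"] = (~silent) & (rng.random(n) < cfg.me2_marked)
    truth["me1_level"] = np.where(
        truth.has_me1, cfg.me1_body * rng.lognormal(0.0, cfg.me1_body_log_sd, n), 0.0
    )
    truth["me2_level"] = np.where(
        truth.has_me2, cfg.me2_body * rng.lognormal(0.0, cfg.me2_body_log_sd, n), 0.0
    )
    truth["level_stressed"] = np.nan
    truth["fold_change"] = np.nan
    truth["p_value"] = np.nan
    return genome, genes, truth


def generate_expression(
    cfg: SyntheticConfig, truth: pd.DataFrame
) -> list[ExpressionRecord]:
    """Fill fold changes and p-values into the truth table; return the records.

    Responsive genes get |fold| log-uniform in ``fold_range`` with p uniform
    in [1e-6, 1e-3]; unchanged genes get |fold| <= 1.2 with p uniform in
    [0.5, 1], so the published thresholds (4-fold, p <= 0.001) separate the
    classes exactly.
    """
    rng = _rng(cfg, 2)
    n = len(truth)
    lo, hi = cfg.fold_range
    fold = np.empty(n)
    p = np.empty(n)
    ratio = np.empty(n)

    resp = truth["response"].to_numpy()
    for which, sign in (("up", +1), ("down", -1)):
        idx = np.flatnonzero(resp == which)
        f = np.exp(rng.uniform(np.log(lo), np.log(hi), size=idx.size))
        fold[idx] = sign * f
        ratio[idx] = f if sign > 0 else 1.0 / f
        p[idx] = rng.uniform(1e-6, 1e-3, size=idx.size)
    idx = np.flatnonzero(resp == "none")
    r = np.exp(rng.uniform(np.log(1 / 1.2), np.log(1.2), size=idx.size))
    fold[idx] = np.where(r >= 1, r, -1.0 / r)
    ratio[idx] = r
    p[idx] = rng.uniform(0.5, 1.0, size=idx.size)

    truth["fold_change"] = fold
    truth["p_value"] = p
    truth["level_stressed"] = truth["level_watered"].to_numpy() * ratio
    return [
        ExpressionRecord(
            gene_id=row.gene_id,
            level_watered=float(row.level_watered),
            level_stressed=float(row.level_stressed),
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
        )
        for row in truth.itertuples(index=False)
    ]


def _me3_heights(cfg: SyntheticConfig, truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Watered/stressed me3 peak heights per gene (coverage units).

    Base height saturates with the watered transcript level (nucleosome
    methylation cannot exceed full occupancy); responsive genes shift by
    ``me3_response_gain * log2|fold|``: up-regulated genes gain that amount
    under stress, down-regulated genes carry it in the watered state and lose
    it.
    """
    level = truth.level_watered.to_numpy()
    base = np.where(
        truth.has_me3, cfg.me3_height_max * level / (level + cfg.me3_level_k), 0.0
    )
    # height shift that changes the per-gene *mean* coverage by
    # me3_response_gain per log2|fold|: unit-height shape area -> height units
    L = truth.length.to_numpy().astype(float)
    broad = truth.broad.to_numpy()
    decay = cfg.me3_decay * np.where(broad, cfg.broad_decay_mult, 1.0)
    unit_area = cfg.me3_rise * (1.0 - np.exp(-cfg.me3_offset / cfg.me3_rise)) + decay * (
        1.0 - np.exp(-(L - cfg.me3_offset) / decay)
    )
    gain = (
        cfg.me3_response_gain
        * np.log2(np.abs(truth.fold_change.to_numpy()))
        * L
        / unit_area
    )
    h_w = base.copy()
    h_s = base.copy()
    resp = truth["response"].to_numpy()
    h_s[resp == "up"] = base[resp == "up"] + gain[resp == "up"]
    h_w[resp == "down"] = base[resp == "down"] + gain[resp == "down"]
    return h_w, h_s


def me3_body_shape(
    cfg: SyntheticConfig, length: int, height: float, broad: bool
) -> np.ndarray:
    """Expected me3 coverage over a gene body of ``length`` bp."""
    d = np.arange(length)
    decay = cfg.me3_decay * (cfg.broad_decay_mult if broad else 1.0)
    return height * np.where(
        d < cfg.me3_offset,
        np.exp((d - cfg.me3_offset) / cfg.me3_rise),
        np.exp(-(d - cfg.me3_offset) / decay),
    )


def nonspecific_islands(
    cfg: SyntheticConfig, truth: pd.DataFrame, genome: Genome
) -> list[tuple[str, int, int]]:
    """Intergenic sticky-island intervals shared by all methylation samples.

    Islands carry the nonspecific pulldown mass that lifts the intergenic
    mean coverage of the methylation ChIPs from the off-target floor up to
    ``cfg.background``. They never come within ``island_margin`` bp of a gene.
    Deterministic under the config seed.
    """
    rng = _rng(cfg, 4)
    # intergenic gaps per chromosome, from the packed gene layout
    gaps: list[tuple[str, int, int]] = []
    intergenic_len = 0
    for chrom, length in genome.items():
        spans = truth.loc[truth.chrom == chrom, ["start", "end"]].sort_values("start")
        pos = 0
        for s, e in spans.itertuples(index=False):
            if s > pos:
                gaps.append((chrom, pos, s))
            pos = e
        if pos < length:
            gaps.append((chrom, pos, length))
        intergenic_len += length - int((spans.end - spans.start).sum())

    need = max(cfg.background - cfg.nonspecific_rate, 0.0) * intergenic_len
    per_island = (cfg.island_height - cfg.nonspecific_rate) * cfg.island_width
    n_islands = int(round(need / per_island)) if per_island > 0 else 0
    usable = [
        (chrom, s + cfg.island_margin, e - cfg.island_margin - cfg.island_width)
        for chrom, s, e in gaps
        if (e - s) >= cfg.island_width + 2 * cfg.island_margin
    ]
    if not usable or n_islands == 0:
        return []
    weights = np.array([hi - lo + 1 for _, lo, hi in usable], dtype=float)
    weights /= weights.sum()
    choices = rng.choice(len(usable), size=n_islands, p=weights)
    islands = []
    for gi in choices:
        chrom, lo, hi = usable[gi]
        start = int(rng.integers(lo, hi + 1))
        islands.append((chrom, start, start + cfg.island_width))
    return sorted(islands)


def _intensity(
    cfg: SyntheticConfig,
    truth: pd.DataFrame,
    genome: Genome,
    mark: str,
    condition: str,
    islands: list[tuple[str, int, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-base expected coverage (intensity) for one sample."""
    if mark == INPUT:
        level = cfg.background * cfg.input_depth_factor
        return {c: np.full(length, level) for c, length in genome.items()}
    if mark == "H3":
        # total H3 is everywhere; genic enrichment and NFR dips added below
        lam = {c: np.full(length, float(cfg.background)) for c, length in genome.items()}
    else:
        # targeted methylation ChIP: low off-target floor + sticky islands
        lam = {c: np.full(length, float(cfg.nonspecific_rate)) for c, length in genome.items()}
        if islands is None:
            islands = nonspecific_islands(cfg, truth, genome)
        for chrom, s, e in islands:
            lam[chrom][s:e] += cfg.island_height - cfg.nonspecific_rate
    h_w, h_s = _me3_heights(cfg, truth)
    heights = h_w if condition == "watered" else h_s

    for i, row in enumerate(truth.itertuples(index=False)):
        arr = lam[row.chrom]
        L = row.length
        if mark == "H3K4me3":
            h = heights[i]
            if h <= 0:
                continue
            shape = me3_body_shape(cfg, L, h, row.broad)
        elif mark == "H3K4me1":
            if row.me1_level <= 0:
                continue
            factor = 1.0
            if condition == "stressed" and row.response == "up":
                factor = cfg.me1_up_factor
            elif condition == "stressed" and row.response == "down":
                factor = cfg.me1_down_factor
            d = np.arange(L)
            bump = cfg.me1_bump * cfg.me1_bump_by_quintile[row.quintile - 1]
            shape = factor * (row.me1_level + bump * np.exp(-d / cfg.me1_bump_decay))
        elif mark == "H3K4me2":
            if row.me2_level <= 0:
                continue
            shape = np.full(L, row.me2_level)
        elif mark == "H3":
            shape = np.full(L, cfg.background * cfg.h3_genic_gain)
        else:
            raise ValueError(f"unknown mark {mark!r}")

        if row.strand == "-":
            shape = shape[::-1]
        arr[row.start : row.end] += shape

        if mark == "H3" and row.quintile >= cfg.nfr_min_quintile:
            # nucleosome-depleted dip immediately upstream of the TSS
            reach = int(4 * cfg.nfr_sd - cfg.nfr_center)
            if row.strand == "+":
                p0 = max(row.start - reach, 0)
                u = np.arange(p0 - row.start, 0)  # upstream offsets, negative
                seg = slice(p0, row.start)
            else:
                p1 = min(row.end + reach, arr.size)
                u = (row.end - 1) - np.arange(row.end, p1)
                seg = slice(row.end, p1)
            dip = cfg.nfr_depth * cfg.background * np.exp(
                -((u - cfg.nfr_center) ** 2) / (2 * cfg.nfr_sd**2)
            )
            arr[seg] -= dip

    floor = 0.01 * cfg.background
    return {c: np.maximum(v, floor) for c, v in lam.items()}


def _sample_reads_from_intensity(
    lam: dict[str, np.ndarray], cfg: SyntheticConfig, rng: np.random.Generator
) -> list[ReadAlignment]:
    """Draw reads whose centers follow the intensity; coverage mass is conserved."""
    reads: list[ReadAlignment] = []
    half = cfg.read_length // 2
    for chrom in lam:
        intensity = lam[chrom]
        total = float(intensity.sum())
        expected = total / cfg.read_length
        if cfg.negative_binomial:
            # NB via gamma-Poisson mixture: mean preserved, overdispersed
            shape = cfg.nb_dispersion
            n_reads = int(rng.poisson(rng.gamma(shape, expected / shape)))
        else:
            n_reads = int(rng.poisson(expected))
        if n_reads == 0:
            continue
        cdf = np.cumsum(intensity)
        u = rng.random(n_reads) * total
        centers = np.searchsorted(cdf, u)
        starts = np.clip(centers - half, 0, intensity.size - cfg.read_length)
        starts.sort()
        strands = rng.choice(["+", "-"], size=n_reads)
        reads.extend(
            ReadAlignment(chrom=chrom, start=int(s), end=int(s) + cfg.read_length, strand=str(st))
            for s, st in zip(starts, strands)
        )
    return reads


def generate_reads(
    cfg: SyntheticConfig, truth: pd.DataFrame, genome: Genome
) -> dict[tuple[str, str], list[ReadAlignment]]:
    """Read sets for every sample: 4 marks + input, in both conditions.

    The truth table must be complete (fold changes filled in by
    :func:`generate_expression`).
    """
    if truth["fold_change"].isna().any():
        raise ValueError("truth table incomplete: run generate_expression first")
    rng = _rng(cfg, 3)
    islands = nonspecific_islands(cfg, truth, genome)
    out: dict[tuple[str, str], list[ReadAlignment]] = {}
    for mark, condition in [(m, c) for c in CONDITIONS for m in MARKS + (INPUT,)]:
        lam = _intensity(cfg, truth, genome, mark, condition, islands=islands)
        out[(mark, condition)] = _sample_reads_from_intensity(lam, cfg, rng)
    return out


def sample_gene_profiles(
    cfg: SyntheticConfig,
    n_genes: int,
    broad: bool,
    rng: np.random.Generator,
    std_len: int = 1500,
    length_range: tuple[int, int] = (1000, 2000),
) -> np.ndarray:
    """Noisy per-gene length-normalized me3 body profiles, one row per gene.

    A lightweight profile-level sampler (per-base Poisson around the planted
    shape plus background) used to study the broadness statistic at cohort
    sizes beyond the default genome, without simulating full read sets.
    """
    out = np.empty((n_genes, std_len))
    lo, hi = length_range
    for i in range(n_genes):
        L = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        level = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd)
        h = cfg.me3_height_max * level / (level + cfg.me3_level_k)
        lam = me3_body_shape(cfg, L, h, broad) + cfg.nonspecific_rate
        out[i] = resample_body(rng.poisson(lam).astype(float), std_len)
    return out


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the standard files the pipeline consumes.

    Writes genes.gff3, expression.tsv, truth.tsv, chrom.sizes, one BED per
    sample (reads_<mark>_<condition>.bed) and the resolved config
    (synthetic_config.yaml). Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome_and_genes(cfg)
    records = generate_expression(cfg, truth)
    reads = generate_reads(cfg, truth, genome)

    paths: dict[str, Path] = {}
    paths["genes"] = outdir / "genes.gff3"
    write_genes(genes, paths["genes"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(records, paths["expression"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    paths["genome"] = outdir / "chrom.sizes"
    write_genome_sizes(genome, paths["genome"])
    for (mark, condition), sample_reads in reads.items():
        p = outdir / f"reads_{mark}_{condition}.bed"
        with open(p, "w") as fh:
            for r in sample_reads:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")
        paths[f"reads_{mark}_{condition}"] = p
    paths["config"] = outdir / "synthetic_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    # ready-to-run pipeline config pointing at the files above
    paths["pipeline"] = outdir / "pipeline.yaml"
    pipeline_cfg = {
        "genome": "chrom.sizes",
        "genes": "genes.gff3",
        "expression": "expression.tsv",
        "reads": {
            mark: {cond: f"reads_{mark}_{cond}.bed" for cond in CONDITIONS}
            for mark in MARKS + (INPUT,)
        },
    }
    with open(paths["pipeline"], "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    return paths
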