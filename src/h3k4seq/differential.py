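"""Dehydration-responsive gene sets and per-gene methylation changes.

Responsive genes are those whose transcript level changed at least
``fold_min``-fold (4 by default, both boundaries inclusive) with
``p <= p_max`` (0.001). They are binned into change-of-expression quintiles
separately per direction: up-regulated genes into 1..5 by |fold| (5 = largest
increase), down-regulated into -1..-5 (-5 = largest decrease).

The per-gene methylation change is the difference of mean per-base normalized
coverage over the gene span (stressed minus watered) -- a mean, not a sum, so
the statistic is gene-length independent (a sum is available behind a flag).
The stability control computes, for genes whose expression did not change,
the Pearson correlation of per-gene coverage between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import ExpressionRecord, GeneModel
from .coverage import CoverageTrack
from .metagene import assign_quintiles
from .stats_core import pearson

log = logging.getLogger(__name__)


@dataclass
class ResponsiveGeneSet:
    up: list[str]
    down: list[str]
    fold_min: float = 4.0
    p_max: float = 0.001

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")


def filter_responsive_genes(
    records: Sequence[ExpressionRecord], fold_min: float = 4.0, p_max: float = 0.001
) -> ResponsiveGeneSet:
    """Genes with |fold| >= fold_min and p <= p_max, split by direction."""
    up = [r.gene_id for r in records if r.fold_change >= fold_min and r.p_value <= p_max]
    down = [r.gene_id for r in records if r.fold_change <= -fold_min and r.p_value <= p_max]
    return ResponsiveGeneSet(up=sorted(up), down=sorted(down), fold_min=fold_min, p_max=p_max)


def unchanged_genes(
    records: Sequence[ExpressionRecord], fold_max: float = 1.2, p_min: float = 0.5
) -> list[str]:
    """The stability-control cohort: |fold| <= fold_max and p > p_min."""
    return sorted(
        r.gene_id for r in records if abs(r.fold_change) <= fold_max and r.p_value > p_min
    )


def change_quintiles(
    responsive: ResponsiveGeneSet, records: Sequence[ExpressionRecord]
) -> dict[str, int]:
    """Change-of-expression quintiles: +1..+5 for up genes, -1..-5 for down.

    Each direction is quintiled independently on |fold| via
    :func:`assign_quintiles`; quintile 5 (or -5) holds the genes with the
    largest change. A direction with fewer than 5 genes is left unbinned with
    a warning.
    """
    folds = {r.gene_id: abs(r.fold_change) for r in records}
    out: dict[str, int] = {}
    for direction, sign in ((responsive.up, +1), (responsive.down, -1)):
        subset = {g: folds[g] for g in direction}
        if len(subset) < 5:
            log.warning(
                "only %d %s-regulated genes; direction left unbinned",
                len(subset),
                "up" if sign > 0 else "down",
            )
            continue
        for g, q in assign_quintiles(subset).items():
            out[g] = sign * q
    return out


@dataclass
class MethylationDelta:
    """Per gene x mark change in mean per-base coverage (stressed - watered)."""

    table: pd.DataFrame  # index gene_id, one column per mark


def _gene_means(
    track: CoverageTrack, genes: Sequence[GeneModel], statistic: str
) -> dict[str, float]:
    out = {}
    skipped = 0
    for g in genes:
        if g.chrom not in track.data:
            skipped += 1
            continue
        span = track.data[g.chrom][g.start : g.end]
        out[g.gene_id] = float(span.sum() if statistic == "sum" else span.mean())
    if skipped:
        log.warning("%d genes absent from the genome skipped", skipped)
    return out


def methylation_change(
    track_pairs: Mapping[str, tuple[CoverageTrack, CoverageTrack]],
    genes: Sequence[GeneModel],
    statistic: str = "mean",
) -> MethylationDelta:
    """Per-gene coverage change per mark from (watered, stressed) track pairs.

    Both tracks of a pair must have been normalized by the same rule; the
    delta of two identical tracks is exactly zero.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"statistic must be 'mean' or 'sum', got {statistic!r}")
    columns: dict[str, pd.Series] = {}
    for mark, (watered, stressed) in track_pairs.items():
        w = _gene_means(watered, genes, statistic)
        s = _gene_means(stressed, genes, statistic)
        columns[mark] = pd.Series({g: s[g] - w[g] for g in w if g in s})
    table = pd.DataFrame(columns)
    table.index.name = "gene_id"
    return MethylationDelta(table=table)


def quintile_delta_summary(
    delta: MethylationDelta, quintiles: Mapping[str, int]
) -> pd.DataFrame:
    """Median and SD of per-gene deltas per change-quintile per mark."""
    rows = []
    present = [g for g in quintiles if g in delta.table.index]
    by_q: dict[int, list[str]] = {}
    for g in present:
        by_q.setdefault(quintiles[g], []).append(g)
    for q in sorted(by_q):
        members = by_q[q]
        sub = delta.table.loc[members]
        for mark in delta.table.columns:
            vals = sub[mark].to_numpy()
            rows.append((q, mark, float(np.median(vals)), float(np.std(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["quintile", "mark", "median", "sd", "n_genes"])


def stability_correlation(
    track_pairs: Mapping[str, tuple[CoverageTrack, CoverageTrack]],
    genes: Sequence[GeneModel],
    unchanged: Sequence[str],
) -> dict[str, float]:
    """Pearson r of per-gene mean coverage between conditions, per mark.

    Computed over the unchanged-gene cohort; high correlations indicate the
    methylation landscape of non-responding genes is stable across conditions.
    """
    cohort = [g for g in genes if g.gene_id in set(unchanged)]
    if len(cohort) < 3:
        raise ValueError("need at least 3 unchanged genes")
    out: dict[str, float] = {}
    for mark, (watered, stressed) in track_pairs.items():
        w = _gene_means(watered, cohort, "mean")
        s = _gene_means(stressed, cohort, "mean")
        ids = sorted(set(w) & set(s))
        out[mark] = pearson([w[g] for g in ids], [s[g] for g in ids])
    return out
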