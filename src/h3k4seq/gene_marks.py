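"""Peak-to-gene assignment and gene-level methylation mark summaries.

A peak is *genic* when it overlaps at least ``min_overlap`` bp of any gene
span (optionally extended by an upstream promoter flank); a peak overlapping
two genes marks both but is counted once in the genic fraction. The summary
table reports, per mark and condition, how many genes carry that mark, plus
the union row (genes with one or more H3K4 methylation types, in either
condition) and its complement (genes lacking them all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations_io import GeneModel
from .peak_calling import Peak

log = logging.getLogger(__name__)

ME_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")
CONDITIONS = ("watered", "stressed")


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    gene_ids: tuple[str, ...]

    @property
    def genic(self) -> bool:
        return bool(self.gene_ids)


def _gene_trees(
    genes: Sequence[GeneModel], upstream_flank: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "+":
            start, end = g.start - upstream_flank, g.end
        else:
            start, end = g.start, g.end + upstream_flank
        trees.setdefault(g.chrom, IntervalTree()).addi(max(start, 0), end, g.gene_id)
    return trees


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
    upstream_flank: int = 0,
) -> list[PeakAssignment]:
    """Map each peak to all genes it overlaps by >= ``min_overlap`` bp.

    Intervals are half-open, so a peak ending where a gene begins shares no
    base and stays intergenic.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _gene_trees(genes, upstream_flank)
    out: list[PeakAssignment] = []
    for p in peaks:
        hits: list[str] = []
        tree = trees.get(p.chrom)
        if tree is not None:
            for iv in tree.overlap(p.start, p.end):
                if min(iv.end, p.end) - max(iv.begin, p.start) >= min_overlap:
                    hits.append(iv.data)
        out.append(PeakAssignment(peak=p, gene_ids=tuple(sorted(hits))))
    return out


def genic_fraction(assignments: Sequence[PeakAssignment]) -> float | None:
    """Percentage of peaks located on genes; None when there are no peaks."""
    if not assignments:
        return None
    genic = sum(1 for a in assignments if a.genic)
    return 100.0 * genic / len(assignments)


@dataclass
class GeneMarkTable:
    """Gene x (mark, condition) boolean mark table plus the derived summary.

    ``summary`` mirrors the published per-mark table: one row per
    condition/mark with gene count and percentage of all annotated genes,
    followed by the "one or more types" union row and the "lacking" row. The
    union counts a gene that carries any methylation type in either condition
    (flagged in the report header when written).
    """

    has_mark: pd.DataFrame
    summary: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gene universe: all annotated genes supplied\n")
            fh.write("# 'one or more types' row: union over marks and conditions\n")
            self.summary.to_csv(fh, sep="\t", index=False, float_format="%.1f")


def summarize_gene_marks(
    peak_sets: Mapping[tuple[str, str], Sequence[Peak]],
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
    upstream_flank: int = 0,
) -> GeneMarkTable:
    """Build the per-mark gene counts/percentages from six methylation peak sets."""
    required = [(m, c) for c in CONDITIONS for m in ME_MARKS]
    missing = [key for key in required if key not in peak_sets]
    if missing:
        raise ValueError(f"missing methylation peak sets: {missing}")

    gene_ids = [g.gene_id for g in genes]
    n_total = len(gene_ids)
    marked: dict[tuple[str, str], set[str]] = {}
    for key in required:
        hits: set[str] = set()
        for a in assign_peaks_to_genes(
            peak_sets[key], genes, min_overlap=min_overlap, upstream_flank=upstream_flank
        ):
            hits.update(a.gene_ids)
        marked[key] = hits

    has = pd.DataFrame(
        {f"{cond}:{mark}": [g in marked[(mark, cond)] for g in gene_ids]
         for (mark, cond) in required},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    rows = []
    for mark, cond in required:
        n = len(marked[(mark, cond)])
        rows.append((f"{cond}: {mark}", n, 100.0 * n / n_total if n_total else 0.0))
    any_mark = set().union(*marked.values()) if marked else set()
    n_any = len(any_mark)
    rows.append(
        ("Genes with one or more types of H3K4 methylation", n_any,
         100.0 * n_any / n_total if n_total else 0.0)
    )
    rows.append(
        ("Genes lacking H3K4 methylation", n_total - n_any,
         100.0 * (n_total - n_any) / n_total if n_total else 0.0)
    )
    summary = pd.DataFrame(rows, columns=["row", "n_genes", "pct_genes"])
    return GeneMarkTable(has_mark=has, summary=summary)


def peak_location_summary(
    peak_sets: Mapping[tuple[str, str], Sequence[Peak]],
    genes: Sequence[GeneModel],
    min_overlap: int = 1,
    upstream_flank: int = 0,
) -> pd.DataFrame:
    """Per-sample genic/intergenic peak counts and percent genic."""
    rows = []
    for (mark, cond), peaks in peak_sets.items():
        assignments = assign_peaks_to_genes(
            peaks, genes, min_overlap=min_overlap, upstream_flank=upstream_flank
        )
        n_genic = sum(1 for a in assignments if a.genic)
        frac = genic_fraction(assignments)
        rows.append(
            (mark, cond, n_genic, len(assignments) - n_genic,
             float("nan") if frac is None else frac)
        )
    return pd.DataFrame(
        rows, columns=["mark", "condition", "genic_peaks", "intergenic_peaks", "pct_genic"]
    )
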