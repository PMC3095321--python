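"""Gene annotations, expression tables, and genome-browser track files.

This module owns every coordinate convention in the package. Internally all
intervals are 0-based half-open (the BED/bedGraph convention); GFF3's 1-based
closed coordinates are converted at the file boundary, in both directions.

Strand-aware anchors are derived, never stored: the transcription start site
(TSS) of a minus-strand gene is its last base, and reversing a gene's strand
swaps its TSS and stop-codon anchor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .coverage import CoverageTrack, ReadAlignment
    from .peak_calling import Peak

log = logging.getLogger(__name__)

EXPRESSION_COLUMNS = (
    "gene_id",
    "level_watered",
    "level_stressed",
    "fold_change",
    "p_value",
)


class ParseError(ValueError):
    """A malformed annotation/track line; the message names the line number."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: span plus strand, in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def tss(self) -> int:
        """Transcription start site: first transcribed base on the gene's strand."""
        return self.start if self.strand == "+" else self.end - 1

    def stop_anchor(self) -> int:
        """Last transcribed base on the gene's strand (the stop-codon anchor)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene transcript levels in both conditions with signed fold change.

    The fold change is signed: down-regulation is reported as a negative fold
    (-4 means a 4-fold decrease), so ``|fold_change| >= 1`` always. Filters use
    the magnitude.
    """

    gene_id: str
    level_watered: float
    level_stressed: float
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.level_watered < 0 or self.level_stressed < 0:
            raise ValueError(f"{self.gene_id}: expression levels must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.gene_id}: p_value must be in [0, 1], got {self.p_value}")
        if abs(self.fold_change) < 1.0:
            raise ValueError(
                f"{self.gene_id}: |fold_change| must be >= 1 under the signed-fold "
                f"convention, got {self.fold_change}"
            )


class Genome:
    """Ordered map of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0, got {length}")
        self._sizes: dict[str, int] = {name: int(length) for name, length in items}

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Genome({self._sizes!r})"


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix == ".bed":
        return "bed"
    raise ValueError(f"cannot infer annotation format from {path.name}; pass format=")


def read_genes(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a GFF3 or BED6/BED12 file.

    GFF3 coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention; only ``gene`` features are kept. For BED only the
    first six columns are used (the gene span; exon blocks are ignored).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GFF3 columns")
                    if fields[2] != "gene":
                        continue
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                    m = _GFF_ID_RE.search(fields[8])
                    if m is None:
                        raise ValueError("gene feature without an ID attribute")
                    gene = GeneModel(m.group(1), fields[0], start, end, fields[6])
                elif fmt == "bed":
                    if len(fields) < 6:
                        raise ValueError("expected at least 6 BED columns")
                    gene = GeneModel(
                        fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5]
                    )
                else:
                    raise ValueError(f"unknown annotation format {fmt!r}")
            except ValueError as exc:
                raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ParseError(f"{path.name} line {lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path, format: str | None = None) -> None:
    """Write gene models as GFF3 (1-based closed) or BED6, sorted by position."""
    path = Path(path)
    fmt = _infer_format(path, format)
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in ordered:
                fh.write(
                    f"{g.chrom}\th3k4seq\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif fmt == "bed":
            for g in ordered:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


def filter_genes_to_genome(genes: Iterable[GeneModel], genome: Genome) -> list[GeneModel]:
    """Drop genes on chromosomes absent from the genome (warned, not an error)."""
    kept, dropped = [], 0
    for g in genes:
        if g.chrom in genome:
            if g.end > genome[g.chrom]:
                raise ValueError(
                    f"{g.gene_id}: end {g.end} beyond {g.chrom} length {genome[g.chrom]}"
                )
            kept.append(g)
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d genes on chromosomes absent from the genome", dropped)
    return kept


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a 5-column expression TSV; rows with a missing p-value keep p=1."""
    df = pd.read_csv(path, sep="\t")
    unknown = set(df.columns) - set(EXPRESSION_COLUMNS)
    if unknown:
        raise ValueError(f"unknown expression column(s): {sorted(unknown)}")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing expression column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        p = 1.0 if pd.isna(row.p_value) else float(row.p_value)
        records.append(
            ExpressionRecord(
                gene_id=str(row.gene_id),
                level_watered=float(row.level_watered),
                level_stressed=float(row.level_stressed),
                fold_change=float(row.fold_change),
                p_value=p,
            )
        )
    return records


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.gene_id, r.level_watered, r.level_stressed, r.fold_change, r.p_value)
            for r in records
        ],
        columns=list(EXPRESSION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# browser tracks: bedGraph coverage and BED peaks
# ---------------------------------------------------------------------------


def _format_value(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return f"{v:.10g}"


def write_bedgraph(track: "CoverageTrack", path: str | Path) -> None:
    """Write per-base coverage as bedGraph; equal-value runs merged, zeros omitted."""
    with open(path, "w") as fh:
        for chrom in track.data:
            values = np.asarray(track.data[chrom])
            if values.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(values) != 0) + 1
            bounds = np.concatenate(([0], breaks, [values.size]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_format_value(float(v))}\n")


def read_coverage(
    path: str | Path,
    genome: Genome,
    mark: str = "",
    condition: str = "",
    total_reads: float | None = None,
) -> "CoverageTrack":
    """Read a bedGraph into a dense per-base CoverageTrack over ``genome``."""
    from .coverage import CoverageTrack

    data = {chrom: np.zeros(length, dtype=float) for chrom, length in genome.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{Path(path).name} line {lineno}: {exc}") from exc
            if chrom not in data:
                log.warning("bedGraph interval on unknown chromosome %s skipped", chrom)
                continue
            data[chrom][start:end] = value
    return CoverageTrack(mark=mark, condition=condition, data=data, total_reads=total_reads)


def write_peaks(peaks: Sequence["Peak"], path: str | Path, name: str = "peak") -> None:
    """Write peaks as BED6+1: score column scaled to 0-1000, true score in column 7."""
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    max_score = max((p.score for p in ordered), default=1.0) or 1.0
    with open(path, "w") as fh:
        for p in ordered:
            scaled = int(round(1000 * p.score / max_score))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{scaled}\t.\t{p.score:.6g}\n"
            )


def write_track(obj, path: str | Path, format: str | None = None, name: str = "peak") -> None:
    """Dispatch: CoverageTrack -> bedGraph, peak list -> BED."""
    from .coverage import CoverageTrack

    if isinstance(obj, CoverageTrack):
        write_bedgraph(obj, path)
    else:
        write_peaks(obj, path, name=name)


def read_reads_bed(path: str | Path) -> list["ReadAlignment"]:
    """Read aligned-read footprints from a BED6 file (strand optional)."""
    from .coverage import ReadAlignment

    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "strand": str},
    )
    return [
        ReadAlignment(chrom=c, start=s, end=e, strand=st)
        for c, s, e, st in zip(df.chrom, df.start, df.end, df.strand)
    ]


def read_genome_sizes(path: str | Path) -> Genome:
    """Read a two-column chrom-sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return Genome(list(zip(df.chrom.astype(str), df.length.astype(int))))


def write_genome_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
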