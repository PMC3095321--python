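"""Per-base coverage construction and input-DNA normalization.

Coverage is the number of uniquely-aligned read footprints overlapping each
genomic base. Raw tracks conserve mass: the genome-wide sum equals the summed
footprint lengths of the contributing reads (after clipping at chromosome
ends). ChIP tracks are compared after scaling to a common library size and,
optionally, dividing position-wise by a smoothed input-DNA profile, which
removes shearing/sequencing accessibility bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations_io import Genome

log = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 35


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One uniquely-aligned read footprint (0-based half-open).

    Uniqueness and the mismatch limit are an upstream contract of the aligner
    output this package consumes; they are not re-checked here.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read footprint must be non-empty: [{self.start}, {self.end})")


@dataclass
class CoverageTrack:
    """Per-chromosome vectors of per-base coverage for one sample."""

    mark: str
    condition: str
    data: dict[str, np.ndarray]
    total_reads: float | None = None

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def genome_length(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def genome_mean(self) -> float:
        return self.total_mass() / self.genome_length()

    def library_size(self) -> float:
        """Sequencing depth proxy: read count if known, else coverage mass."""
        if self.total_reads is not None and self.total_reads > 0:
            return float(self.total_reads)
        return self.total_mass()

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            mark=self.mark,
            condition=self.condition,
            data={c: v.copy() for c, v in self.data.items()},
            total_reads=self.total_reads,
        )


def build_coverage(
    reads: Iterable[ReadAlignment] | Mapping[str, tuple[np.ndarray, np.ndarray]],
    genome: Genome,
    extension: int = 0,
    mark: str = "",
    condition: str = "",
) -> CoverageTrack:
    """Pile up read footprints into per-base coverage.

    Each read adds +1 over its footprint; with ``extension`` > footprint the
    read is extended in its 3' direction to that many bp (a crude fragment
    model, off by default). Footprints are clipped at chromosome ends. Reads on
    chromosomes absent from ``genome`` are skipped with a warning counter.

    ``reads`` may be an iterable of :class:`ReadAlignment` or, as a fast path,
    a mapping chrom -> (starts, ends) integer arrays.
    """
    diffs = {chrom: np.zeros(length + 1, dtype=np.int64) for chrom, length in genome.items()}
    n_reads = 0
    skipped = 0

    if isinstance(reads, Mapping):
        if extension:
            raise ValueError("extension is only supported for ReadAlignment input")
        for chrom, (starts, ends) in reads.items():
            if chrom not in diffs:
                skipped += len(starts)
                continue
            length = genome[chrom]
            s = np.clip(np.asarray(starts, dtype=np.int64), 0, length)
            e = np.clip(np.asarray(ends, dtype=np.int64), 0, length)
            np.add.at(diffs[chrom], s, 1)
            np.subtract.at(diffs[chrom], e, 1)
            n_reads += len(starts)
    else:
        for r in reads:
            if r.chrom not in diffs:
                skipped += 1
                continue
            length = genome[r.chrom]
            if extension and extension > (r.end - r.start):
                if r.strand == "-":
                    s, e = r.end - extension, r.end
                else:
                    s, e = r.start, r.start + extension
            else:
                s, e = r.start, r.end
            s = max(s, 0)
            e = min(e, length)
            if e <= s:
                continue
            diffs[r.chrom][s] += 1
            diffs[r.chrom][e] -= 1
            n_reads += 1

    if skipped:
        log.warning("%d reads on unknown chromosomes skipped", skipped)
    data = {chrom: np.cumsum(d[:-1]).astype(float) for chrom, d in diffs.items()}
    return CoverageTrack(mark=mark, condition=condition, data=data, total_reads=float(n_reads))


def _centered_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a window truncated at the vector edges."""
    if window <= 1:
        return values.astype(float)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def normalize_to_input(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    mode: str = "input",
    smooth_window: int = 500,
    floor_frac: float = 0.25,
) -> CoverageTrack:
    """Normalize a ChIP track against the input-DNA control.

    The ChIP track is first scaled by the library-size ratio
    ``input.library_size / chip.library_size`` (so a flat input at matched
    depth is the identity), then, in ``mode="input"``, divided position-wise by
    the input profile smoothed with a centered moving average and rescaled to
    genome-wide mean 1. The divisor is floored at ``floor_frac`` of that mean
    so sparse input positions cannot blow up. ``mode="scale"`` stops after the
    depth scaling.
    """
    if set(chip.data) != set(input_track.data):
        raise ValueError("chip and input tracks cover different chromosomes")
    if input_track.total_mass() == 0:
        raise ValueError("input track is all zero; cannot normalize")
    if mode not in ("input", "scale"):
        raise ValueError(f"unknown normalization mode {mode!r}")

    scale = input_track.library_size() / chip.library_size()
    out = {chrom: v * scale for chrom, v in chip.data.items()}
    if mode == "input":
        mu = input_track.genome_mean()
        for chrom, v in out.items():
            smoothed = _centered_mean(input_track.data[chrom], smooth_window)
            divisor = np.maximum(smoothed / mu, floor_frac)
            out[chrom] = v / divisor
    return CoverageTrack(mark=chip.mark, condition=chip.condition, data=out, total_reads=None)


def mean_coverage(
    track: CoverageTrack, intervals: Sequence[tuple[str, int, int]]
) -> float:
    """Mean per-base coverage over a set of genomic intervals.

    The value is the coverage sum over all interval bases divided by the total
    interval length, after clipping intervals to the genome; invariant to
    splitting any interval into adjacent pieces.
    """
    total = 0.0
    n_bases = 0
    for chrom, start, end in intervals:
        if chrom not in track.data:
            continue
        v = track.data[chrom]
        s, e = max(start, 0), min(end, v.size)
        if e > s:
            total += float(v[s:e].sum())
            n_bases += e - s
    if n_bases == 0:
        raise ValueError("no interval bases fall inside the genome")
    return total / n_bases
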