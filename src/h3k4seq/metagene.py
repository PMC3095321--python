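"""Metagene profiles: anchored and length-normalized aggregate coverage.

Two profile geometries are supported:

* **Anchored** -- coverage is read at fixed bp offsets around the TSS or the
  stop-codon anchor of every gene in a cohort, on the gene's strand-oriented
  axis (downstream is positive for both strands), then aggregated per offset.
* **Length-normalized** -- each gene body is resampled to a standard length
  (1500 bp by default) so genes of different sizes align position-for-position,
  with native-scale flanks upstream of the TSS and downstream of the stop; the
  per-position aggregate is the median by default. Cohorts are restricted to a
  gene-length window (1000-2000 bp by default) so the resampling distortion
  stays modest.

Expression cohorts come from :func:`assign_quintiles`, which splits genes into
five blocks by a per-gene statistic (quintile 5 = highest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import GeneModel
from .coverage import CoverageTrack

log = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Per-position aggregate coverage over a gene cohort."""

    axis: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    cohort: tuple[str, ...]
    aggregate_kind: str

    def __post_init__(self) -> None:
        if len(self.axis) != len(self.values):
            raise ValueError("axis and values must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.axis, "value": self.values, "n_genes": self.counts}
        )


def assign_quintiles(values: Mapping[str, float]) -> dict[str, int]:
    """Split genes into quintiles 1..5 (5 = highest) by a per-gene statistic.

    Genes are sorted ascending; ties are broken by gene id so the split is
    deterministic. Blocks are contiguous with sizes differing by at most one:
    ``floor(n/5)`` each, the first ``n mod 5`` blocks one larger.
    """
    n = len(values)
    if n < 5:
        raise ValueError(f"need at least 5 genes to form quintiles, got {n}")
    order = sorted(values, key=lambda g: (values[g], g))
    base, rem = divmod(n, 5)
    sizes = [base + 1] * rem + [base] * (5 - rem)
    out: dict[str, int] = {}
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for g in order[pos : pos + size]:
            out[g] = q
        pos += size
    return out


def _aggregate(matrix: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    counts = np.sum(~np.isnan(matrix), axis=0)
    if kind not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {kind!r}")
    with warnings.catch_warnings():
        # positions where every gene is off-chromosome aggregate to NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(matrix, axis=0) if kind == "mean" else np.nanmedian(matrix, axis=0)
    return values, counts


def anchored_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    anchor: str = "tss",
    window: tuple[int, int] = (-1000, 1000),
    aggregate: str = "mean",
) -> MetageneProfile:
    """Aggregate coverage at fixed offsets around a strand-oriented anchor.

    For minus-strand genes the axis is flipped so positive offsets always point
    downstream. Offsets that fall off the chromosome are excluded from that
    offset's aggregate. Genes shorter than the window are retained; offsets
    beyond the gene simply read whatever coverage is there, as a browser-style
    metaplot does.
    """
    if anchor not in ("tss", "stop"):
        raise ValueError(f"anchor must be 'tss' or 'stop', got {anchor!r}")
    if window[0] >= window[1]:
        raise ValueError("window must be (lo, hi) with lo < hi")
    cohort = [g for g in genes if g.chrom in track.data]
    if not cohort:
        raise ValueError("empty cohort")
    offsets = np.arange(window[0], window[1] + 1)
    matrix = np.full((len(cohort), offsets.size), np.nan)
    for i, g in enumerate(cohort):
        cov = track.data[g.chrom]
        a = g.tss() if anchor == "tss" else g.stop_anchor()
        pos = a + offsets if g.strand == "+" else a - offsets
        valid = (pos >= 0) & (pos < cov.size)
        matrix[i, valid] = cov[pos[valid]]
    values, counts = _aggregate(matrix, aggregate)
    return MetageneProfile(
        axis=offsets,
        values=values,
        counts=counts,
        cohort=tuple(g.gene_id for g in cohort),
        aggregate_kind=aggregate,
    )


def resample_body(values: np.ndarray, std_len: int, mode: str = "interp") -> np.ndarray:
    """Resample a gene-body coverage vector to ``std_len`` positions.

    ``interp`` evaluates the piecewise-linear interpolant of per-base values
    (nodes at base centers) at positions (i + 0.5)/std_len * L -- this is the
    identity, up to half-sample phase, for a gene of exactly ``std_len`` bp and
    preserves linear ramps. ``binmean`` averages within std_len equal bins.
    """
    v = np.asarray(values, dtype=float)
    L = v.size
    if L == 0:
        raise ValueError("empty body")
    if mode == "interp":
        q = (np.arange(std_len) + 0.5) / std_len * L
        return np.interp(q, np.arange(L) + 0.5, v)
    if mode == "binmean":
        edges = np.linspace(0.0, L, std_len + 1)
        csum = np.concatenate(([0.0], np.cumsum(v)))
        cum_at = np.interp(edges, np.arange(L + 1), csum)
        return np.diff(cum_at) / np.diff(edges)
    raise ValueError(f"unknown resampling mode {mode!r}")


def _oriented_slice(cov: np.ndarray, start: int, end: int, minus: bool) -> np.ndarray:
    """Coverage over [start, end) in gene orientation; off-chromosome is NaN."""
    out = np.full(end - start, np.nan)
    s, e = max(start, 0), min(end, cov.size)
    if e > s:
        out[s - start : e - start] = cov[s:e]
    return out[::-1] if minus else out


def gene_body_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    std_len: int = 1500,
    length_range: tuple[int, int] | None = (1000, 2000),
    resample: str = "interp",
) -> tuple[list[str], np.ndarray]:
    """Per-gene length-normalized body coverage, one row per gene.

    Returns the gene ids kept (after the optional length filter) and an
    (n_genes, std_len) matrix in gene orientation.
    """
    kept: list[GeneModel] = []
    for g in genes:
        if g.chrom not in track.data:
            continue
        if length_range is not None and not (length_range[0] <= g.length <= length_range[1]):
            continue
        kept.append(g)
    if not kept:
        raise ValueError("no genes survive the length filter")
    matrix = np.empty((len(kept), std_len))
    for i, g in enumerate(kept):
        body = _oriented_slice(track.data[g.chrom], g.start, g.end, g.strand == "-")
        matrix[i] = resample_body(np.nan_to_num(body), std_len, mode=resample)
    return [g.gene_id for g in kept], matrix


def length_normalized_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    length_range: tuple[int, int] = (1000, 2000),
    std_len: int = 1500,
    flank: int = 500,
    aggregate: str = "median",
    resample: str = "interp",
) -> MetageneProfile:
    """Aggregate coverage over gene bodies rescaled to a standard length.

    The axis runs from ``-flank`` (native bp upstream of the TSS) through the
    ``std_len`` resampled body positions to ``std_len + flank - 1`` (native bp
    downstream of the stop anchor).
    """
    kept = [
        g
        for g in genes
        if g.chrom in track.data and length_range[0] <= g.length <= length_range[1]
    ]
    if not kept:
        raise ValueError("no genes in the length range")
    width = flank + std_len + flank
    matrix = np.full((len(kept), width), np.nan)
    for i, g in enumerate(kept):
        cov = track.data[g.chrom]
        minus = g.strand == "-"
        if minus:
            upstream = _oriented_slice(cov, g.end, g.end + flank, True)
            downstream = _oriented_slice(cov, g.start - flank, g.start, True)
        else:
            upstream = _oriented_slice(cov, g.start - flank, g.start, False)
            downstream = _oriented_slice(cov, g.end, g.end + flank, False)
        body = _oriented_slice(cov, g.start, g.end, minus)
        matrix[i, :flank] = upstream
        matrix[i, flank : flank + std_len] = resample_body(
            np.nan_to_num(body), std_len, mode=resample
        )
        matrix[i, flank + std_len :] = downstream
    values, counts = _aggregate(matrix, aggregate)
    axis = np.arange(-flank, std_len + flank)
    return MetageneProfile(
        axis=axis,
        values=values,
        counts=counts,
        cohort=tuple(g.gene_id for g in kept),
        aggregate_kind=aggregate,
    )


def peak_normalize(profile: MetageneProfile) -> MetageneProfile:
    """Rescale a profile by its maximum so shapes, not heights, are compared."""
    finite = profile.values[np.isfinite(profile.values)]
    if finite.size == 0 or finite.max() <= 0:
        raise ValueError("cannot peak-normalize an all-zero profile")
    return MetageneProfile(
        axis=profile.axis.copy(),
        values=profile.values / finite.max(),
        counts=profile.counts.copy(),
        cohort=profile.cohort,
        aggregate_kind=profile.aggregate_kind,
    )


def profile_peak_position(profile: MetageneProfile) -> int:
    """Axis position of the profile maximum; smallest offset on ties.

    A flat profile has no meaningful peak and raises ``ValueError``.
    """
    finite_mask = np.isfinite(profile.values)
    if not finite_mask.any():
        raise ValueError("profile has no finite values")
    finite = profile.values[finite_mask]
    if np.isclose(finite.max(), finite.min()):
        raise ValueError("flat profile: peak position undefined")
    values = np.where(finite_mask, profile.values, -np.inf)
    return int(profile.axis[int(np.argmax(values))])
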