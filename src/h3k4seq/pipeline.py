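"""End-to-end pipeline orchestration with a strict YAML config.

Stage order: coverage -> input normalization -> background estimation -> peak
calling -> gene-level marks -> metagene profiles -> differential analysis ->
broadness test. Every run writes a machine-readable ``manifest.json`` with the
resolved configuration, package version, and per-sample background levels, so
two runs with the same config and inputs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations_io import (
    filter_genes_to_genome,
    read_expression,
    read_genes,
    read_genome_sizes,
    read_reads_bed,
    write_bedgraph,
    write_peaks,
)
from .coverage import CoverageTrack, build_coverage, normalize_to_input
from .differential import (
    change_quintiles,
    filter_responsive_genes,
    methylation_change,
    quintile_delta_summary,
    stability_correlation,
    unchanged_genes,
)
from .gene_marks import peak_location_summary, summarize_gene_marks
from .metagene import (
    anchored_profile,
    assign_quintiles,
    gene_body_matrix,
    length_normalized_profile,
    peak_normalize,
)
from .peak_calling import (
    CHIP_MARKS,
    CONDITIONS,
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_SCORE,
    peaks_for_all_samples,
)
from .stats_core import broadness_scores, wilcoxon_rank_sum

log = logging.getLogger(__name__)

ME_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (strict: unknown keys are rejected)."""

    genome: str
    genes: str
    expression: str
    reads: dict[str, dict[str, str]]  # mark -> condition -> BED path

    extension: int = 0
    normalization_mode: str = "input"
    smooth_window: int = 500
    floor_frac: float = 0.25
    min_score: float = DEFAULT_MIN_SCORE
    min_length: int = DEFAULT_MIN_LENGTH
    min_overlap: int = 1
    upstream_flank: int = 0
    metagene_window: tuple[int, int] = (-1000, 1000)
    length_range: tuple[int, int] = (1000, 2000)
    std_len: int = 1500
    flank: int = 500
    fold_min: float = 4.0
    p_max: float = 0.001
    unchanged_fold_max: float = 1.2
    unchanged_p_min: float = 0.5
    expressed_quantile: float = 0.2
    write_tracks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("metagene_window", "length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        base = Path(path).parent
        cfg.genome = str((base / cfg.genome))
        cfg.genes = str((base / cfg.genes))
        cfg.expression = str((base / cfg.expression))
        cfg.reads = {
            m: {c: str(base / p) for c, p in conds.items()} for m, conds in cfg.reads.items()
        }
        return cfg

    def validate_paths(self) -> None:
        required = [(m, c) for m in CHIP_MARKS + ("input",) for c in CONDITIONS]
        missing = [
            (m, c) for m, c in required if m not in self.reads or c not in self.reads[m]
        ]
        if missing:
            raise ValueError(f"config missing read files for samples: {missing}")
        for p in [self.genome, self.genes, self.expression] + [
            path for conds in self.reads.values() for path in conds.values()
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        for key in ("metagene_window", "length_range"):
            out[key] = list(out[key])
        return out


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def _df_to_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and write the report directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate_paths()

    genome = read_genome_sizes(config.genome)
    genes = filter_genes_to_genome(read_genes(config.genes), genome)
    records = read_expression(config.expression)
    genes_by_id = {g.gene_id: g for g in genes}

    # --- coverage -----------------------------------------------------------
    @_stage("coverage")
    def _coverage() -> dict[tuple[str, str], CoverageTrack]:
        tracks = {}
        for mark, conds in config.reads.items():
            for cond, path in conds.items():
                reads = read_reads_bed(path)
                tracks[(mark, cond)] = build_coverage(
                    reads, genome, extension=config.extension, mark=mark, condition=cond
                )
        return tracks

    tracks = _coverage()
    if config.write_tracks:
        for (mark, cond), track in tracks.items():
            write_bedgraph(track, outdir / f"coverage_{mark}_{cond}.bedGraph")

    # --- normalization ------------------------------------------------------
    @_stage("normalize")
    def _normalize() -> dict[tuple[str, str], CoverageTrack]:
        out = {}
        for cond in CONDITIONS:
            inp = tracks[("input", cond)]
            for mark in CHIP_MARKS:
                out[(mark, cond)] = normalize_to_input(
                    tracks[(mark, cond)],
                    inp,
                    mode=config.normalization_mode,
                    smooth_window=config.smooth_window,
                    floor_frac=config.floor_frac,
                )
        return out

    normalized = _normalize()

    # --- background + peaks (on raw coverage, per-run background) -----------
    @_stage("peaks")
    def _peaks():
        chip = {k: v for k, v in tracks.items() if k[0] != "input"}
        return peaks_for_all_samples(
            chip, genes, genome, min_score=config.min_score, min_length=config.min_length
        )

    peak_sets, backgrounds = _peaks()
    for (mark, cond), peaks in peak_sets.items():
        write_peaks(peaks, outdir / f"peaks_{mark}_{cond}.bed", name=f"{mark}_{cond}")

    # --- gene-level marks ---------------------------------------------------
    @_stage("gene_marks")
    def _marks():
        me_sets = {k: v for k, v in peak_sets.items() if k[0] in ME_MARKS}
        table = summarize_gene_marks(
            me_sets, genes, min_overlap=config.min_overlap, upstream_flank=config.upstream_flank
        )
        location = peak_location_summary(
            me_sets, genes, min_overlap=config.min_overlap, upstream_flank=config.upstream_flank
        )
        return table, location

    mark_table, location = _marks()
    mark_table.to_tsv(outdir / "gene_mark_summary.tsv")
    _df_to_tsv(location, outdir / "peak_location_summary.tsv")

    # --- metagene profiles by expression quintile ---------------------------
    @_stage("metagene")
    def _metagene() -> None:
        levels = {r.gene_id: r.level_watered for r in records if r.gene_id in genes_by_id}
        quintiles = assign_quintiles(levels)
        frames = []
        for mark in CHIP_MARKS:
            for anchor in ("tss", "stop"):
                for q in range(1, 6):
                    cohort = [genes_by_id[g] for g, qq in quintiles.items() if qq == q]
                    prof = anchored_profile(
                        normalized[(mark, "watered")],
                        cohort,
                        anchor=anchor,
                        window=config.metagene_window,
                        aggregate="mean",
                    )
                    df = prof.to_frame()
                    df.insert(0, "quintile", q)
                    df.insert(0, "anchor", anchor)
                    df.insert(0, "mark", mark)
                    frames.append(df)
        _df_to_tsv(pd.concat(frames, ignore_index=True), outdir / "metagene_quintiles.tsv")

    _metagene()

    # --- differential methylation -------------------------------------------
    @_stage("differential")
    def _differential():
        responsive = filter_responsive_genes(records, fold_min=config.fold_min, p_max=config.p_max)
        quintiles = change_quintiles(responsive, records)
        pairs = {
            mark: (normalized[(mark, "watered")], normalized[(mark, "stressed")])
            for mark in ME_MARKS
        }
        delta = methylation_change(pairs, genes)
        summary = quintile_delta_summary(delta, quintiles)
        stable = unchanged_genes(
            records, fold_max=config.unchanged_fold_max, p_min=config.unchanged_p_min
        )
        corr = stability_correlation(pairs, genes, stable)
        return responsive, quintiles, delta, summary, corr

    responsive, quintiles, delta, summary, corr = _differential()
    _df_to_tsv(
        pd.DataFrame(
            [("up", g) for g in responsive.up] + [("down", g) for g in responsive.down],
            columns=["direction", "gene_id"],
        ),
        outdir / "responsive_genes.tsv",
    )
    _df_to_tsv(
        pd.DataFrame(sorted(quintiles.items()), columns=["gene_id", "change_quintile"]),
        outdir / "change_quintiles.tsv",
    )
    _df_to_tsv(delta.table.sort_index(), outdir / "methylation_change.tsv", index=True)
    _df_to_tsv(summary, outdir / "quintile_delta_summary.tsv")
    _df_to_tsv(
        pd.DataFrame(sorted(corr.items()), columns=["mark", "pearson_r"]),
        outdir / "stability_correlation.tsv",
    )

    # --- broadness test -----------------------------------------------------
    @_stage("broadness")
    def _broadness() -> pd.DataFrame:
        levels = {r.gene_id: r.level_watered for r in records if r.gene_id in genes_by_id}
        cutoff = float(np.quantile(list(levels.values()), config.expressed_quantile))
        expressed_ids = {g for g, lv in levels.items() if lv >= cutoff}
        induced_ids = set(responsive.up)
        rows = []
        profiles = []
        for cond in CONDITIONS:
            track = normalized[("H3K4me3", cond)]
            cohorts = {
                "expressed": [genes_by_id[g] for g in sorted(expressed_ids)],
                "induced": [genes_by_id[g] for g in sorted(induced_ids)],
            }
            scores = {}
            for name, cohort in cohorts.items():
                ids, matrix = gene_body_matrix(
                    track, cohort, std_len=config.std_len, length_range=config.length_range
                )
                scores[name] = broadness_scores(matrix)
                prof = length_normalized_profile(
                    track,
                    cohort,
                    length_range=config.length_range,
                    std_len=config.std_len,
                    flank=config.flank,
                    aggregate="median",
                )
                for kind, p in (("median", prof), ("peak_normalized", peak_normalize(prof))):
                    df = p.to_frame()
                    df.insert(0, "kind", kind)
                    df.insert(0, "cohort", name)
                    df.insert(0, "condition", cond)
                    profiles.append(df)
            res = wilcoxon_rank_sum(scores["induced"], scores["expressed"])
            rows.append(
                (cond, res.U, res.n_a, res.n_b, res.z, res.p, res.method)
            )
        _df_to_tsv(
            pd.concat(profiles, ignore_index=True), outdir / "length_normalized_profiles.tsv"
        )
        return pd.DataFrame(
            rows, columns=["condition", "U", "n_induced", "n_expressed", "z", "p", "method"]
        )

    broadness = _broadness()
    _df_to_tsv(broadness, outdir / "broadness_test.tsv")

    manifest = {
        "package": "h3k4seq",
        "version": __version__,
        "config": config.to_dict(),
        "backgrounds": {f"{m}:{c}": b for (m, c), b in sorted(backgrounds.items())},
        "n_genes": len(genes),
        "n_records": len(records),
        "stages": [
            "coverage",
            "normalize",
            "peaks",
            "gene_marks",
            "metagene",
            "differential",
            "broadness",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
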