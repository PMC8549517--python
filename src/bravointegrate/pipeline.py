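"""End-to-end orchestration: simulate (or load), align, detect, quantify.

A :class:`PipelineConfig` holds either a :class:`~bravointegrate.synthdata.SimConfig`
(simulation mode) or paths to real inputs (precomputed 12-column
alignment tables plus annotations), never both.  ``run_pipeline``
executes chimera detection, junction analysis, quantification and the
window randomness test, writes every table, and returns the in-memory
bundle for programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align import ReferenceIndex
from .chimera import (
    AlignmentHit,
    ChimericRead,
    Thresholds,
    chimeras_to_frame,
    dedupe_pcr,
    find_chimeras,
    parse_alignment_table,
)
from .junctions import (
    JRegions,
    annotate_chimeras,
    classify_junctions,
    delineate_j_regions,
    junction_histogram,
    observed_mh_distribution,
    simulate_null_chimeras,
    compare_mh_distributions,
)
from .landscape import make_windows, poisson_randomness_test, window_ie_counts
from .quantify import (
    IntegrationEvent,
    call_ies,
    coverage_track,
    events_to_frame,
    sample_stats,
)
from .synthdata import SegmentAnnotation, SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger("bravointegrate")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``sim`` (simulation mode) or the real-input paths
    (``wasp_alignments``/``host_alignments``) must be provided.
    Threshold defaults are the published filter values.
    """

    sim: SimConfig | None = None
    wasp_alignments: str | None = None
    host_alignments: str | None = None
    read_length: int = 150
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_support: int = 2  # J-region delineation support
    null_min_side: int = 28
    null_reads: int = 20_000
    window_size: int = 100_000
    restrict_to_j: bool = True
    seed: int = 0
    sample_id: str = "sample"

    def validate(self) -> None:
        real = self.wasp_alignments is not None or self.host_alignments is not None
        if self.sim is not None and real:
            raise ConfigError("provide either a simulation block or real input paths, not both")
        if self.sim is None and not (self.wasp_alignments and self.host_alignments):
            raise ConfigError("real-input mode needs both wasp and host alignment tables")
        for name in ("read_length", "min_support", "null_min_side", "window_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sim is not None and self.sim.read_length != self.read_length:
            raise ConfigError(
                f"read_length {self.read_length} inconsistent with simulated "
                f"reads of {self.sim.read_length} bp"
            )


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    config: PipelineConfig
    dataset: SimulatedDataset | None
    wasp_hits: list[AlignmentHit]
    host_hits: list[AlignmentHit]
    chimeras: list[ChimericRead]  # deduplicated, annotated, classified
    n_pcr_duplicates: int
    rejections: list
    j_regions: dict[str, JRegions]
    category_counts: pd.DataFrame
    events: list[IntegrationEvent]
    stats: object
    mh_table: pd.DataFrame | None
    window_test: object
    summary: dict


def align_simulated(
    dataset: SimulatedDataset,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Align simulated reads to the wasp genome, then wasp-positive
    reads to the host reference (mirrors the two-stage search used on
    real data)."""
    wasp_index = ReferenceIndex(dataset.wasp)
    wasp_hits = wasp_index.align_reads(dataset.reads, genome="wasp")
    wasp_read_ids = {h.read_id for h in wasp_hits}
    host_index = ReferenceIndex(dataset.host_ref)
    host_hits = host_index.align_reads(
        [(rid, seq) for rid, seq in dataset.reads if rid in wasp_read_ids],
        genome="host",
    )
    return wasp_hits, host_hits


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    config.validate()
    logger.info(
        "bravointegrate %s | seed=%d | thresholds=%s", __version__, config.seed, config.thresholds
    )
    dataset: SimulatedDataset | None = None
    segments: Sequence[SegmentAnnotation] = []
    if config.sim is not None:
        dataset = simulate_dataset(config.sim)
        segments = dataset.segments
        wasp_hits, host_hits = align_simulated(dataset)
    else:
        wasp_hits = parse_alignment_table(config.wasp_alignments, genome="wasp")
        host_hits = parse_alignment_table(config.host_alignments, genome="host")

    raw_chimeras, rejections = find_chimeras(
        wasp_hits, host_hits, config.read_length, config.thresholds
    )
    chimeras, n_dups = dedupe_pcr(raw_chimeras)
    chimeras = annotate_chimeras(chimeras, segments)

    j_regions: dict[str, JRegions] = {}
    for seg in segments:
        if not seg.has_him:
            continue
        hist = junction_histogram(chimeras, seg)
        jr = delineate_j_regions(hist, seg.him_circle, config.min_support)
        j_regions[seg.segment_id] = jr
    category_counts = classify_junctions(chimeras, segments, j_regions)

    events = call_ies(chimeras, restrict_to_j=config.restrict_to_j)

    mh_table = None
    chi2 = mh_p = None
    if dataset is not None:
        observed = observed_mh_distribution(chimeras)
        null = simulate_null_chimeras(
            dataset.circles,
            dataset.host_ref,
            n_reads=config.null_reads,
            read_length=config.read_length,
            min_side=config.null_min_side,
            seed=np.random.default_rng(config.seed + 1),
            thresholds=config.thresholds,
        )
        if observed.total > 0:
            mh_table, chi2, dof, mh_p = compare_mh_distributions(observed, null.distribution)
        else:
            chi2 = dof = mh_p = float("nan")

    host_lengths = (
        {k: len(v) for k, v in dataset.host_ref.items()}
        if dataset is not None
        else _lengths_from_hits(host_hits)
    )
    wasp_lengths = (
        {k: len(v) for k, v in dataset.wasp.items()}
        if dataset is not None
        else _lengths_from_hits(wasp_hits)
    )
    stats = sample_stats(
        config.sample_id,
        wasp_hits,
        host_hits,
        events,
        segments,
        config.read_length,
        host_lengths,
        wasp_lengths,
    )

    windows = make_windows(host_lengths, config.window_size)
    if windows.n_windows >= 2 and events:
        counts = window_ie_counts(events, windows)
        window_test = poisson_randomness_test(counts.counts)
    else:
        window_test = None

    summary = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": vars(config.thresholds),
        "n_wasp_hits": len(wasp_hits),
        "n_host_hits": len(host_hits),
        "n_chimeras_raw": len(raw_chimeras),
        "n_pcr_duplicates_removed": n_dups,
        "n_chimeras": len(chimeras),
        "n_rejected": len(rejections),
        "n_events": len(events),
        "ipmh": stats.ipmh,
        "ies_per_genome": stats.ies_per_genome,
        "window_p_value": None if window_test is None else window_test.p_value,
        "mh_chi2": None if mh_table is None else chi2,
        "mh_p_value": None if mh_table is None else mh_p,
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        wasp_hits=wasp_hits,
        host_hits=host_hits,
        chimeras=chimeras,
        n_pcr_duplicates=n_dups,
        rejections=rejections,
        j_regions=j_regions,
        category_counts=category_counts,
        events=events,
        stats=stats,
        mh_table=mh_table,
        window_test=window_test,
        summary=summary,
    )
    if outdir is not None:
        write_result(result, Path(outdir))
    return result


def _lengths_from_hits(hits: Sequence[AlignmentHit]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for h in hits:
        lengths[h.subject_id] = max(lengths.get(h.subject_id, 0), h.subject_end)
    return lengths


def write_result(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chimeras_to_frame(result.chimeras).to_csv(outdir / "chimeras.tsv", sep="\t", index=False)
    pd.DataFrame([vars(r) for r in result.rejections]).to_csv(
        outdir / "rejections.tsv", sep="\t", index=False
    )
    events_to_frame(result.events).to_csv(outdir / "events.tsv", sep="\t", index=False)
    result.category_counts.to_csv(outdir / "junction_categories.tsv", sep="\t")
    jr_rows = [
        {
            "segment_id": sid,
            "j2_start": jr.j2[0] if jr.j2 else "",
            "j2_end": jr.j2[1] if jr.j2 else "",
            "j1_start": jr.j1[0] if jr.j1 else "",
            "j1_end": jr.j1[1] if jr.j1 else "",
            "separation": jr.separation if jr.separation is not None else "",
        }
        for sid, jr in sorted(result.j_regions.items())
    ]
    pd.DataFrame(jr_rows).to_csv(outdir / "j_regions.tsv", sep="\t", index=False)
    if result.mh_table is not None:
        result.mh_table.to_csv(outdir / "microhomology.tsv", sep="\t", index=False)
    if result.window_test is not None:
        result.window_test.expected.to_csv(outdir / "window_occupancy.tsv", sep="\t", index=False)
    stats_row = {k: v for k, v in vars(result.stats).items() if not isinstance(v, dict)}
    pd.DataFrame([stats_row]).to_csv(outdir / "sample_stats.tsv", sep="\t", index=False)
    seg_depth_rows = [
        {"segment_id": k, "mean_depth": v} for k, v in sorted(result.stats.segment_depths.items())
    ]
    pd.DataFrame(seg_depth_rows).to_csv(outdir / "segment_depths.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
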