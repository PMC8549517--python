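"""Integration-event calling and the sample-level normalizations.

An integration event (IE) is a unique integration position, counted
once regardless of how many chimeric reads support it.  Absolute IE
counts are normalized to IEs per million host-mapped reads (IPMH) and
converted to IEs per haploid genome as

    IEs/genome = (IPMH / read_length) * genome_size_Mbp

which makes samples of different sequencing effort comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chimera import AlignmentHit, ChimericRead
from .synthdata import SegmentAnnotation

J_CLASSES = ("J1", "J2")


@dataclass
class IntegrationEvent:
    """A unique (segment, junction, host position, orientation) integration."""

    segment_id: str | None
    junction_class: str | None  # J1 | J2 | HIM_other | outside_HIM
    host_contig: str
    host_position: int  # canonical breakpoint (last host base before the insert)
    orientation: str
    support: int  # number of (deduplicated) chimeric reads
    max_overlap: int = 0  # largest junction microhomology among supporting reads
    max_insert: int = 0  # largest non-templated insertion among supporting reads


@dataclass
class SampleStats:
    """Per-sample mapping totals, depths and normalized IE counts."""

    sample_id: str
    reads_mapped_host: int
    reads_mapped_wasp: int
    read_length: int
    mean_depth_host: float
    mean_depth_wasp: float
    segment_depths: dict[str, float] = field(default_factory=dict)
    n_ies: int = 0
    ipmh: float = 0.0
    ies_per_genome: float = 0.0


def call_ies(
    chimeras: Sequence[ChimericRead], restrict_to_j: bool = True
) -> list[IntegrationEvent]:
    """Group deduplicated chimeras into integration events.

    One event per unique (segment, host contig, canonical host
    breakpoint, orientation, junction class); support is the group
    size.  By default only J1/J2-class junctions are counted, the
    parsimonious quantification; ``restrict_to_j=False`` includes every
    junction category.
    """
    groups: dict[tuple, list[ChimericRead]] = {}
    for c in chimeras:
        if restrict_to_j and c.junction_class not in J_CLASSES:
            continue
        key = (c.segment_id, c.host_subject, c.host_breakpoint, c.orientation, c.junction_class)
        groups.setdefault(key, []).append(c)
    events = [
        IntegrationEvent(
            segment_id=key[0],
            junction_class=key[4],
            host_contig=key[1],
            host_position=key[2],
            orientation=key[3],
            support=len(members),
            max_overlap=max(m.overlap_len for m in members),
            max_insert=max(m.insert_len for m in members),
        )
        for key, members in sorted(groups.items(), key=lambda kv: str(kv[0]))
    ]
    return events


def ipmh(n_ies: int, reads_mapped_host: int) -> float:
    """Integration events per million reads mapped to the host genome."""
    if reads_mapped_host <= 0:
        raise ValueError("reads_mapped_host must be > 0")
    return n_ies / (reads_mapped_host / 1e6)


def ies_per_genome(ipmh_value: float, read_length: int, genome_size_mbp: float) -> float:
    """Average integration events per haploid genome.

    ``(IPMH / read_length) * genome_size_Mbp``: IPMH counts junctions
    per million 150-bp reads, so dividing by the read length and
    scaling by the genome size in Mbp yields events per genome copy.
    """
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    return (ipmh_value / read_length) * genome_size_mbp


def genome_size_mbp(contigs: Mapping[str, str] | Mapping[str, int]) -> float:
    """Total assembly size in Mbp from sequences or contig lengths."""
    total = sum(len(v) if isinstance(v, str) else int(v) for v in contigs.values())
    return total / 1e6


def max_cells_sequenced(mean_depth: float, ploidy: int = 2) -> int:
    """Upper bound on the number of cells sequenced at a given haploid depth.

    Each diploid cell contributes two haploid genome copies, so at most
    ``floor(depth / ploidy)`` cells can have been fully sampled.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return math.floor(mean_depth / ploidy)


def coverage_track(
    hits: Iterable[AlignmentHit], contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base alignment depth from subject intervals of hits."""
    deltas = {name: np.zeros(length + 1, dtype=np.int64) for name, length in contig_lengths.items()}
    for h in hits:
        d = deltas.get(h.subject_id)
        if d is None:
            continue
        d[h.subject_start - 1] += 1
        d[h.subject_end] -= 1
    return {name: np.cumsum(d[:-1]) for name, d in deltas.items()}


def segment_depth(track: Mapping[str, np.ndarray], seg: SegmentAnnotation) -> float:
    """Arithmetic mean depth over a segment interval."""
    if seg.contig not in track:
        raise KeyError(f"no depth track for contig {seg.contig}")
    arr = track[seg.contig]
    if seg.end > len(arr) or seg.start < 1 or seg.start > seg.end:
        raise ValueError(f"segment {seg.segment_id} outside the depth track")
    return float(arr[seg.start - 1 : seg.end].mean())


def depth_ie_correlation(
    depths: Mapping[str, float], ie_counts: Mapping[str, int]
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation between per-segment depth and IE counts.

    Also returns the per-segment depth/IE ratio table.  With fewer than
    4 segments or a constant vector the correlation is undefined and
    returned as NaN.
    """
    seg_ids = sorted(set(depths) & set(ie_counts))
    d = np.array([depths[s] for s in seg_ids], dtype=float)
    n = np.array([ie_counts[s] for s in seg_ids], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n > 0, d / n, np.nan)
    table = pd.DataFrame({"segment_id": seg_ids, "depth": d, "n_ies": n, "depth_ie_ratio": ratio})
    if len(seg_ids) < 4 or np.all(d == d[0]) or np.all(n == n[0]):
        return float("nan"), float("nan"), table
    rho, p = stats.spearmanr(d, n)
    return float(rho), float(p), table


def expected_outside_him(
    busco_exon_total_bp: float,
    busco_mean_depth: float,
    observed_busco_chimeras: float,
    circle_length_bp: float,
    circle_mean_depth: float,
) -> float:
    """Expected chimeras on a circle from the single-copy-exon baseline.

    Chimeras on exons of conserved single-copy (BUSCO) genes measure
    the background chimera rate per aligned base; scaling by each
    circle's length x depth product gives the count expected if circles
    behaved like ordinary wasp sequence.
    """
    baseline = busco_exon_total_bp * busco_mean_depth
    if baseline <= 0:
        raise ValueError("BUSCO baseline length x depth must be > 0")
    return observed_busco_chimeras * (circle_length_bp * circle_mean_depth) / baseline


def sample_stats(
    sample_id: str,
    wasp_hits: Sequence[AlignmentHit],
    host_hits: Sequence[AlignmentHit],
    events: Sequence[IntegrationEvent],
    segments: Sequence[SegmentAnnotation],
    read_length: int,
    host_lengths: Mapping[str, int],
    wasp_lengths: Mapping[str, int],
) -> SampleStats:
    """Assemble the per-sample summary used for normalized reporting."""
    reads_host = len({h.read_id for h in host_hits})
    reads_wasp = len({h.read_id for h in wasp_hits})
    host_track = coverage_track(host_hits, host_lengths)
    wasp_track = coverage_track(wasp_hits, wasp_lengths)
    mean_host = float(np.mean([t.mean() for t in host_track.values()])) if host_track else 0.0
    mean_wasp = float(np.mean([t.mean() for t in wasp_track.values()])) if wasp_track else 0.0
    seg_depths = {s.segment_id: segment_depth(wasp_track, s) for s in segments}
    n = len(events)
    ipmh_val = ipmh(n, reads_host) if reads_host else 0.0
    return SampleStats(
        sample_id=sample_id,
        reads_mapped_host=reads_host,
        reads_mapped_wasp=reads_wasp,
        read_length=read_length,
        mean_depth_host=mean_host,
        mean_depth_wasp=mean_wasp,
        segment_depths=seg_depths,
        n_ies=n,
        ipmh=ipmh_val,
        ies_per_genome=ies_per_genome(ipmh_val, read_length, genome_size_mbp(host_lengths)),
    )


def events_to_frame(events: Sequence[IntegrationEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


@dataclass
class RecoveryMetrics:
    """Round-trip comparison of called events against simulated truth."""

    n_truth: int
    n_called: int
    n_truth_recovered: int
    n_called_matched: int

    @property
    def recall(self) -> float:
        return self.n_truth_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_called_matched / self.n_called if self.n_called else float("nan")


def match_events_to_truth(
    events: Sequence[IntegrationEvent], truth: Sequence, extra_tolerance: int = 0
) -> RecoveryMetrics:
    """Match called events to truth events.

    A called event matches a truth event when segment, host contig and
    orientation agree and the called breakpoint lies within the
    observed positional uncertainty of the junction: the doubly-aligned
    overlap (microhomology) or, for junctions with apparent
    non-templated bases, the inserted length.  Events with neither must
    match exactly.
    """
    matched_truth: set[int] = set()
    n_called_matched = 0
    for ev in events:
        hit = False
        for ti, t in enumerate(truth):
            tol = max(t.microhomology_length, ev.max_overlap, ev.max_insert) + extra_tolerance
            if (
                ev.segment_id == t.segment_id
                and ev.host_contig == t.host_contig
                and ev.orientation == t.orientation
                and abs(ev.host_position - t.host_position) <= tol
            ):
                matched_truth.add(ti)
                hit = True
        if hit:
            n_called_matched += 1
    return RecoveryMetrics(
        n_truth=len(truth),
        n_called=len(events),
        n_truth_recovered=len(matched_truth),
        n_called_matched=n_called_matched,
    )
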