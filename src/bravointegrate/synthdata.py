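"""Synthetic wasp/host genomes, bracovirus circles, integrations and reads.

The generator emulates the biology the downstream analysis assumes:

* a wasp genome carrying non-overlapping proviral segments, each
  flanked by two identical direct repeat junctions (DRJs);
* a fraction of segments carrying a host integration motif (HIM) made
  of a J2 motif, a spacer of 41-73 bp, and a J1 motif (J2 left of J1
  when the circle is oriented 5'DRJ -> 3'DRJ);
* circle excision collapsing the two DRJ copies into one;
* HIM-mediated integration that linearizes the circle by double-strand
  breaks at canonical positions inside J1 and J2, deletes the spacer
  and places J1 and J2 at the extremities of the inserted sequence;
* junction microhomologies of configurable length, engineered by
  adjusting the host target sequence (the canonical cut positions on
  the circle never move);
* fixed-length single-end reads with substitution errors and exact PCR
  duplicates, from both genomes at controllable depths.

Every simulated integration is recorded as a :class:`TruthEvent` so the
detection pipeline can be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import revcomp, write_fasta, write_fastq, write_gff3

DNA = "ACGT"


class SizingError(ValueError):
    """Requested features do not fit in the requested genome length."""


class AnnotationError(ValueError):
    """Segment annotation violates a structural precondition."""


@dataclass
class SimConfig:
    """Parameters of one simulated parasitism experiment.

    Defaults describe a desk-scale experiment: a 300-kb host contig, 16
    HIM-bearing proviral segments, 150-bp reads at 30x on both genomes,
    ~200 integrations with microhomologies of 0-5 bp, a 0.1%
    substitution error rate and 2% exact PCR duplicates.
    """

    host_length: int = 300_000
    wasp_length: int = 60_000
    n_segments: int = 16
    him_fraction: float = 1.0
    drj_length: int = 20
    spacer_length: int | None = None  # None: per-segment uniform in [41, 73]
    read_length: int = 150
    depth_host: float = 30.0
    depth_wasp: float = 30.0
    n_integrations_per_segment: int = 12
    n_integrations_total: int | None = None  # overrides the per-segment count
    n_integrations_by_segment: dict[str, int] | None = None  # per-segment override
    microhomology_probs: dict[int, float] = field(
        default_factory=lambda: {k: 1.0 / 6.0 for k in range(6)}
    )
    pcr_dup_rate: float = 0.02
    error_rate: float = 0.001
    seed: int = 0
    # motif geometry; J motif lengths of 35 bp with a 41-73 bp spacer give
    # HIMs of 111-143 bp, bracketing the canonical 121-bp motif
    j1_length: int = 35
    j2_length: int = 35
    j1_cut_offset: int = 0  # canonical cut this many bases inside J1, from its start
    j2_cut_offset: int | None = None  # default: at the J2/spacer boundary (J2 end)
    gc_content: float = 0.5
    circle_depths: dict[str, float] = field(default_factory=dict)  # free episomal circles
    host_contig: str = "host_1"
    wasp_contig: str = "wasp_1"

    def validate(self) -> None:
        if self.read_length < 32:
            raise ValueError("read_length must be >= 32 so chimeras are detectable")
        for name in ("him_fraction", "pcr_dup_rate", "error_rate", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spacer_length is not None and not 41 <= self.spacer_length <= 73:
            raise ValueError("spacer_length must lie in [41, 73]")
        if self.n_segments < 0 or self.drj_length <= 0:
            raise ValueError("n_segments must be >= 0 and drj_length positive")
        if min(self.microhomology_probs) < 0 or max(self.microhomology_probs) > 13:
            raise ValueError("microhomology lengths must lie in 0..13")
        if any(p < 0 for p in self.microhomology_probs.values()):
            raise ValueError("microhomology probabilities must be non-negative")


@dataclass
class SegmentAnnotation:
    """A proviral segment on the wasp genome (1-based inclusive intervals)."""

    segment_id: str
    contig: str
    start: int
    end: int
    drj5: tuple[int, int]
    drj3: tuple[int, int] | None
    him: tuple[int, int] | None = None
    j1: tuple[int, int] | None = None
    j2: tuple[int, int] | None = None
    j1_cut_offset: int = 0
    j2_cut_offset: int | None = None

    @property
    def has_him(self) -> bool:
        return self.him is not None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def drj_length(self) -> int:
        return self.drj5[1] - self.drj5[0] + 1

    @property
    def circle_length(self) -> int:
        return self.length - self.drj_length

    @property
    def spacer_interval(self) -> tuple[int, int] | None:
        if not self.has_him:
            return None
        return (self.j2[1] + 1, self.j1[0] - 1)

    @property
    def spacer_length(self) -> int | None:
        iv = self.spacer_interval
        return None if iv is None else iv[1] - iv[0] + 1

    def genome_to_circle(self, pos: int) -> int | None:
        """Map a wasp genome position to the circle coordinate.

        The circle is reported linearized starting at the single
        retained DRJ, oriented 5'DRJ -> 3'DRJ.  Positions inside the
        3' DRJ map onto the retained copy.
        """
        if self.drj3 is not None and self.drj3[0] <= pos <= self.drj3[1]:
            return pos - self.drj3[0] + 1
        if self.start <= pos < (self.drj3[0] if self.drj3 else self.end + 1):
            return pos - self.start + 1
        return None

    @property
    def j1_cut_circle(self) -> int:
        """Circle coordinate of the first base retained on the J1 side."""
        if not self.has_him:
            raise AnnotationError(f"{self.segment_id} has no HIM")
        return self.genome_to_circle(self.j1[0] + self.j1_cut_offset)

    @property
    def j2_cut_circle(self) -> int:
        """Circle coordinate of the last base retained on the J2 side."""
        if not self.has_him:
            raise AnnotationError(f"{self.segment_id} has no HIM")
        offset = self.j2_cut_offset
        if offset is None:
            offset = self.j2[1] - self.j2[0] + 1
        return self.genome_to_circle(self.j2[0] - 1 + offset)

    @property
    def him_circle(self) -> tuple[int, int] | None:
        if not self.has_him:
            return None
        return (self.genome_to_circle(self.him[0]), self.genome_to_circle(self.him[1]))


@dataclass(frozen=True)
class TruthEvent:
    """One simulated integration with exact coordinates."""

    segment_id: str
    host_contig: str
    host_position: int  # 1-based position of the last host base before the insert
    orientation: str  # "+": circle inserted in 5'DRJ->3'DRJ sense
    microhomology_length: int
    inserted_length: int


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(DNA), size=n, p=probs))


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    options = [b for b in DNA if b not in avoid]
    return options[int(rng.integers(len(options)))]


def gen_genomes(config: SimConfig) -> tuple[str, str, list[SegmentAnnotation]]:
    """Generate host and wasp sequences with planted proviral segments.

    The wasp genome carries ``n_segments`` non-overlapping segments,
    each flanked by two identical DRJ copies; ``him_fraction`` of them
    carry a HIM (J2 + spacer + J1).  The J1 and J2 motifs are shared
    across segments (they are conserved motifs); DRJs and spacers are
    segment specific.  Spacer boundary bases are constrained to differ
    from the adjacent motif bases so canonical junctions carry no
    incidental wasp-side microhomology.  Deterministic for a fixed
    seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content

    j1_motif = _random_seq(rng, config.j1_length, gc)
    j2_motif = _random_seq(rng, config.j2_length, gc)

    n_him = int(round(config.him_fraction * config.n_segments))
    him_flags = np.zeros(config.n_segments, dtype=bool)
    him_flags[:n_him] = True
    rng.shuffle(him_flags)

    pieces: list[str] = []
    seg_specs: list[dict] = []
    for i in range(config.n_segments):
        drj = _random_seq(rng, config.drj_length, gc)
        a_len = int(rng.integers(350, 551))
        b_len = int(rng.integers(250, 451))
        a_seq = _random_seq(rng, a_len, gc)
        b_seq = _random_seq(rng, b_len, gc)
        if him_flags[i]:
            sp_len = (
                config.spacer_length
                if config.spacer_length is not None
                else int(rng.integers(41, 74))
            )
            spacer = list(_random_seq(rng, sp_len, gc))
            # no incidental microhomology at the canonical cuts
            if spacer[0] == j1_motif[0]:
                spacer[0] = _other_base(rng, j1_motif[0])
            if spacer[-1] == j2_motif[-1]:
                spacer[-1] = _other_base(rng, j2_motif[-1])
            him_seq = j2_motif + "".join(spacer) + j1_motif
        else:
            him_seq = ""
        seq = drj + a_seq + him_seq + b_seq + drj
        seg_specs.append(
            {
                "seq": seq,
                "a_len": a_len,
                "b_len": b_len,
                "him_len": len(him_seq),
                "has_him": bool(him_flags[i]),
            }
        )
        pieces.append(seq)

    total_seg = sum(len(p) for p in pieces)
    n_gaps = config.n_segments + 1
    if total_seg + n_gaps * 50 > config.wasp_length:
        raise SizingError(
            f"{config.n_segments} segments totalling {total_seg} bp do not fit "
            f"in a {config.wasp_length} bp wasp genome"
        )
    gap = (config.wasp_length - total_seg) // n_gaps

    wasp_parts: list[str] = []
    segments: list[SegmentAnnotation] = []
    cursor = 0
    for i, spec in enumerate(seg_specs):
        gap_seq = _random_seq(rng, gap, gc)
        wasp_parts.append(gap_seq)
        cursor += gap
        start = cursor + 1  # 1-based
        seq = spec["seq"]
        drj_len = config.drj_length
        drj5 = (start, start + drj_len - 1)
        him = j1 = j2 = None
        if spec["has_him"]:
            him_start = start + drj_len + spec["a_len"]
            him = (him_start, him_start + spec["him_len"] - 1)
            j2 = (him_start, him_start + config.j2_length - 1)
            j1 = (him[1] - config.j1_length + 1, him[1])
        end = start + len(seq) - 1
        drj3 = (end - drj_len + 1, end)
        segments.append(
            SegmentAnnotation(
                segment_id=f"S{i + 1}",
                contig=config.wasp_contig,
                start=start,
                end=end,
                drj5=drj5,
                drj3=drj3,
                him=him,
                j1=j1,
                j2=j2,
                j1_cut_offset=config.j1_cut_offset,
                j2_cut_offset=config.j2_cut_offset,
            )
        )
        wasp_parts.append(seq)
        cursor += len(seq)
    tail = config.wasp_length - cursor
    wasp_parts.append(_random_seq(rng, tail, gc))
    wasp = "".join(wasp_parts)

    host = _random_seq(rng, config.host_length, gc)
    return host, wasp, segments


def excise_circle(wasp_seq: str, seg: SegmentAnnotation) -> str:
    """Excise and circularize a proviral segment.

    Site-specific recombination between the two DRJ copies collapses
    them into one, so the circle is ``drj_length`` shorter than the
    segment.  The circle is returned linearized starting at the single
    retained DRJ.
    """
    if seg.drj3 is None:
        raise AnnotationError(f"{seg.segment_id} lacks a 3' DRJ; cannot circularize")
    d5 = wasp_seq[seg.drj5[0] - 1 : seg.drj5[1]]
    d3 = wasp_seq[seg.drj3[0] - 1 : seg.drj3[1]]
    if d5 != d3:
        raise AnnotationError(f"{seg.segment_id}: DRJ copies are not identical")
    return wasp_seq[seg.start - 1 : seg.drj3[0] - 1]


def insert_sequence(circle: str, seg: SegmentAnnotation) -> str:
    """Linearize a circle at the canonical J1/J2 cuts, dropping the spacer.

    The insert starts with the retained part of J1 and ends with the
    retained part of J2, matching the observed structure of integrated
    circles.
    """
    c1 = seg.j1_cut_circle  # first retained base (J1 side)
    c2 = seg.j2_cut_circle  # last retained base (J2 side)
    return circle[c1 - 1 :] + circle[:c2]


def _engineer_site(
    host: list[str],
    ins: str,
    before_1: str,
    after_1: str,
    p0: int,
    mh_len: int,
    rng: np.random.Generator,
) -> None:
    """Adjust host reference bases around an insertion point in place.

    Creates exactly ``mh_len`` bases of microhomology between each
    insert extremity and the flanking host sequence, and removes any
    incidental one-off matches so the doubly-aligned overlap measured
    downstream equals ``mh_len`` on both junctions.  ``p0`` is the
    0-based insertion index; ``before_1``/``after_1`` are the circle
    bases adjacent to the insert extremities (first lost spacer bases),
    which a wasp-side alignment could otherwise extend into.
    """
    m = mh_len
    if m > 0:
        host[p0 : p0 + m] = list(ins[:m])
        host[p0 - m : p0] = list(ins[-m:])
    if host[p0 + m] == ins[m]:
        host[p0 + m] = _other_base(rng, ins[m])
    if host[p0 - m - 1] == ins[-m - 1]:
        host[p0 - m - 1] = _other_base(rng, ins[-m - 1])
    if m == 0:
        if host[p0] in (ins[0], after_1):
            host[p0] = _other_base(rng, ins[0], after_1)
        if host[p0 - 1] in (ins[-1], before_1):
            host[p0 - 1] = _other_base(rng, ins[-1], before_1)


def _junction_context(
    circle: str, seg: SegmentAnnotation, orientation: str
) -> tuple[str, str, str]:
    """Insert sequence and the circle bases flanking its extremities."""
    ins = insert_sequence(circle, seg)
    c1, c2 = seg.j1_cut_circle, seg.j2_cut_circle
    before_fwd = circle[c1 - 2]  # last spacer base (precedes the J1 cut)
    after_fwd = circle[c2]  # first spacer base (follows the J2 cut)
    if orientation == "+":
        return ins, before_fwd, after_fwd
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return revcomp(ins), comp[after_fwd], comp[before_fwd]


def integrate_circle(
    host_seq: str,
    circle: str,
    seg: SegmentAnnotation,
    position: int,
    orientation: str = "+",
    mh_len: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, TruthEvent]:
    """Integrate one circle into the host sequence at ``position``.

    ``position`` is the 1-based host coordinate of the last base before
    the insert.  The host target site is adjusted so that exactly
    ``mh_len`` bases are shared between each insert extremity and the
    flanking host sequence; the canonical cuts on the circle never
    move.  Returns the modified host sequence (adjusted flanks plus
    insert) and the :class:`TruthEvent` recording all coordinates.
    """
    if not seg.has_him:
        raise AnnotationError(
            f"{seg.segment_id} has no HIM; non-HIM integration is not simulated"
        )
    if mh_len < 0:
        raise ValueError("mh_len must be >= 0")
    margin = mh_len + 2
    if not margin <= position <= len(host_seq) - margin:
        raise ValueError(f"position {position} too close to the host sequence end")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ins, before_1, after_1 = _junction_context(circle, seg, orientation)
    host = list(host_seq)
    _engineer_site(host, ins, before_1, after_1, position, mh_len, rng)
    modified = "".join(host[:position]) + ins + "".join(host[position:])
    truth = TruthEvent(
        segment_id=seg.segment_id,
        host_contig="host",
        host_position=position,
        orientation=orientation,
        microhomology_length=mh_len,
        inserted_length=len(ins),
    )
    return modified, truth


def simulate_reads(
    sources: Sequence[tuple[str, str, float]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw fixed-length reads from weighted sources.

    ``sources`` is a sequence of ``(source_id, sequence, depth)``.  For
    each source, ``round(depth * len / read_length)`` reads start at
    uniform positions on a uniform strand; substitution errors are
    applied at ``error_rate`` per base, and a ``pcr_dup_rate`` fraction
    of the reads is then duplicated exactly (same sequence, distinct
    identifiers).  Returns the reads and a truth table mapping each
    read to its source interval.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for source_id, seq, depth in sources:
        if depth <= 0:
            raise ValueError(f"depth for {source_id} must be > 0")
        if L > len(seq):
            raise ValueError(f"read_length {L} exceeds source {source_id} length")
        n = int(round(depth * len(seq) / L))
        starts = rng.integers(0, len(seq) - L + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        n_errs = rng.binomial(L, config.error_rate, size=n)
        for i in range(n):
            s = int(starts[i])
            frag = seq[s : s + L]
            strand = "+" if strands[i] == 0 else "-"
            if strand == "-":
                frag = revcomp(frag)
            ne = int(n_errs[i])
            if ne:
                frag_l = list(frag)
                for pos in rng.choice(L, size=ne, replace=False):
                    frag_l[pos] = _other_base(rng, frag_l[pos])
                frag = "".join(frag_l)
            read_id = f"{source_id}_r{i}"
            reads.append((read_id, frag))
            rows.append(
                {
                    "read_id": read_id,
                    "source_id": source_id,
                    "start": s + 1,
                    "end": s + L,
                    "strand": strand,
                    "n_errors": ne,
                    "duplicate_of": "",
                }
            )
    n_dup = int(round(config.pcr_dup_rate * len(reads)))
    if n_dup:
        dup_idx = rng.choice(len(reads), size=n_dup, replace=False)
        for j, idx in enumerate(sorted(int(x) for x in dup_idx)):
            rid, seq = reads[idx]
            dup_id = f"{rid}_dup{j}"
            reads.append((dup_id, seq))
            row = dict(rows[idx])
            row["read_id"] = dup_id
            row["duplicate_of"] = rid
            rows.append(row)
    return reads, pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """Everything one simulation produced, with full ground truth."""

    config: SimConfig
    host_ref: dict[str, str]  # alignment reference (microhomology-adjusted, no inserts)
    wasp: dict[str, str]
    integrated_host: dict[str, str]
    segments: list[SegmentAnnotation]
    circles: dict[str, str]
    truth_events: list[TruthEvent]
    reads: list[tuple[str, str]]
    read_truth: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generative model for one sample.

    Integration sites are placed on a jittered grid so neighbouring
    events stay more than two read lengths apart and every junction can
    be recovered independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    host, wasp, segments = gen_genomes(config)
    circles = {s.segment_id: excise_circle(wasp, s) for s in segments if s.drj3}

    him_segments = [s for s in segments if s.has_him]
    counts = {s.segment_id: 0 for s in him_segments}
    if config.n_integrations_by_segment is not None:
        unknown = set(config.n_integrations_by_segment) - set(counts)
        if unknown:
            raise ValueError(f"integration counts for non-HIM segments: {sorted(unknown)}")
        counts.update(config.n_integrations_by_segment)
    elif config.n_integrations_total is not None:
        for i in range(config.n_integrations_total):
            counts[him_segments[i % len(him_segments)].segment_id] += 1
    else:
        for s in him_segments:
            counts[s.segment_id] = config.n_integrations_per_segment
    n_events = sum(counts.values())

    truth_events: list[TruthEvent] = []
    host_list = list(host)
    inserts: list[tuple[int, str]] = []  # (0-based insertion index, sequence)
    if n_events:
        min_sep = 2 * config.read_length + 50
        margin = config.read_length + 20
        spacing = (config.host_length - 2 * margin) // n_events
        if spacing < min_sep:
            raise SizingError(
                f"{n_events} integrations do not fit in a {config.host_length} bp host "
                f"with {min_sep} bp separation"
            )
        jitter = rng.integers(0, spacing - min_sep + 1, size=n_events)
        positions = [margin + i * spacing + int(jitter[i]) for i in range(n_events)]

        mh_lengths = sorted(config.microhomology_probs)
        probs = np.array([config.microhomology_probs[k] for k in mh_lengths], dtype=float)
        probs = probs / probs.sum()

        event_segments = [
            seg for seg in him_segments for _ in range(counts[seg.segment_id])
        ]
        perm = rng.permutation(n_events)
        event_segments = [event_segments[int(i)] for i in perm]
        for seg, p0 in zip(event_segments, positions):
            orientation = "+" if rng.integers(0, 2) == 0 else "-"
            m = int(mh_lengths[int(rng.choice(len(mh_lengths), p=probs))])
            ins, before_1, after_1 = _junction_context(
                circles[seg.segment_id], seg, orientation
            )
            _engineer_site(host_list, ins, before_1, after_1, p0, m, rng)
            inserts.append((p0, ins))
            truth_events.append(
                TruthEvent(
                    segment_id=seg.segment_id,
                    host_contig=config.host_contig,
                    host_position=p0,
                    orientation=orientation,
                    microhomology_length=m,
                    inserted_length=len(ins),
                )
            )

    host_ref = "".join(host_list)
    parts: list[str] = []
    prev = 0
    for p0, ins in sorted(inserts):
        parts.append(host_ref[prev:p0])
        parts.append(ins)
        prev = p0
    parts.append(host_ref[prev:])
    integrated = "".join(parts)

    sources: list[tuple[str, str, float]] = [
        (config.host_contig, integrated, config.depth_host),
        (config.wasp_contig, wasp, config.depth_wasp),
    ]
    for seg_id, depth in config.circle_depths.items():
        # free (non-integrated) circles; doubled so reads can span the origin
        circ = circles[seg_id]
        sources.append((f"circle_{seg_id}", circ + circ[: config.read_length], depth))
    reads, read_truth = simulate_reads(sources, config, rng)

    return SimulatedDataset(
        config=config,
        host_ref={config.host_contig: host_ref},
        wasp={config.wasp_contig: wasp},
        integrated_host={config.host_contig: integrated},
        segments=segments,
        circles=circles,
        truth_events=truth_events,
        reads=reads,
        read_truth=read_truth,
    )


def segment_gff_features(segments: Sequence[SegmentAnnotation]):
    for seg in segments:
        attrs = {"ID": seg.segment_id}
        yield (seg.contig, "synthdata", "segment", seg.start, seg.end, None, "+", attrs)
        yield (
            seg.contig, "synthdata", "DRJ", seg.drj5[0], seg.drj5[1], None, "+",
            {"ID": f"{seg.segment_id}_DRJ5", "Parent": seg.segment_id},
        )
        if seg.drj3:
            yield (
                seg.contig, "synthdata", "DRJ", seg.drj3[0], seg.drj3[1], None, "+",
                {"ID": f"{seg.segment_id}_DRJ3", "Parent": seg.segment_id},
            )
        if seg.has_him:
            yield (
                seg.contig, "synthdata", "HIM", seg.him[0], seg.him[1], None, "+",
                {"ID": f"{seg.segment_id}_HIM", "Parent": seg.segment_id},
            )
            yield (
                seg.contig, "synthdata", "J2", seg.j2[0], seg.j2[1], None, "+",
                {"ID": f"{seg.segment_id}_J2", "Parent": f"{seg.segment_id}_HIM"},
            )
            yield (
                seg.contig, "synthdata", "J1", seg.j1[0], seg.j1[1], None, "+",
                {"ID": f"{seg.segment_id}_J1", "Parent": f"{seg.segment_id}_HIM"},
            )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize a dataset (FASTA/GFF3/FASTQ/TSV) and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host_fasta": outdir / "host.fasta",
        "wasp_fasta": outdir / "wasp.fasta",
        "integrated_fasta": outdir / "host_integrated.fasta",
        "circles_fasta": outdir / "circles.fasta",
        "segments_gff": outdir / "segments.gff3",
        "reads_fastq": outdir / "reads.fastq",
        "read_truth": outdir / "read_truth.tsv",
        "truth_events": outdir / "truth_events.tsv",
    }
    write_fasta(paths["host_fasta"], ds.host_ref)
    write_fasta(paths["wasp_fasta"], ds.wasp)
    write_fasta(paths["integrated_fasta"], ds.integrated_host)
    write_fasta(paths["circles_fasta"], ds.circles)
    write_gff3(paths["segments_gff"], segment_gff_features(ds.segments))
    write_fastq(paths["reads_fastq"], ds.reads)
    ds.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    pd.DataFrame([vars(t) for t in ds.truth_events]).to_csv(
        paths["truth_events"], sep="\t", index=False
    )
    return paths
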