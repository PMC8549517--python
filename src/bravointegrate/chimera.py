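"""Wasp-host chimeric read detection from tabular alignments.

A chimeric read aligns partly to a bracovirus proviral segment (wasp
genome) and partly to the caterpillar host genome, and is the read-level
evidence of one integration junction.  Candidate reads are classified
from their best alignment on each genome with four filters:

  (i)   at least ``min_side`` bases align only on the wasp genome and
        at least ``min_side`` other bases align only on the host;
  (ii)  fewer than ``max_unaligned_frac`` of the read bases align to
        neither genome (flanking unaligned bases plus any gap between
        the two alignments);
  (iii) no more than ``max_overlap`` bases align to both genomes at
        once -- the doubly-aligned overlap is the junction
        microhomology;
  (iv)  no more than ``max_insert`` bases lie between the two
        alignments -- non-templated insertions at the junction.

The junction position on the wasp genome is taken as the wasp alignment
end coordinate on the junction side regardless of any overlap, so a
k-bp microhomology shifts the apparent junction by up to k bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: canonical 12-column tabular alignment dialect (BLAST outfmt 6)
TABLE_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


class TabularFormatError(ValueError):
    """Raised when an alignment table cannot be parsed."""


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against one genome.

    Read coordinates (``read_start``/``read_end``) are 1-based inclusive
    and ascending on the read.  Subject coordinates are 1-based
    inclusive ascending on the forward strand of the subject; ``strand``
    records the alignment orientation.
    """

    read_id: str
    genome: str  # "wasp" | "host"
    subject_id: str
    read_start: int
    read_end: int
    subject_start: int
    subject_end: int
    strand: str  # "+" | "-"
    percent_identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.read_start <= self.read_end):
            raise ValueError(f"bad read interval for {self.read_id}")
        if self.subject_start > self.subject_end:
            raise ValueError(f"subject interval not normalized for {self.read_id}")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1

    def subject_coord_at(self, read_pos: int) -> int:
        """Subject coordinate aligned with ``read_pos`` (ungapped model)."""
        offset = read_pos - self.read_start
        if self.strand == "+":
            return self.subject_start + offset
        return self.subject_end - offset


@dataclass
class ChimericRead:
    """One accepted wasp-host chimeric read with its junction geometry."""

    read_id: str
    wasp_interval: tuple[int, int]  # read coordinates, 1-based inclusive
    host_interval: tuple[int, int]
    wasp_subject: str
    host_subject: str
    junction_on_wasp: int  # wasp subject coordinate at the junction side
    junction_on_host: int  # host subject coordinate at the junction side
    orientation: str  # "+" if wasp and host align on the same strand
    overlap_len: int  # doubly-aligned bases (microhomology)
    insert_len: int  # non-templated bases between the two alignments
    unaligned_len: int  # flanking bases aligning to neither genome
    wasp_side: str  # "left" | "right": side of the read the wasp part occupies
    wasp_strand: str = "+"
    host_strand: str = "+"
    wasp_subject_interval: tuple[int, int] = (0, 0)
    host_subject_interval: tuple[int, int] = (0, 0)
    segment_id: str | None = None
    circle_pos: int | None = None  # junction position on the circle (5'DRJ->3'DRJ)
    junction_class: str | None = None  # J1 | J2 | HIM_other | outside_HIM

    @property
    def host_breakpoint(self) -> int:
        """Host coordinate of the last host base before the insertion.

        When the host alignment abuts the junction at its high
        (forward-strand) end the raw junction coordinate already names
        that base; when it abuts at its low end the raw coordinate
        names the first base after the insertion, so one is subtracted.
        With zero microhomology both junctions of one integration then
        report the same breakpoint.
        """
        abuts_high_end = (self.wasp_side == "left") == (self.host_strand == "-")
        if abuts_high_end:
            return self.junction_on_host
        return self.junction_on_host - 1


@dataclass(frozen=True)
class Thresholds:
    """Chimera acceptance filters (defaults follow the published pipeline)."""

    min_side: int = 16
    max_unaligned_frac: float = 0.10
    max_overlap: int = 20
    max_insert: int = 5


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str
    filter_id: str  # "i" | "ii" | "iii" | "iv" | other


def parse_alignment_table(path: str, genome: str) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into :class:`AlignmentHit`.

    Rows with swapped query coordinates (a minus-strand dialect) or
    swapped subject coordinates are normalized so read coordinates
    ascend and strand is explicit.  Malformed rows raise
    :class:`TabularFormatError` listing the offending line numbers.
    """
    hits: list[AlignmentHit] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(TABLE_COLUMNS):
                bad.append(lineno)
                continue
            try:
                hit = _hit_from_row(parts, genome)
            except (ValueError, TypeError):
                bad.append(lineno)
                continue
            hits.append(hit)
    if bad:
        raise TabularFormatError(
            f"{path}: malformed rows at lines {', '.join(map(str, bad))}"
        )
    return hits


def _hit_from_row(parts: Sequence[str], genome: str) -> AlignmentHit:
    qseqid, sseqid = parts[0], parts[1]
    pident = float(parts[2])
    qstart, qend = int(parts[6]), int(parts[7])
    sstart, send = int(parts[8]), int(parts[9])
    bitscore = float(parts[11])
    strand = "+"
    if qstart > qend:  # minus-strand dialect on the query
        qstart, qend = qend, qstart
        strand = "-" if strand == "+" else "+"
        sstart, send = min(sstart, send), max(sstart, send)
    if sstart > send:
        sstart, send = send, sstart
        strand = "-"
    return AlignmentHit(
        read_id=qseqid,
        genome=genome,
        subject_id=sseqid,
        read_start=qstart,
        read_end=qend,
        subject_start=sstart,
        subject_end=send,
        strand=strand,
        percent_identity=pident,
        bitscore=bitscore,
    )


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])


def select_best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Deterministic best hit for one read on one genome.

    Highest bitscore wins; ties break by higher percent identity, then
    lexicographically smallest subject id, then smallest subject start.
    """
    if not hits:
        return None
    ids = {(h.read_id, h.genome) for h in hits}
    if len(ids) > 1:
        raise ValueError("select_best_hit requires hits from one read and one genome")
    return min(
        hits,
        key=lambda h: (-h.bitscore, -h.percent_identity, h.subject_id, h.subject_start),
    )


def best_hits_per_read(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit per read id (all hits must come from the same genome)."""
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.read_id, []).append(h)
    return {rid: select_best_hit(hs) for rid, hs in grouped.items()}


def is_ambiguous(
    hits: Sequence[AlignmentHit],
    best: AlignmentHit,
    tie_slack: int = 5,
    score_margin: float = 16.0,
) -> bool:
    """True when a distinct-location hit comes within ``score_margin``
    bitscore of the best hit.

    Conserved motifs (HIM/J1/J2 copies shared between segments, DRJs)
    make short read portions multi-mapping; a wrong copy can even score
    a few bases above the true one by chance extension across the
    junction.  Requiring a clear score margin (16 bitscore is about 8
    matching bases) excludes reads that cannot be confidently assigned
    to a single junction.
    """
    for h in hits:
        if h is best:
            continue
        if h.bitscore < best.bitscore - score_margin:
            continue
        if h.subject_id != best.subject_id or abs(h.subject_start - best.subject_start) > tie_slack:
            return True
    return False


def classify_chimera(
    read_length: int,
    wasp_hit: AlignmentHit,
    host_hit: AlignmentHit,
    thresholds: Thresholds = Thresholds(),
) -> ChimericRead | Rejection:
    """Apply the four chimera filters to a (wasp hit, host hit) pair.

    Decomposes the read into wasp-only, host-only, doubly-aligned
    (overlap = microhomology), inserted (gap between alignments) and
    flanking unaligned bases; these five counts always sum to
    ``read_length``.
    """
    if wasp_hit.read_id != host_hit.read_id:
        raise ValueError("hits belong to different reads")
    ws, we = wasp_hit.read_start, wasp_hit.read_end
    hs, he = host_hit.read_start, host_hit.read_end

    overlap = max(0, min(we, he) - max(ws, hs) + 1)
    gap = max(0, max(ws, hs) - min(we, he) - 1)
    wasp_only = (we - ws + 1) - overlap
    host_only = (he - hs + 1) - overlap
    unaligned_flank = (min(ws, hs) - 1) + (read_length - max(we, he))
    unaligned_total = unaligned_flank + gap

    rid = wasp_hit.read_id
    if wasp_only < thresholds.min_side or host_only < thresholds.min_side:
        return Rejection(rid, f"<{thresholds.min_side} bases exclusive to one genome", "i")
    if unaligned_total >= thresholds.max_unaligned_frac * read_length:
        return Rejection(rid, f"{unaligned_total} bases align to neither genome", "ii")
    if overlap > thresholds.max_overlap:
        return Rejection(rid, f"{overlap} bases align to both genomes", "iii")
    if gap > thresholds.max_insert:
        return Rejection(rid, f"{gap} bases inserted at the junction", "iv")

    wasp_side = "left" if (ws + we) <= (hs + he) else "right"
    if wasp_side == "left":
        junction_on_wasp = wasp_hit.subject_coord_at(we)
        junction_on_host = host_hit.subject_coord_at(hs)
    else:
        junction_on_wasp = wasp_hit.subject_coord_at(ws)
        junction_on_host = host_hit.subject_coord_at(he)

    return ChimericRead(
        read_id=rid,
        wasp_interval=(ws, we),
        host_interval=(hs, he),
        wasp_subject=wasp_hit.subject_id,
        host_subject=host_hit.subject_id,
        junction_on_wasp=junction_on_wasp,
        junction_on_host=junction_on_host,
        orientation="+" if wasp_hit.strand == host_hit.strand else "-",
        overlap_len=overlap,
        insert_len=gap,
        unaligned_len=unaligned_flank,
        wasp_side=wasp_side,
        wasp_strand=wasp_hit.strand,
        host_strand=host_hit.strand,
        wasp_subject_interval=(wasp_hit.subject_start, wasp_hit.subject_end),
        host_subject_interval=(host_hit.subject_start, host_hit.subject_end),
    )


def find_chimeras(
    wasp_hits: Iterable[AlignmentHit],
    host_hits: Iterable[AlignmentHit],
    read_lengths: int | dict[str, int],
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[ChimericRead], list[Rejection]]:
    """Classify every read with a best hit on both genomes.

    ``read_lengths`` is either a constant read length or a per-read map.
    Reads with a hit on only one genome are silently ignored (they are
    ordinary non-chimeric reads); reads whose best hit on either genome
    ties with a distinct location (multi-mapping over conserved motif
    copies) are rejected as ambiguous.
    """
    grouped: dict[str, dict[str, list[AlignmentHit]]] = {"wasp": {}, "host": {}}
    for h in wasp_hits:
        grouped["wasp"].setdefault(h.read_id, []).append(h)
    for h in host_hits:
        grouped["host"].setdefault(h.read_id, []).append(h)
    accepted: list[ChimericRead] = []
    rejected: list[Rejection] = []
    for rid in sorted(set(grouped["wasp"]) & set(grouped["host"])):
        length = read_lengths if isinstance(read_lengths, int) else read_lengths[rid]
        pair = {}
        ambiguous = None
        for genome in ("wasp", "host"):
            hits = grouped[genome][rid]
            best = select_best_hit(hits)
            if is_ambiguous(hits, best):
                ambiguous = genome
                break
            pair[genome] = best
        if ambiguous:
            rejected.append(
                Rejection(rid, f"best {ambiguous} hit is ambiguous (multi-mapping)", "amb")
            )
            continue
        result = classify_chimera(length, pair["wasp"], pair["host"], thresholds)
        if isinstance(result, ChimericRead):
            accepted.append(result)
        else:
            rejected.append(result)
    return accepted, rejected


def dedupe_pcr(chimeras: Sequence[ChimericRead]) -> tuple[list[ChimericRead], int]:
    """Collapse PCR duplicates to one representative.

    Two chimeras are duplicates when they are identical in junction
    coordinates on both genomes, orientation, and the alignment
    boundaries on both genomes (identical sequenced fragments).  Reads
    from independent fragments that happen to share a junction differ
    in their boundaries and are both retained.  Idempotent.
    """
    seen: dict[tuple, ChimericRead] = {}
    for c in chimeras:
        key = (
            c.wasp_subject,
            c.junction_on_wasp,
            c.host_subject,
            c.junction_on_host,
            c.orientation,
            c.wasp_subject_interval,
            c.host_subject_interval,
        )
        if key not in seen:
            seen[key] = c
    unique = list(seen.values())
    return unique, len(chimeras) - len(unique)


def chimeras_to_frame(chimeras: Sequence[ChimericRead]) -> pd.DataFrame:
    rows = []
    for c in chimeras:
        rows.append(
            {
                "read_id": c.read_id,
                "segment_id": c.segment_id,
                "wasp_subject": c.wasp_subject,
                "host_subject": c.host_subject,
                "wasp_read_start": c.wasp_interval[0],
                "wasp_read_end": c.wasp_interval[1],
                "host_read_start": c.host_interval[0],
                "host_read_end": c.host_interval[1],
                "junction_on_wasp": c.junction_on_wasp,
                "junction_on_host": c.junction_on_host,
                "host_breakpoint": c.host_breakpoint,
                "circle_pos": c.circle_pos,
                "junction_class": c.junction_class,
                "orientation": c.orientation,
                "overlap_len": c.overlap_len,
                "insert_len": c.insert_len,
                "unaligned_len": c.unaligned_len,
                "wasp_side": c.wasp_side,
            }
        )
    return pd.DataFrame(rows)
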