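"""Motif annotation on a wasp genome: DRJs, HIMs, and duplication calls.

Proviral circle sequences can re-enter the wasp germ-line genome.  Two
signatures distinguish these accidental duplications from ordinary
proviral segments:

* Hdp (HIM-mediated duplication): an integrated circle copy flanked by
  the J1 motif at one extremity and the J2 motif at the other --
  exactly the structure left in a host genome after HIM-mediated
  integration -- and without DRJs at its extremities.  A similarity
  search with the full HIM query then hits one *half* of the motif at
  each extremity.
* Rdp (rearranged duplication): a circle-derived copy carrying a
  single internal DRJ (the relic of circularization), with neither
  flanking DRJs nor flanking J1/J2 motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import ReferenceIndex


@dataclass(frozen=True)
class MotifHit:
    """One similarity hit of a motif on a genome (1-based inclusive,
    forward-strand genome coordinates)."""

    motif_id: str
    contig: str
    start: int
    end: int
    strand: str
    percent_identity: float
    motif_start: int = 0  # interval covered on the motif itself
    motif_end: int = 0
    motif_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")


@dataclass
class DuplicationCall:
    parent_segment_id: str
    contig: str
    start: int
    end: int
    kind: str  # "Hdp" | "Rdp"
    evidence: list[MotifHit] = field(default_factory=list)


def search_motifs(
    genome: Mapping[str, str],
    motifs: Mapping[str, str],
    min_identity: float = 80.0,
    min_score: int = 14,
    k: int = 12,
) -> list[MotifHit]:
    """Local similarity search of motifs against both genome strands.

    Coordinates are reported 1-based inclusive on the forward strand;
    reverse-strand hits carry ``strand='-'``.  Empty genomes and empty
    motif sets are usage errors.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if not motifs:
        raise ValueError("no motifs given")
    index = ReferenceIndex(dict(genome), k=k)
    hits: list[MotifHit] = []
    for motif_id, seq in motifs.items():
        for aln in index.align_read(
            motif_id, seq, genome="genome", seed_stride=1, min_score=min_score, max_hits=50
        ):
            if aln.percent_identity < min_identity:
                continue
            hits.append(
                MotifHit(
                    motif_id=motif_id,
                    contig=aln.subject_id,
                    start=aln.subject_start,
                    end=aln.subject_end,
                    strand=aln.strand,
                    percent_identity=aln.percent_identity,
                    motif_start=aln.read_start,
                    motif_end=aln.read_end,
                    motif_length=len(seq),
                )
            )
    hits.sort(key=lambda h: (h.contig, h.start, h.motif_id))
    return hits


def _half_of_him(hit: MotifHit, min_frac: float = 0.8) -> str | None:
    """Classify a HIM hit as lying on the J2 (left) or J1 (right) half.

    A hit is a half-HIM when at least ``min_frac`` of its aligned motif
    interval falls on one side of the motif midpoint (the spacer) and
    at most ``1 - min_frac`` on the other; full-HIM hits (intact
    proviral segments) straddle both halves and return None.
    """
    if hit.motif_length <= 0:
        return None
    mid = hit.motif_length // 2
    hit_len = hit.motif_end - hit.motif_start + 1
    cov_left = max(0, min(hit.motif_end, mid) - hit.motif_start + 1)
    cov_right = max(0, hit.motif_end - max(hit.motif_start, mid + 1) + 1)
    if cov_left / hit_len >= min_frac and cov_right / hit_len <= 1 - min_frac:
        return "J2half"
    if cov_right / hit_len >= min_frac and cov_left / hit_len <= 1 - min_frac:
        return "J1half"
    return None


def call_him_duplications(
    him_hits: Sequence[MotifHit],
    junction_hits: Sequence[MotifHit] | None,
    drj_hits: Sequence[MotifHit],
    segment_hits: Sequence[MotifHit] | None = None,
    slack: int = 10,
    max_span: int = 50_000,
    min_span: int = 100,
) -> list[DuplicationCall]:
    """Detect Hdp and Rdp duplications from motif search outputs.

    Hdp: a pair of half-HIM hits bounding a region, the J1-containing
    half outermost on the 5' side for forward copies (mirrored on the
    reverse strand), with no DRJ hit at either extremity; when
    junction-query hits are supplied they must overlap the half-HIM
    hits to within ``slack``.  Rdp (requires ``segment_hits``): a
    segment-homologous region containing exactly one internal DRJ hit,
    with neither terminal DRJs nor terminal half-HIM hits.  Empty
    inputs produce empty output.
    """
    calls: list[DuplicationCall] = []

    halves = [(h, _half_of_him(h)) for h in him_hits]
    halves = [(h, side) for h, side in halves if side is not None]
    by_contig: dict[str, list[tuple[MotifHit, str]]] = {}
    for h, side in halves:
        by_contig.setdefault(h.contig, []).append((h, side))

    for contig, items in sorted(by_contig.items()):
        items.sort(key=lambda t: t[0].start)
        for (a, side_a), (b, side_b) in zip(items, items[1:]):
            if side_a == side_b:
                continue
            span = b.end - a.start + 1
            if not min_span <= span <= max_span:
                continue
            if a.strand == b.strand == "+" and side_a != "J1half":
                continue
            if a.strand == b.strand == "-" and side_a != "J2half":
                continue
            if a.strand != b.strand:
                continue
            # terminal DRJs would make this an ordinary proviral segment
            if any(
                d.contig == contig
                and (
                    (d.start <= a.end + slack and d.end >= a.start - slack)
                    or (d.start <= b.end + slack and d.end >= b.start - slack)
                )
                for d in drj_hits
            ):
                continue
            if junction_hits is not None:
                def _supported(h: MotifHit) -> bool:
                    return any(
                        j.contig == contig
                        and j.start <= h.end + slack
                        and j.end >= h.start - slack
                        for j in junction_hits
                    )
                if not (_supported(a) and _supported(b)):
                    continue
            calls.append(
                DuplicationCall(
                    parent_segment_id=a.motif_id,
                    contig=contig,
                    start=a.start,
                    end=b.end,
                    kind="Hdp",
                    evidence=[a, b],
                )
            )

    if segment_hits:
        regions = _merge_regions(segment_hits)
        for motif_id, contig, rs, re_ in regions:
            drjs_in = [
                d for d in drj_hits if d.contig == contig and d.start >= rs and d.end <= re_
            ]
            terminal = [
                d for d in drjs_in
                if d.start - rs <= slack or re_ - d.end <= slack
            ]
            internal = [d for d in drjs_in if d not in terminal]
            half_at_ends = [
                h for h, side in halves
                if h.contig == contig
                and (abs(h.start - rs) <= slack or abs(h.end - re_) <= slack)
            ]
            if len(internal) == 1 and not terminal and not half_at_ends:
                calls.append(
                    DuplicationCall(
                        parent_segment_id=motif_id,
                        contig=contig,
                        start=rs,
                        end=re_,
                        kind="Rdp",
                        evidence=internal,
                    )
                )
    calls.sort(key=lambda c: (c.contig, c.start, c.kind))
    return calls


def _merge_regions(hits: Sequence[MotifHit], join_gap: int = 100) -> list[tuple[str, str, int, int]]:
    """Merge per-(motif, contig) hits closer than ``join_gap`` into regions."""
    grouped: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        grouped.setdefault((h.motif_id, h.contig), []).append(h)
    regions = []
    for (motif_id, contig), hs in sorted(grouped.items()):
        hs.sort(key=lambda h: h.start)
        cur_s, cur_e = hs[0].start, hs[0].end
        for h in hs[1:]:
            if h.start <= cur_e + join_gap:
                cur_e = max(cur_e, h.end)
            else:
                regions.append((motif_id, contig, cur_s, cur_e))
                cur_s, cur_e = h.start, h.end
        regions.append((motif_id, contig, cur_s, cur_e))
    return regions
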