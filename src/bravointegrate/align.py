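"""Read-to-genome alignment producing the 12-column tabular dialect.

Two engines emit the same dialect:

* :class:`ReferenceIndex` -- a built-in gapless seed-and-extend aligner
  (k-mer seeding, X-drop extension, substitution-aware).  It is exact
  for the substitution-only reads produced by the synthetic-data module
  and fast enough to realign whole simulated datasets in pure Python.
* :func:`run_blastn` -- a thin wrapper around the NCBI ``blastn``
  binary, for real genomes and as an independent cross-check of the
  built-in engine.

Since the synthetic reads contain no indels (see synthdata non-goals),
a gapless extension model loses nothing on simulated data.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

from .chimera import AlignmentHit
from .io import revcomp, write_fasta

_MATCH = 1
_MISMATCH = -3
_XDROP = 9


class ReferenceIndex:
    """K-mer index of a reference genome for gapless local alignment."""

    def __init__(self, contigs: dict[str, str], k: int = 12, max_positions: int = 64):
        self.k = k
        self.contig_names = list(contigs)
        self.contig_seqs = [contigs[name].upper() for name in self.contig_names]
        index: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(self.contig_seqs):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                slot = index.setdefault(kmer, [])
                if len(slot) < max_positions:
                    slot.append((ci, pos))
        self._index = index

    def align_read(
        self,
        read_id: str,
        seq: str,
        genome: str,
        seed_stride: int = 4,
        min_score: int = 14,
        max_hits: int = 5,
    ) -> list[AlignmentHit]:
        """All local alignments of ``seq`` against the index, both strands.

        ``seed_stride`` of 4 with k=12 guarantees a sampled seed inside
        any exactly matching read region of >= 16 bp, the shortest side
        the chimera filters accept.
        """
        raw: list[tuple] = []
        for strand, query in (("+", seq.upper()), ("-", revcomp(seq).upper())):
            found: list[tuple[int, int, int, int]] = []  # (ci, diag, qs, qe)
            k = self.k
            positions = range(0, max(1, len(query) - k + 1), seed_stride)
            for qi in positions:
                for ci, spos in self._index.get(query[qi : qi + k], ()):
                    diag = spos - qi
                    if any(
                        ci == fci and abs(diag - fd) <= 2 and fqs <= qi <= fqe
                        for fci, fd, fqs, fqe in found
                    ):
                        continue
                    aln = _extend(query, self.contig_seqs[ci], qi, spos)
                    if aln is None:
                        continue
                    qs, qe, ss, se, matches, score = aln
                    if score < min_score:
                        continue
                    found.append((ci, diag, qs, qe))
                    raw.append((strand, ci, qs, qe, ss, se, matches, score))
        raw.sort(key=lambda r: (-r[7], r[1], r[4]))
        hits: list[AlignmentHit] = []
        n = len(seq)
        seen: set[tuple] = set()
        for strand, ci, qs, qe, ss, se, matches, score in raw[: max_hits * 2]:
            if strand == "-":  # map query coords back to the original read
                qs, qe = n - 1 - qe, n - 1 - qs
            key = (strand, ci, qs, qe, ss)
            if key in seen:
                continue
            seen.add(key)
            length = qe - qs + 1
            hits.append(
                AlignmentHit(
                    read_id=read_id,
                    genome=genome,
                    subject_id=self.contig_names[ci],
                    read_start=qs + 1,
                    read_end=qe + 1,
                    subject_start=ss + 1,
                    subject_end=se + 1,
                    strand=strand,
                    percent_identity=round(100.0 * matches / length, 2),
                    bitscore=float(2 * score),
                )
            )
            if len(hits) >= max_hits:
                break
        return hits

    def align_reads(
        self, reads: Iterable[tuple[str, str]], genome: str, **kwargs
    ) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        for read_id, seq in reads:
            hits.extend(self.align_read(read_id, seq, genome, **kwargs))
        return hits


def _extend(query: str, subject: str, qi: int, si: int):
    """Gapless X-drop extension around a seed; returns the max-score HSP.

    Coordinates returned are 0-based inclusive.  ``None`` when the seed
    base itself mismatches (cannot happen for seeds from the index).
    """
    nq, ns = len(query), len(subject)

    # right extension (including the seed base at qi/si)
    score = 0
    best = -1
    best_right = (qi - 1, si - 1, 0)  # (qe, se, matches)
    matches = 0
    q, s = qi, si
    while q < nq and s < ns:
        score += _MATCH if query[q] == subject[s] else _MISMATCH
        if query[q] == subject[s]:
            matches += 1
        if score > best:
            best = score
            best_right = (q, s, matches)
        if best - score > _XDROP:
            break
        q += 1
        s += 1
    right_score = max(best, 0)
    qe, se, right_matches = best_right

    # left extension (excluding qi)
    score = 0
    best = 0
    best_left = (qi, si, 0)
    matches = 0
    q, s = qi - 1, si - 1
    while q >= 0 and s >= 0:
        score += _MATCH if query[q] == subject[s] else _MISMATCH
        if query[q] == subject[s]:
            matches += 1
        if score > best:
            best = score
            best_left = (q, s, matches)
        if best - score > _XDROP:
            break
        q -= 1
        s -= 1
    left_score = best
    qs, ss, left_matches = best_left

    if qe < qs:
        return None
    total = right_score + left_score
    return qs, qe, ss, se, left_matches + right_matches, total


def hits_to_table(hits: Sequence[AlignmentHit], path: str) -> None:
    """Serialize hits as 12-column rows (subject coords descend on minus)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.subject_start, h.subject_end
            else:
                ss, se = h.subject_end, h.subject_start
            length = h.read_end - h.read_start + 1
            mismatch = round(length * (1 - h.percent_identity / 100))
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.read_id,
                        h.subject_id,
                        h.percent_identity,
                        length,
                        mismatch,
                        0,
                        h.read_start,
                        h.read_end,
                        ss,
                        se,
                        0.0,
                        h.bitscore,
                    )
                )
                + "\n"
            )


def run_blastn(
    query_fasta: str,
    subject_fasta: str,
    out_path: str,
    task: str = "blastn",
    word_size: int = 11,
    evalue: float = 1e-3,
    max_target_seqs: int = 5,
) -> str:
    """Run ``blastn`` and write 12-column tabular output to ``out_path``."""
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn executable not found on PATH")
    cmd = [
        "blastn",
        "-task",
        task,
        "-word_size",
        str(word_size),
        "-evalue",
        str(evalue),
        "-max_target_seqs",
        str(max_target_seqs),
        "-dust",
        "no",
        "-query",
        str(query_fasta),
        "-subject",
        str(subject_fasta),
        "-outfmt",
        "6",
        "-out",
        str(out_path),
    ]
    subprocess.run(cmd, check=True, capture_output=True)
    return out_path


def blastn_hits(
    reads: Iterable[tuple[str, str]], contigs: dict[str, str], genome: str, **kwargs
) -> list[AlignmentHit]:
    """Align reads with blastn and return parsed hits."""
    from .chimera import parse_alignment_table

    with tempfile.TemporaryDirectory() as tmp:
        qpath = str(Path(tmp) / "reads.fasta")
        spath = str(Path(tmp) / "ref.fasta")
        opath = str(Path(tmp) / "hits.tsv")
        write_fasta(qpath, dict(reads))
        write_fasta(spath, contigs)
        run_blastn(qpath, spath, opath, **kwargs)
        return parse_alignment_table(opath, genome)
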