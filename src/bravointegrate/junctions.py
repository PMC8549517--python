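"""Junction localization on circles, J-region delineation and the
microhomology null model.

Junction positions of chimeric reads are expressed on the circle
oriented 5'DRJ -> 3'DRJ.  Within a HIM, junctions pile up in two modes:
the J2 region (left) and the J1 region (right), separated by the
spacer that is lost upon integration.  Observed junction microhomology
lengths are compared against random chimeric reads simulated in silico
from the same sequences and pushed through the production chimera
classification, so the null inherits every quirk of the real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .chimera import AlignmentHit, ChimericRead, Thresholds, classify_chimera
from .synthdata import SegmentAnnotation


@dataclass
class JunctionHistogram:
    """Per-position counts of chimeric-read junctions along one circle."""

    segment_id: str
    counts: np.ndarray  # length = circle length; index 0 = circle position 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MicrohomologyDistribution:
    """Counts of junction microhomology lengths (and insertion lengths)."""

    label: str  # "observed" | "expected"
    mh_counts: np.ndarray  # index = microhomology length, 0..L_max
    insertion_counts: np.ndarray  # index = insertion length, 0..max_insert

    @property
    def total(self) -> int:
        return int(self.mh_counts.sum())


@dataclass
class JRegions:
    """Empirically delineated J2 (left) and J1 (right) intervals on a circle."""

    segment_id: str
    j2: tuple[int, int] | None
    j1: tuple[int, int] | None

    @property
    def separation(self) -> int | None:
        """Gap between the two regions; tracks the spacer length."""
        if self.j1 is None or self.j2 is None:
            return None
        return self.j1[0] - self.j2[1] - 1


def annotate_chimeras(
    chimeras: Iterable[ChimericRead], segments: Sequence[SegmentAnnotation]
) -> list[ChimericRead]:
    """Assign each chimera to the segment containing its wasp junction.

    Sets ``segment_id`` and the circle coordinate of the junction.
    Chimeras whose wasp junction falls outside every annotated segment
    are retained with ``segment_id`` left as ``None`` (they feed the
    outside-segment baseline), never discarded.
    """
    trees: dict[str, IntervalTree] = {}
    for seg in segments:
        trees.setdefault(seg.contig, IntervalTree()).addi(seg.start, seg.end + 1, seg)
    out = []
    for c in chimeras:
        tree = trees.get(c.wasp_subject)
        hits = tree[c.junction_on_wasp] if tree is not None else set()
        if hits:
            seg = min(hits, key=lambda iv: iv.data.segment_id).data
            c.segment_id = seg.segment_id
            c.circle_pos = seg.genome_to_circle(c.junction_on_wasp)
        out.append(c)
    return out


def junction_histogram(
    chimeras: Iterable[ChimericRead], seg: SegmentAnnotation
) -> JunctionHistogram:
    """Count junction positions of a segment's chimeras along its circle."""
    counts = np.zeros(seg.circle_length, dtype=int)
    for c in chimeras:
        if c.segment_id != seg.segment_id or c.circle_pos is None:
            continue
        if 1 <= c.circle_pos <= seg.circle_length:
            counts[c.circle_pos - 1] += 1
    return JunctionHistogram(segment_id=seg.segment_id, counts=counts)


def _extend_mode(counts: np.ndarray, lo: int, hi: int, min_support: int) -> tuple[int, int]:
    """Grow a region around the argmax in ``counts[lo:hi]`` (0-based, half-open).

    The argmax position is always retained; the region extends in both
    directions while positions hold at least ``min_support`` reads.
    """
    peak = lo + int(np.argmax(counts[lo:hi]))
    left = peak
    while left - 1 >= lo and counts[left - 1] >= min_support:
        left -= 1
    right = peak
    while right + 1 < hi and counts[right + 1] >= min_support:
        right += 1
    return left, right


def delineate_j_regions(
    hist: JunctionHistogram,
    him_interval: tuple[int, int],
    min_support: int = 2,
) -> JRegions:
    """Delineate the J1 and J2 regions from a junction histogram.

    Each region is the most-supported position inside the HIM plus the
    flanking positions until support drops below ``min_support``.  The
    two modes are searched on either side of the first one; if only one
    mode exists the result degrades softly to a single region.
    ``him_interval`` is in circle coordinates (1-based inclusive).
    """
    lo, hi = him_interval[0] - 1, him_interval[1]  # 0-based half-open
    counts = hist.counts
    if counts[lo:hi].sum() == 0:
        return JRegions(segment_id=hist.segment_id, j2=None, j1=None)
    r1 = _extend_mode(counts, lo, hi, min_support)

    masked = counts.copy()
    masked[r1[0] : r1[1] + 1] = 0
    regions = [r1]
    if masked[lo:hi].sum() > 0:
        r2 = _extend_mode(masked, lo, hi, min_support)
        regions.append(r2)
    regions.sort()
    to_iv = lambda r: (r[0] + 1, r[1] + 1)  # back to 1-based inclusive
    if len(regions) == 1:
        # single mode: cannot tell J1 from J2; report it on the J1 slot
        return JRegions(segment_id=hist.segment_id, j2=None, j1=to_iv(regions[0]))
    return JRegions(
        segment_id=hist.segment_id, j2=to_iv(regions[0]), j1=to_iv(regions[1])
    )


def intersect_j_regions(per_sample: Sequence[JRegions]) -> JRegions:
    """Intersect per-sample J regions for pooled reporting."""
    seg_ids = {r.segment_id for r in per_sample}
    if len(seg_ids) != 1:
        raise ValueError("J regions from different segments")

    def _isect(ivs: list[tuple[int, int] | None]) -> tuple[int, int] | None:
        if any(iv is None for iv in ivs):
            return None
        lo = max(iv[0] for iv in ivs)
        hi = min(iv[1] for iv in ivs)
        return (lo, hi) if lo <= hi else None

    return JRegions(
        segment_id=seg_ids.pop(),
        j2=_isect([r.j2 for r in per_sample]),
        j1=_isect([r.j1 for r in per_sample]),
    )


def classify_junctions(
    chimeras: Iterable[ChimericRead],
    segments: Sequence[SegmentAnnotation],
    j_regions: Mapping[str, JRegions],
) -> pd.DataFrame:
    """Assign each chimera exactly one junction category.

    Categories partition the chimera set: ``J1``/``J2`` for junctions
    inside the delineated regions, ``HIM_other`` for junctions inside a
    HIM but outside both regions, ``outside_HIM`` otherwise (including
    segments without a HIM and junctions outside annotated segments).
    Returns per-segment category counts; the class is also written onto
    each chimera.
    """
    seg_by_id = {s.segment_id: s for s in segments}
    rows: dict[str, dict[str, int]] = {}
    for c in chimeras:
        cls = "outside_HIM"
        seg = seg_by_id.get(c.segment_id) if c.segment_id else None
        if seg is not None and seg.has_him and c.circle_pos is not None:
            him = seg.him_circle
            if him[0] <= c.circle_pos <= him[1]:
                cls = "HIM_other"
                jr = j_regions.get(seg.segment_id)
                if jr is not None:
                    if jr.j1 and jr.j1[0] <= c.circle_pos <= jr.j1[1]:
                        cls = "J1"
                    elif jr.j2 and jr.j2[0] <= c.circle_pos <= jr.j2[1]:
                        cls = "J2"
        c.junction_class = cls
        key = c.segment_id or "unassigned"
        rows.setdefault(key, {"J1": 0, "J2": 0, "HIM_other": 0, "outside_HIM": 0})
        rows[key][cls] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    frame.index.name = "segment_id"
    return frame.sort_index()


@dataclass
class NullChimeraResult:
    """Outcome of the in-silico random-chimera null simulation."""

    distribution: MicrohomologyDistribution
    n_simulated: int
    n_classified: int
    # one-sided extension lengths at the true junction of every simulated
    # read: matches of the next circle bases vs the host continuation and
    # vice versa, measured directly on the source sequences
    ext_circle_side: np.ndarray
    ext_host_side: np.ndarray

    def one_sided_match_freq(self, min_len: int = 1) -> float:
        """Fraction of junctions whose host-side bases extend the circle
        match by at least ``min_len`` bases (1/4 per base for uniform
        composition)."""
        ext = np.concatenate([self.ext_circle_side, self.ext_host_side])
        return float((ext >= min_len).mean())


def _match_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def simulate_null_chimeras(
    circles: Mapping[str, str],
    host: Mapping[str, str],
    n_reads: int,
    read_length: int = 150,
    min_side: int = 28,
    seed: int | np.random.Generator = 0,
    thresholds: Thresholds = Thresholds(),
    mh_max: int = 13,
) -> NullChimeraResult:
    """Simulate random chimeric reads and measure their microhomology.

    Each artificial read concatenates a random circle substring and a
    random host substring, each at least ``min_side`` bp, summing to
    ``read_length``.  Each read is realigned to its sources -- exact
    maximal-extension alignment, which for error-free substrings equals
    what any local aligner reports -- and pushed through the production
    :func:`~bravointegrate.chimera.classify_chimera`, so the expected
    microhomology distribution is measured by the identical code path
    as the observed one.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    circle_ids = sorted(circles)
    host_ids = sorted(host)
    for name, seqs in (("circle", circles), ("host", host)):
        for sid, s in seqs.items():
            if len(s) < read_length:
                raise ValueError(f"{name} source {sid} shorter than read_length")

    clens = np.array([len(circles[c]) for c in circle_ids], dtype=float)
    hlens = np.array([len(host[h]) for h in host_ids], dtype=float)

    circ_choice = rng.choice(len(circle_ids), size=n_reads, p=clens / clens.sum())
    host_choice = rng.choice(len(host_ids), size=n_reads, p=hlens / hlens.sum())
    a_lens = rng.integers(min_side, read_length - min_side + 1, size=n_reads)

    mh_counts = np.zeros(mh_max + 1, dtype=int)
    ins_counts = np.zeros(thresholds.max_insert + 1, dtype=int)
    ext_c = np.zeros(n_reads, dtype=int)
    ext_h = np.zeros(n_reads, dtype=int)
    n_classified = 0
    for i in range(n_reads):
        cseq = circles[circle_ids[int(circ_choice[i])]]
        hseq = host[host_ids[int(host_choice[i])]]
        a = int(a_lens[i])
        b = read_length - a
        cs = int(rng.integers(0, len(cseq) - a + 1))
        hs = int(rng.integers(0, len(hseq) - b + 1))
        circle_part = cseq[cs : cs + a]
        host_part = hseq[hs : hs + b]

        # maximal exact extension across the junction, both directions
        right = _match_len(host_part, cseq[cs + a :])
        left = _match_len(circle_part[::-1], hseq[:hs][::-1])
        ext_c[i] = right
        ext_h[i] = left

        wasp_hit = AlignmentHit(
            read_id=f"null_{i}",
            genome="wasp",
            subject_id=circle_ids[int(circ_choice[i])],
            read_start=1,
            read_end=a + right,
            subject_start=cs + 1,
            subject_end=cs + a + right,
            strand="+",
            percent_identity=100.0,
            bitscore=float(2 * (a + right)),
        )
        host_hit = AlignmentHit(
            read_id=f"null_{i}",
            genome="host",
            subject_id=host_ids[int(host_choice[i])],
            read_start=a + 1 - left,
            read_end=read_length,
            subject_start=hs + 1 - left,
            subject_end=hs + b,
            strand="+",
            percent_identity=100.0,
            bitscore=float(2 * (b + left)),
        )
        result = classify_chimera(read_length, wasp_hit, host_hit, thresholds)
        if isinstance(result, ChimericRead):
            n_classified += 1
            if result.overlap_len <= mh_max:
                mh_counts[result.overlap_len] += 1
            ins_counts[result.insert_len] += 1
    dist = MicrohomologyDistribution(
        label="expected", mh_counts=mh_counts, insertion_counts=ins_counts
    )
    return NullChimeraResult(
        distribution=dist,
        n_simulated=n_reads,
        n_classified=n_classified,
        ext_circle_side=ext_c,
        ext_host_side=ext_h,
    )


def observed_mh_distribution(
    chimeras: Iterable[ChimericRead], mh_max: int = 13, max_insert: int = 5
) -> MicrohomologyDistribution:
    mh = np.zeros(mh_max + 1, dtype=int)
    ins = np.zeros(max_insert + 1, dtype=int)
    for c in chimeras:
        if c.overlap_len <= mh_max:
            mh[c.overlap_len] += 1
        if c.insert_len <= max_insert:
            ins[c.insert_len] += 1
    return MicrohomologyDistribution(label="observed", mh_counts=mh, insertion_counts=ins)


def compare_mh_distributions(
    observed: MicrohomologyDistribution,
    expected: MicrohomologyDistribution,
) -> tuple[pd.DataFrame, float, int, float]:
    """Per-length observed/expected ratios and a goodness-of-fit test.

    The expected counts are rescaled to the observed total; upper-tail
    length classes are pooled until every expected class count is at
    least 5, then a chi-square statistic is computed.  Returns
    ``(table, chi2, dof, p_value)``.
    """
    obs = observed.mh_counts.astype(float)
    exp = expected.mh_counts.astype(float)
    if exp.sum() <= 0:
        raise ValueError("expected distribution is empty")
    exp_scaled = exp * obs.sum() / exp.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_scaled > 0, obs / exp_scaled, np.nan)
    table = pd.DataFrame(
        {
            "mh_length": np.arange(len(obs)),
            "observed": obs.astype(int),
            "expected": exp_scaled,
            "ratio": ratio,
        }
    )

    # pool the upper tail until every class expects >= 5
    obs_pool: list[float] = []
    exp_pool: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs[::-1], exp_scaled[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_pool.append(acc_o)
            exp_pool.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_pool:
        obs_pool[-1] += acc_o
        exp_pool[-1] += acc_e
    if not exp_pool:
        raise ValueError("no class with expected count >= 5 after pooling")
    obs_arr = np.array(obs_pool[::-1])
    exp_arr = np.array(exp_pool[::-1])
    exp_arr = exp_arr * obs_arr.sum() / exp_arr.sum()  # guard rounding drift
    dof = max(len(obs_arr) - 1, 1)
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    p = float(stats.chi2.sf(chi2, dof))
    return table, chi2, dof, p
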