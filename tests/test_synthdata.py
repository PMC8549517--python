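"""Generator structure: segments, circles, integrations, reads, truth."""

import numpy as np
import pytest

from bravointegrate.io import revcomp
from bravointegrate.synthdata import (
    AnnotationError,
    SimConfig,
    SizingError,
    excise_circle,
    gen_genomes,
    insert_sequence,
    integrate_circle,
    simulate_dataset,
    simulate_reads,
)


def _cfg(**kwargs) -> SimConfig:
    base = dict(
        host_length=40_000,
        wasp_length=25_000,
        n_segments=3,
        n_integrations_total=4,
        depth_host=5,
        depth_wasp=5,
        error_rate=0.0,
        pcr_dup_rate=0.0,
        seed=1,
    )
    base.update(kwargs)
    return SimConfig(**base)


class TestGenGenomes:
    def test_all_him_segments_planted(self):
        cfg = _cfg(wasp_length=40_000, n_segments=16, him_fraction=1.0)
        host, wasp, segments = gen_genomes(cfg)
        assert len(segments) == 16
        assert all(s.has_him for s in segments)
        assert len(wasp) == cfg.wasp_length
        assert len(host) == cfg.host_length
        # non-overlapping, ordered
        for a, b in zip(segments, segments[1:]):
            assert a.end < b.start

    def test_drj_copies_identical_and_flanking(self):
        _, wasp, segments = gen_genomes(_cfg())
        for seg in segments:
            d5 = wasp[seg.drj5[0] - 1 : seg.drj5[1]]
            d3 = wasp[seg.drj3[0] - 1 : seg.drj3[1]]
            assert d5 == d3
            assert seg.drj5[0] == seg.start and seg.drj3[1] == seg.end

    def test_him_structure_j2_before_j1(self):
        cfg = _cfg()
        _, _, segments = gen_genomes(cfg)
        for seg in segments:
            assert seg.j2[1] < seg.j1[0]
            assert seg.him[0] == seg.j2[0] and seg.him[1] == seg.j1[1]
            assert 41 <= seg.spacer_length <= 73

    def test_him_fraction(self):
        cfg = _cfg(n_segments=4, him_fraction=0.5)
        _, _, segments = gen_genomes(cfg)
        assert sum(s.has_him for s in segments) == 2
        for seg in segments:
            if not seg.has_him:
                assert seg.j1 is None and seg.j2 is None

    def test_no_segments_empty_annotation(self):
        host, wasp, segments = gen_genomes(_cfg(n_segments=0, n_integrations_total=0))
        assert segments == []
        assert len(wasp) == 25_000

    def test_deterministic_for_fixed_seed(self):
        a = gen_genomes(_cfg())
        b = gen_genomes(_cfg())
        assert a[0] == b[0] and a[1] == b[1]
        assert [vars(s) for s in a[2]] == [vars(s) for s in b[2]]

    def test_sizing_error_when_segments_do_not_fit(self):
        with pytest.raises(SizingError):
            gen_genomes(_cfg(wasp_length=3_000, n_segments=5))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            _cfg(him_fraction=1.5).validate()
        with pytest.raises(ValueError):
            _cfg(spacer_length=30).validate()
        with pytest.raises(ValueError):
            _cfg(read_length=20).validate()


class TestExcision:
    def test_circle_length_drops_one_drj(self):
        _, wasp, segments = gen_genomes(_cfg())
        for seg in segments:
            circle = excise_circle(wasp, seg)
            assert len(circle) == seg.length - seg.drj_length
            assert len(circle) == seg.circle_length

    def test_circle_contains_exactly_one_drj_copy(self):
        _, wasp, segments = gen_genomes(_cfg())
        seg = segments[0]
        circle = excise_circle(wasp, seg)
        drj = wasp[seg.drj5[0] - 1 : seg.drj5[1]]
        assert circle.count(drj) == 1

    def test_missing_drj3_is_an_error(self):
        _, wasp, segments = gen_genomes(_cfg())
        seg = segments[0]
        seg.drj3 = None
        with pytest.raises(AnnotationError):
            excise_circle(wasp, seg)

    def test_mismatching_drjs_is_an_error(self):
        _, wasp, segments = gen_genomes(_cfg())
        seg = segments[0]
        pos = seg.drj3[0] - 1
        mutated = wasp[:pos] + ("A" if wasp[pos] != "A" else "C") + wasp[pos + 1 :]
        with pytest.raises(AnnotationError):
            excise_circle(mutated, seg)


class TestIntegration:
    def test_insert_length_is_circle_minus_spacer(self):
        _, wasp, segments = gen_genomes(_cfg())
        for seg in segments:
            circle = excise_circle(wasp, seg)
            ins = insert_sequence(circle, seg)
            assert len(ins) == seg.circle_length - seg.spacer_length

    def test_insert_extremities_are_j1_and_j2(self):
        _, wasp, segments = gen_genomes(_cfg())
        seg = segments[0]
        circle = excise_circle(wasp, seg)
        ins = insert_sequence(circle, seg)
        j1 = wasp[seg.j1[0] - 1 : seg.j1[1]]
        j2 = wasp[seg.j2[0] - 1 : seg.j2[1]]
        assert ins.startswith(j1)
        assert ins.endswith(j2)

    @pytest.mark.parametrize("orientation", ["+", "-"])
    @pytest.mark.parametrize("mh_len", [0, 2, 5])
    def test_engineered_microhomology_exact(self, orientation, mh_len):
        host, wasp, segments = gen_genomes(_cfg())
        seg = segments[0]
        circle = excise_circle(wasp, seg)
        modified, truth = integrate_circle(
            host, circle, seg, position=10_000, orientation=orientation,
            mh_len=mh_len, seed=3,
        )
        ins = insert_sequence(circle, seg)
        if orientation == "-":
            ins = revcomp(ins)
        assert truth.inserted_length == len(ins)
        assert len(modified) == len(host) + len(ins)
        p = truth.host_position  # 1-based last base before the insert
        # reference host = modified with the insert removed
        ref = modified[:p] + modified[p + len(ins):]
        # shared bases between insert extremities and flanking host
        k_right = 0
        while ins[k_right] == ref[p + k_right]:
            k_right += 1
        k_left = 0
        while ins[-1 - k_left] == ref[p - 1 - k_left]:
            k_left += 1
        assert k_right == mh_len
        assert k_left == mh_len

    def test_segment_without_him_unsupported(self):
        cfg = _cfg(n_segments=2, him_fraction=0.0, n_integrations_total=0)
        host, wasp, segments = gen_genomes(cfg)
        circle = excise_circle(wasp, segments[0])
        with pytest.raises(AnnotationError):
            integrate_circle(host, circle, segments[0], position=5_000)


class TestSimulateReads:
    def test_read_count_tracks_depth(self):
        cfg = _cfg(read_length=150)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        reads, truth = simulate_reads([("src", seq, 10.0)], cfg, rng)
        realized = len(reads) * cfg.read_length / len(seq)
        assert abs(realized - 10.0) / 10.0 < 0.05

    def test_no_duplicates_means_unique_ids(self):
        cfg = _cfg(pcr_dup_rate=0.0)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        reads, _ = simulate_reads([("src", seq, 5.0)], cfg, rng)
        ids = [r[0] for r in reads]
        assert len(ids) == len(set(ids))

    def test_error_free_reads_are_exact_substrings(self):
        cfg = _cfg(error_rate=0.0)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        reads, truth = simulate_reads([("src", seq, 2.0)], cfg, rng)
        by_id = dict(reads)
        for row in truth.itertuples():
            frag = seq[row.start - 1 : row.end]
            if row.strand == "-":
                frag = revcomp(frag)
            assert by_id[row.read_id] == frag

    def test_duplicates_copy_sequence_exactly(self):
        cfg = _cfg(pcr_dup_rate=0.2, error_rate=0.01)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        reads, truth = simulate_reads([("src", seq, 3.0)], cfg, rng)
        by_id = dict(reads)
        dups = truth[truth.duplicate_of != ""]
        assert len(dups) > 0
        for row in dups.itertuples():
            assert by_id[row.read_id] == by_id[row.duplicate_of]

    def test_read_longer_than_source_is_an_error(self):
        cfg = _cfg()
        with pytest.raises(ValueError):
            simulate_reads([("src", "ACGT" * 10, 5.0)], cfg, np.random.default_rng(0))


class TestDataset:
    def test_truth_events_obey_length_identity(self, small_dataset):
        segs = {s.segment_id: s for s in small_dataset.segments}
        for t in small_dataset.truth_events:
            seg = segs[t.segment_id]
            assert t.inserted_length + seg.spacer_length == seg.circle_length

    def test_integrated_host_length(self, small_dataset):
        extra = sum(t.inserted_length for t in small_dataset.truth_events)
        host = next(iter(small_dataset.host_ref.values()))
        integrated = next(iter(small_dataset.integrated_host.values()))
        assert len(integrated) == len(host) + extra

    def test_same_seed_byte_identical(self, small_config, small_dataset):
        again = simulate_dataset(small_config)
        assert again.host_ref == small_dataset.host_ref
        assert again.wasp == small_dataset.wasp
        assert again.reads == small_dataset.reads
        assert [vars(t) for t in again.truth_events] == [
            vars(t) for t in small_dataset.truth_events
        ]

    def test_per_segment_override(self):
        cfg = _cfg(
            host_length=60_000,
            n_integrations_total=None,
            n_integrations_by_segment={"S1": 3, "S2": 1},
        )
        ds = simulate_dataset(cfg)
        by_seg = {}
        for t in ds.truth_events:
            by_seg[t.segment_id] = by_seg.get(t.segment_id, 0) + 1
        assert by_seg == {"S1": 3, "S2": 1}
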