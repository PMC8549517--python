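"""Chimera filters, junction geometry, table parsing and PCR dedup."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bravointegrate.chimera import (
    AlignmentHit,
    ChimericRead,
    Rejection,
    TabularFormatError,
    Thresholds,
    classify_chimera,
    dedupe_pcr,
    find_chimeras,
    parse_alignment_table,
    select_best_hit,
)

READ_LEN = 150


def _hit(genome, rs, re_, ss=None, se=None, read_id="r1", subject="c1",
         strand="+", bitscore=100.0, pident=100.0):
    if ss is None:
        ss, se = 1000 + rs, 1000 + re_
    return AlignmentHit(
        read_id=read_id, genome=genome, subject_id=subject,
        read_start=rs, read_end=re_, subject_start=ss, subject_end=se,
        strand=strand, percent_identity=pident, bitscore=bitscore,
    )


class TestParseTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "aln.tsv"
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return str(path)

    def test_well_formed_rows_parsed(self, tmp_path):
        rows = [
            ["r1", "c1", 100.0, 80, 0, 0, 1, 80, 501, 580, 1e-30, 160],
            ["r2", "c1", 98.0, 70, 1, 0, 10, 79, 700, 769, 1e-25, 130],
            ["r3", "c2", 100.0, 50, 0, 0, 1, 50, 88, 137, 1e-20, 100],
        ]
        hits = parse_alignment_table(self._write(tmp_path, rows), genome="wasp")
        assert len(hits) == 3
        assert all(h.genome == "wasp" for h in hits)

    def test_empty_file_empty_list(self, tmp_path):
        assert parse_alignment_table(self._write(tmp_path, []), genome="host") == []

    def test_minus_strand_subject_normalized(self, tmp_path):
        rows = [["r1", "c1", 100.0, 80, 0, 0, 1, 80, 580, 501, 1e-30, 160]]
        (hit,) = parse_alignment_table(self._write(tmp_path, rows), genome="wasp")
        assert hit.strand == "-"
        assert hit.subject_start == 501 and hit.subject_end == 580
        assert hit.read_start == 1 and hit.read_end == 80

    def test_minus_strand_query_dialect_normalized(self, tmp_path):
        rows = [["r1", "c1", 100.0, 80, 0, 0, 80, 1, 501, 580, 1e-30, 160]]
        (hit,) = parse_alignment_table(self._write(tmp_path, rows), genome="wasp")
        assert hit.read_start == 1 and hit.read_end == 80
        assert hit.strand == "-"

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("r1\tc1\tnot_a_number\n")
        with pytest.raises(TabularFormatError, match="line"):
            parse_alignment_table(str(path), genome="wasp")


class TestBestHit:
    def test_highest_bitscore_wins(self):
        hits = [_hit("wasp", 1, 80, bitscore=100), _hit("wasp", 1, 70, bitscore=90)]
        assert select_best_hit(hits) is hits[0]

    def test_full_tie_breaks_on_subject_start(self):
        a = _hit("wasp", 1, 80, ss=900, se=979)
        b = _hit("wasp", 1, 80, ss=500, se=579)
        assert select_best_hit([a, b]) is b

    def test_no_hits_returns_none(self):
        assert select_best_hit([]) is None

    def test_mixed_reads_rejected(self):
        with pytest.raises(ValueError):
            select_best_hit([_hit("wasp", 1, 80), _hit("wasp", 1, 80, read_id="r2")])


class TestFilters:
    """The four acceptance filters on read-coordinate interval geometry."""

    def test_overlap_counted_as_microhomology(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 80), _hit("host", 76, 150))
        assert isinstance(res, ChimericRead)
        assert res.overlap_len == 5
        assert res.insert_len == 0

    def test_short_wasp_side_fails_filter_i(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 15), _hit("host", 16, 150))
        assert isinstance(res, Rejection) and res.filter_id == "i"

    def test_21bp_overlap_fails_filter_iii(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 70), _hit("host", 50, 150))
        assert isinstance(res, Rejection) and res.filter_id == "iii"

    def test_boundary_overlap_20_accepted(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 70), _hit("host", 51, 150))
        assert isinstance(res, ChimericRead) and res.overlap_len == 20

    def test_6_inserted_bases_fail_filter_iv(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 70), _hit("host", 77, 150))
        assert isinstance(res, Rejection) and res.filter_id == "iv"

    def test_boundary_insert_5_accepted(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 70), _hit("host", 76, 150))
        assert isinstance(res, ChimericRead) and res.insert_len == 5

    def test_16_unaligned_bases_fail_filter_ii_strictly(self):
        # 10% of 150 = 15; filter is strict, so 15 unaligned already fails
        res = classify_chimera(READ_LEN, _hit("wasp", 1, 64), _hit("host", 81, 150))
        assert isinstance(res, Rejection) and res.filter_id == "ii"

    def test_14_unaligned_bases_pass_filter_ii(self):
        res = classify_chimera(READ_LEN, _hit("wasp", 8, 72), _hit("host", 73, 143))
        assert isinstance(res, ChimericRead) and res.unaligned_len == 14

    def test_hits_from_different_reads_are_a_usage_error(self):
        with pytest.raises(ValueError):
            classify_chimera(
                READ_LEN, _hit("wasp", 1, 80), _hit("host", 76, 150, read_id="other")
            )

    @given(
        ws=st.integers(1, 140), wlen=st.integers(1, 149),
        hs=st.integers(1, 140), hlen=st.integers(1, 149),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_partition_identity(self, ws, wlen, hs, hlen):
        """wasp-only + host-only + overlap + unaligned + inserted = read length."""
        we, he = min(ws + wlen, READ_LEN), min(hs + hlen, READ_LEN)
        res = classify_chimera(READ_LEN, _hit("wasp", ws, we), _hit("host", hs, he))
        if isinstance(res, ChimericRead):
            wasp_only = (we - ws + 1) - res.overlap_len
            host_only = (he - hs + 1) - res.overlap_len
            assert (
                wasp_only + host_only + res.overlap_len
                + res.unaligned_len + res.insert_len
            ) == READ_LEN


class TestJunctionConvention:
    def test_junction_is_wasp_alignment_end_regardless_of_overlap(self):
        res = classify_chimera(
            READ_LEN,
            _hit("wasp", 1, 80, ss=2001, se=2080),
            _hit("host", 76, 150, ss=9076, se=9150),
        )
        assert res.wasp_side == "left"
        assert res.junction_on_wasp == 2080  # end coordinate, overlap included
        assert res.junction_on_host == 9076
        assert res.host_breakpoint == 9075

    def test_breakpoint_agrees_between_left_and_right_junction_reads(self):
        # two reads of one mh=0 integration: host part left, then host part right
        left = classify_chimera(
            READ_LEN,
            _hit("wasp", 61, 150, ss=3001, se=3090),
            _hit("host", 1, 60, ss=4941, se=5000),
        )
        right = classify_chimera(
            READ_LEN,
            _hit("wasp", 1, 90, ss=3401, se=3490),
            _hit("host", 91, 150, ss=5001, se=5060),
        )
        assert left.wasp_side == "right" and right.wasp_side == "left"
        assert left.host_breakpoint == right.host_breakpoint == 5000

    def test_orientation_from_strand_combination(self):
        same = classify_chimera(
            READ_LEN, _hit("wasp", 1, 80, strand="-"), _hit("host", 81, 150, strand="-")
        )
        opposite = classify_chimera(
            READ_LEN, _hit("wasp", 1, 80, strand="-"), _hit("host", 81, 150, strand="+")
        )
        assert same.orientation == "+"
        assert opposite.orientation == "-"


class TestAmbiguityAndDedup:
    def test_multimapping_read_rejected_as_ambiguous(self):
        wasp = [
            _hit("wasp", 1, 40, ss=1000, se=1039, bitscore=80),
            _hit("wasp", 1, 40, ss=7000, se=7039, bitscore=80),
        ]
        host = [_hit("host", 41, 150, ss=5000, se=5109, bitscore=220)]
        accepted, rejected = find_chimeras(wasp, host, READ_LEN)
        assert accepted == []
        assert rejected[0].filter_id == "amb"

    def test_clearly_best_hit_not_ambiguous(self):
        wasp = [
            _hit("wasp", 1, 60, ss=1000, se=1059, bitscore=120),
            _hit("wasp", 1, 40, ss=7000, se=7039, bitscore=80),
        ]
        host = [_hit("host", 61, 150, ss=5000, se=5089, bitscore=180)]
        accepted, _ = find_chimeras(wasp, host, READ_LEN)
        assert len(accepted) == 1

    def _chim(self, **kwargs):
        base = dict(
            read_id="r1", wasp_interval=(1, 80), host_interval=(81, 150),
            wasp_subject="w1", host_subject="h1", junction_on_wasp=500,
            junction_on_host=900, orientation="+", overlap_len=0, insert_len=0,
            unaligned_len=0, wasp_side="left",
            wasp_subject_interval=(421, 500), host_subject_interval=(900, 969),
        )
        base.update(kwargs)
        return ChimericRead(**base)

    def test_identical_fragments_collapse(self):
        a = self._chim()
        b = self._chim(read_id="r1_dup0")
        unique, removed = dedupe_pcr([a, b])
        assert len(unique) == 1 and removed == 1

    def test_same_junction_different_boundaries_both_kept(self):
        a = self._chim()
        b = self._chim(read_id="r2", wasp_subject_interval=(431, 500),
                       host_subject_interval=(900, 959))
        unique, removed = dedupe_pcr([a, b])
        assert len(unique) == 2 and removed == 0

    def test_dedupe_idempotent_and_empty_safe(self):
        chims = [self._chim(), self._chim(read_id="x"), self._chim(read_id="r2",
                 wasp_subject_interval=(431, 500))]
        once, _ = dedupe_pcr(chims)
        twice, removed = dedupe_pcr(once)
        assert [c.read_id for c in twice] == [c.read_id for c in once]
        assert removed == 0
        assert dedupe_pcr([]) == ([], 0)
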