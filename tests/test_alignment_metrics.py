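import gzip
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplopurge.alignment_metrics import (
    AlignmentParseError,
    RawAlignment,
    compute_metrics,
    filter_eligible,
    parse_paf,
    parse_psl,
    qr_prime_of,
    write_psl,
)

PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\n"
    "     \tmatch\tmatch\t   \n"
    + "-" * 80 + "\n"
)


def _psl_row(matches=950, mismatches=50, rep=0, qname="ctgB", qsize=1000,
             qstart=0, qend=1000, tname="ctgA", tsize=1200, tstart=0,
             tend=1000):
    qspan = qend - qstart
    return "\t".join(str(x) for x in (
        matches, mismatches, rep, 0, 0, 0, 0, 0, "+",
        qname, qsize, qstart, qend, tname, tsize, tstart, tend,
        1, f"{qspan},", f"{qstart},", f"{tstart},")) + "\n"


class TestParsePsl:
    def test_single_row(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text(PSL_HEADER + _psl_row())
        (rec,) = parse_psl(p)
        assert rec.matches == 950
        assert rec.mismatches == 50
        assert rec.query_length == 1000
        assert rec.target_length == 1200
        assert (rec.query_start, rec.query_end) == (0, 1000)

    def test_header_only_gives_empty(self, tmp_path):
        p = tmp_path / "empty.psl"
        p.write_text(PSL_HEADER)
        assert parse_psl(p) == []

    def test_gzip_round_trip(self, tmp_path):
        plain = tmp_path / "a.psl"
        plain.write_text(PSL_HEADER + _psl_row())
        gz = tmp_path / "a.psl.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(PSL_HEADER + _psl_row())
        assert parse_psl(gz) == parse_psl(plain)
        assert parse_psl(gz, gzipped=True) == parse_psl(plain)

    def test_bad_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text(PSL_HEADER + "1\t2\t3\n")
        with pytest.raises(AlignmentParseError, match="line 6"):
            parse_psl(p)

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "neg.psl"
        p.write_text(_psl_row(qstart=-5))
        with pytest.raises(AlignmentParseError):
            parse_psl(p)


class TestParsePaf:
    PAF_ROW = "ctgB\t1000\t0\t1000\t+\tctgA\t1200\t0\t1000\t950\t1000\t60\n"

    def test_single_row(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(self.PAF_ROW)
        (rec,) = parse_paf(p)
        assert rec.query_length == 1000
        assert rec.matches == 950
        assert rec.block_length == 1000
        assert rec.mismatches == 50  # block - matches
        assert rec.target_length == 1200
        assert rec.rep_matches == 0

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.paf"
        p.write_text("")
        assert parse_paf(p) == []

    def test_trailing_tags_ignored(self, tmp_path):
        p = tmp_path / "t.paf"
        p.write_text(self.PAF_ROW.rstrip("\n") + "\ttp:A:P\tcg:Z:1000M\n")
        (rec,) = parse_paf(p)
        assert rec.matches == 950

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "s.paf"
        p.write_text("ctgB\t1000\t0\t1000\n")
        with pytest.raises(AlignmentParseError, match="12"):
            parse_paf(p)

    def test_non_integer_field_rejected(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("ctgB\tten\t0\t1000\t+\tctgA\t1200\t0\t1000\t950\t1000\t60\n")
        with pytest.raises(AlignmentParseError):
            parse_paf(p)


class TestComputeMetrics:
    def test_worked_example(self):
        raw = RawAlignment("ctgB", 1000, 0, 1000, "ctgA", 1200, 0, 1000,
                           matches=950, mismatches=50, block_length=1000)
        table = compute_metrics([raw])
        (rec,) = table.records
        assert rec.identity == pytest.approx(0.95)
        assert rec.q == pytest.approx(1.0)
        assert rec.r == pytest.approx(1000 / 1200)
        assert rec.qr == pytest.approx(1.2)
        assert rec.qr_prime == pytest.approx(math.exp(-math.log2(1.2)))

    def test_qr_prime_fixed_points(self):
        assert qr_prime_of(1.0) == pytest.approx(1.0, abs=1e-12)
        assert qr_prime_of(2.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_self_alignments_dropped(self):
        raw = RawAlignment("ctgA", 1000, 0, 1000, "ctgA", 1000, 0, 1000,
                           matches=1000, mismatches=0)
        assert len(compute_metrics([raw])) == 0

    def test_degenerate_target_span_rejected(self, caplog):
        raw = RawAlignment("ctgB", 1000, 0, 100, "ctgA", 1200, 50, 50,
                           matches=90, mismatches=10)
        with caplog.at_level("WARNING"):
            table = compute_metrics([raw])
        assert len(table) == 0
        assert "degenerate" in caplog.text

    def test_rep_matches_in_identity_denominator(self):
        raw = RawAlignment("ctgB", 1000, 0, 1000, "ctgA", 1200, 0, 1000,
                           matches=900, mismatches=50, rep_matches=50)
        (rec,) = compute_metrics([raw]).records
        assert rec.identity == pytest.approx(900 / 1000)
        (rec,) = compute_metrics([raw], count_rep_matches=False).records
        assert rec.identity == pytest.approx(900 / 950)

    def test_best_row_per_pair_keeps_highest_identity(self):
        rows = [
            RawAlignment("b", 1000, 0, 1000, "a", 1200, 0, 1000,
                         matches=900, mismatches=100),
            RawAlignment("b", 1000, 0, 1000, "a", 1200, 0, 1000,
                         matches=990, mismatches=10),
        ]
        table = compute_metrics(rows, best_row_per_pair=True)
        assert len(table) == 1
        assert table.records[0].identity == pytest.approx(0.99)


class TestFilterEligible:
    @staticmethod
    def _table(*raws):
        return compute_metrics(raws)

    def test_long_query_removed(self):
        raw = RawAlignment("big", 12_000_000, 0, 1_000_000, "a", 20_000_000,
                           0, 1_000_000, matches=900_000, mismatches=100_000)
        table = self._table(raw)
        assert len(filter_eligible(table)) == 0

    def test_reciprocal_pair_keeps_shorter_query(self):
        ab = RawAlignment("A", 2000, 0, 1000, "B", 1000, 0, 1000,
                          matches=950, mismatches=50)
        ba = RawAlignment("B", 1000, 0, 1000, "A", 2000, 0, 1000,
                          matches=950, mismatches=50)
        table = self._table(ab, ba)
        kept = filter_eligible(table)
        assert [r.raw.query_name for r in kept.records] == ["B"]

    def test_equal_lengths_keep_later_sorting_query(self):
        ab = RawAlignment("A", 1000, 0, 900, "B", 1000, 0, 900,
                          matches=850, mismatches=50)
        ba = RawAlignment("B", 1000, 0, 900, "A", 1000, 0, 900,
                          matches=850, mismatches=50)
        kept = filter_eligible(self._table(ab, ba))
        assert [r.raw.query_name for r in kept.records] == ["B"]

    def test_empty_table(self):
        table = self._table()
        assert len(filter_eligible(table)) == 0


@st.composite
def raw_alignments(draw):
    qlen = draw(st.integers(min_value=2, max_value=10_000))
    tlen = draw(st.integers(min_value=2, max_value=10_000))
    qs = draw(st.integers(min_value=0, max_value=qlen - 1))
    qe = draw(st.integers(min_value=qs + 1, max_value=qlen))
    ts = draw(st.integers(min_value=0, max_value=tlen - 1))
    te = draw(st.integers(min_value=ts + 1, max_value=tlen))
    span = qe - qs
    matches = draw(st.integers(min_value=1, max_value=span))
    return RawAlignment(
        query_name="q", query_length=qlen, query_start=qs, query_end=qe,
        target_name="t", target_length=tlen, target_start=ts, target_end=te,
        matches=matches, mismatches=span - matches,
        block_length=span,
    )


class TestMetricInvariants:
    @settings(max_examples=200, derandomize=True)
    @given(raw=raw_alignments())
    def test_qr_consistency(self, raw):
        (rec,) = compute_metrics([raw]).records
        assert rec.qr * (rec.r / rec.q) == pytest.approx(1.0, abs=1e-12)
        assert rec.qr_prime * qr_prime_of(1.0 / rec.qr) == pytest.approx(
            1.0, abs=1e-9)
        assert (rec.qr > 1) == (rec.qr_prime < 1) or rec.qr == 1

    @settings(max_examples=100, derandomize=True)
    @given(raws=st.lists(raw_alignments(), max_size=10))
    def test_psl_serialize_parse_round_trip(self, raws, tmp_path_factory):
        path = tmp_path_factory.mktemp("psl") / "round.psl"
        write_psl(raws, path)
        assert parse_psl(path) == raws
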