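"""PSI evidence assignment, delta-PSI testing, retention and set algebra."""

import math

import pandas as pd
import pytest

from cardiosplice.annotation import flatten_all
from cardiosplice.psi import (
    JunctionRecord,
    compute_psi,
    delta_psi_test,
    junctions_to_frame,
    read_junctions,
    retention_index,
    spliced_set_overlap,
)
from cardiosplice.simulate import cassette_gene, retention_gene


@pytest.fixture
def cassette_parts():
    return flatten_all(cassette_gene("G"))  # parts at [0,100) [300,400) [600,700)


def _junctions(rows):
    return junctions_to_frame(
        [JunctionRecord("chr1", s, e, "+", sample, c) for s, e, sample, c in rows]
    )


def _coverage(parts, values):
    samples = sorted({s for v in values.values() for s in v})
    frame = pd.DataFrame(0.0, index=[p.part_id for p in parts], columns=samples)
    for part_id, per_sample in values.items():
        for sample, v in per_sample.items():
            frame.at[part_id, sample] = v
    return frame


class TestReadJunctions:
    def test_bed6_convention(self, tmp_path):
        path = tmp_path / "j.bed"
        path.write_text("chr2\t100\t200\tJ1\t15\t+\n")
        (rec,) = read_junctions(str(path), "bed6-intron", sample_id="s1")
        assert (rec.contig, rec.start, rec.end, rec.count) == ("chr2", 100, 200, 15)

    def test_sj_tab_one_based_conversion(self, tmp_path):
        path = tmp_path / "sj.tab"
        path.write_text("chr2\t101\t200\t1\t0\t0\t15\t0\t0\n")
        (rec,) = read_junctions(str(path), "sj-tab")
        assert (rec.start, rec.end, rec.strand) == (100, 200, "+")

    def test_sj_strand_codes(self, tmp_path):
        path = tmp_path / "sj.tab"
        path.write_text(
            "c\t11\t20\t0\t0\t0\t1\t0\t0\nc\t11\t20\t1\t0\t0\t1\t0\t0\nc\t11\t20\t2\t0\t0\t1\t0\t0\n"
        )
        strands = [r.strand for r in read_junctions(str(path), "sj-tab")]
        assert strands == [".", "+", "-"]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.bed"
        path.write_text("")
        assert read_junctions(str(path), "bed6-intron") == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tJ\t5\t+\nchr1\tnope\t300\tJ\t5\t+\n")
        with pytest.raises(ValueError, match=":2"):
            read_junctions(str(path), "bed6-intron")

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tJ\t-5\t+\n")
        with pytest.raises(ValueError):
            read_junctions(str(path), "bed6-intron")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_junctions("x", "csv")


class TestComputePsi:
    def test_raw_ratio(self, cassette_parts):
        # middle part: 30 coverage reads, 10 skip-junction reads
        cov = _coverage(cassette_parts, {"G:002": {"s1": 30}})
        jx = _junctions([(100, 600, "s1", 10)])
        records = {r.part_id: r for r in compute_psi(cassette_parts, jx, cov, mode="raw")}
        assert records["G:002"].psi == pytest.approx(0.75)

    def test_no_exclusion_gives_psi_one(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"s1": 5}})
        jx = _junctions([])
        records = {r.part_id: r for r in compute_psi(cassette_parts, jx, cov, mode="raw")}
        assert records["G:002"].psi == pytest.approx(1.0)

    def test_no_evidence_is_undefined(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"s1": 0}})
        records = {r.part_id: r for r in compute_psi(cassette_parts, _junctions([]), cov, mode="raw")}
        assert math.isnan(records["G:002"].psi)

    def test_length_normalized_example(self, cassette_parts):
        # part length 100, read length 50: inclusion 149 -> 1.0, exclusion 49 -> 1.0
        cov = _coverage(cassette_parts, {"G:002": {"s1": 149}})
        jx = _junctions([(100, 600, "s1", 49)])
        records = {
            r.part_id: r
            for r in compute_psi(
                cassette_parts, jx, cov, read_length=50, mode="length-normalized"
            )
        }
        rec = records["G:002"]
        assert rec.inclusion_norm == pytest.approx(1.0)
        assert rec.exclusion_norm == pytest.approx(1.0)
        assert rec.psi == pytest.approx(0.5)

    def test_abutting_junction_counts_as_inclusion(self, cassette_parts):
        # junction ending at the part start supports inclusion
        cov = _coverage(cassette_parts, {"G:002": {"s1": 0}})
        jx = _junctions([(100, 300, "s1", 12)])
        records = {r.part_id: r for r in compute_psi(cassette_parts, jx, cov, mode="raw")}
        assert records["G:002"].inclusion_raw == 12
        assert records["G:002"].psi == pytest.approx(1.0)

    def test_retained_intron_junction_is_exclusion(self):
        # the spliced junction of a retained intron coincides with the part
        parts = flatten_all(retention_gene("R"))  # retained part [100, 300)
        cov = _coverage(parts, {"R:002": {"s1": 10}})
        jx = _junctions([(100, 300, "s1", 30)])
        records = {r.part_id: r for r in compute_psi(parts, jx, cov, mode="raw")}
        assert records["R:002"].exclusion_raw == 30
        assert records["R:002"].psi == pytest.approx(0.25)

    def test_exclusion_monotonicity(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"s1": 20}})
        psis = []
        for exc in (0, 5, 50, 500):
            jx = _junctions([(100, 600, "s1", exc)])
            records = {r.part_id: r for r in compute_psi(cassette_parts, jx, cov, mode="raw")}
            psis.append(records["G:002"].psi)
        assert psis == sorted(psis, reverse=True)
        assert all(0.0 <= p <= 1.0 for p in psis)

    def test_strand_flip_leaves_psi_unchanged(self):
        plus = flatten_all(cassette_gene("G", strand="+"))
        minus = flatten_all(cassette_gene("G", strand="-"))
        cov_p = _coverage(plus, {"G:002": {"s1": 30}})
        cov_m = _coverage(minus, {"G:002": {"s1": 30}})
        jx_p = _junctions([(100, 600, "s1", 10)])
        jx_m = junctions_to_frame([JunctionRecord("chr1", 100, 600, "-", "s1", 10)])
        rec_p = {r.part_id: r.psi for r in compute_psi(plus, jx_p, cov_p, mode="raw")}
        rec_m = {r.part_id: r.psi for r in compute_psi(minus, jx_m, cov_m, mode="raw")}
        assert rec_p == rec_m

    def test_unknown_contig_junctions_skipped(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"s1": 30}})
        jx = _junctions([(100, 600, "s1", 10)])
        jx["contig"] = "chrUn"
        records = {r.part_id: r for r in compute_psi(cassette_parts, jx, cov, mode="raw")}
        assert records["G:002"].psi == pytest.approx(1.0)

    def test_normalized_mode_needs_read_length(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"s1": 1}})
        with pytest.raises(ValueError, match="read_length"):
            compute_psi(cassette_parts, _junctions([]), cov, read_length=1)


class TestDeltaPsi:
    def _psi_records(self, parts, case_vals, ctrl_vals):
        cov = {}
        samples = {}
        for i, v in enumerate(case_vals):
            samples[f"c{i}"] = v
        for i, v in enumerate(ctrl_vals):
            samples[f"k{i}"] = v
        cov = _coverage(parts, {"G:002": {s: round(1000 * v) for s, v in samples.items()}})
        jx = _junctions(
            [(100, 600, s, round(1000 * (1 - v))) for s, v in samples.items()]
        )
        return compute_psi(parts, jx, cov, mode="raw")

    def test_identical_groups_give_p_one(self, cassette_parts):
        recs = self._psi_records(cassette_parts, [0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        results, _ = delta_psi_test(recs, ["c0", "c1", "c2"], ["k0", "k1", "k2"])
        rec = next(r for r in results if r.part_id == "G:002")
        assert rec.delta_psi == pytest.approx(0.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_delta_is_case_minus_ctrl(self, cassette_parts):
        recs = self._psi_records(cassette_parts, [0.8, 0.82], [0.5, 0.52])
        results, _ = delta_psi_test(recs, ["c0", "c1"], ["k0", "k1"])
        rec = next(r for r in results if r.part_id == "G:002")
        assert rec.delta_psi == pytest.approx(0.3, abs=0.01)
        assert abs(rec.delta_psi) <= 1.0

    def test_insufficient_defined_values_skipped_with_reason(self, cassette_parts):
        cov = _coverage(cassette_parts, {"G:002": {"c0": 0, "c1": 10, "k0": 10, "k1": 10}})
        recs = compute_psi(cassette_parts, _junctions([]), cov, mode="raw")
        results, skipped = delta_psi_test(recs, ["c0", "c1"], ["k0", "k1"])
        assert "G:002" in skipped
        assert "insufficient" in skipped["G:002"]

    def test_results_sorted_by_gene_then_part(self):
        parts = flatten_all(cassette_gene("A") + cassette_gene("B", offset=5000))
        cov = _coverage(
            parts,
            {
                p.part_id: {"c0": 10, "c1": 12, "k0": 9, "k1": 11}
                for p in parts
            },
        )
        recs = compute_psi(parts, _junctions([]), cov, mode="raw")
        results, _ = delta_psi_test(recs, ["c0", "c1"], ["k0", "k1"])
        ids = [r.part_id for r in results]
        assert ids == sorted(ids, key=lambda s: (s.split(":")[0], int(s.split(":")[1])))


class TestRetentionIndex:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((50, 25, 25), (2.0, 2.0, 0.5)),
            ((0, 10, 10), (0.0, 0.0, 0.0)),
            ((100, 20, 5), (5.0, 20.0, 0.8)),
        ],
    )
    def test_arithmetic(self, counts, expected):
        assert retention_index(*counts) == pytest.approx(expected)

    def test_all_zero_flagged_undefined(self):
        result = retention_index(0, 0, 0)
        assert all(math.isnan(v) for v in result)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            retention_index(-1, 2, 3)


class TestSplicedSetOverlap:
    def test_equal_sets(self):
        out = spliced_set_overlap({"a", "b"}, {"a", "b"})
        assert out["intersection"] == {"a", "b"} and out["n_only_a"] == 0

    def test_disjoint_sets(self):
        out = spliced_set_overlap({"a"}, {"b"})
        assert out["intersection"] == set() and out["n_intersection"] == 0

    def test_partial_overlap(self):
        out = spliced_set_overlap({"TTN", "MYL2", "TPM1"}, {"TTN", "RYR2"})
        assert out["intersection"] == {"TTN"}
        assert out["only_a"] == {"MYL2", "TPM1"}
        assert out["only_b"] == {"RYR2"}
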