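"""Normalization, Student's t differential expression, candidate logic."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiosplice.de import (
    de_ttest,
    delta_ct,
    nominate_candidates,
    normalize_counts,
    regulation_counts,
    size_factors,
)
from cardiosplice.hss import compute_hss

from _oracles import pooled_t_by_hand


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(counts).tolist() == pytest.approx([1.0, 1.0])

    def test_scale_equivariance(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_hand_computed_medians_of_ratios(self):
        counts = pd.DataFrame({"A": [2, 4, 6], "B": [4, 8, 12]})
        f = size_factors(counts)
        assert f.tolist() == pytest.approx([0.70710678, 1.41421356])

    def test_matches_reference_normalization(self, rng):
        # independent oracle: pydeseq2's median-of-ratios implementation
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(5, 200, size=(100, 1)), size=(100, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        counts += 1  # ensure all-positive genes exist
        _, expected = pydeseq2.deseq2_norm(counts.to_numpy().T)
        assert size_factors(counts).to_numpy() == pytest.approx(expected, rel=1e-4)

    def test_no_qualifying_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [-1, 2], "b": [1, 2]}))


class TestDeTtest:
    def test_fold_change_is_ratio_of_means(self):
        norm = pd.DataFrame(
            {"c1": [4.0], "c2": [4.001], "k1": [2.0], "k2": [1.999]}, index=["g"]
        )
        (rec,) = de_ttest(norm, ["c1", "c2"], ["k1", "k2"])
        assert rec.fold_change == pytest.approx(2.0, rel=1e-3)

    def test_worked_example_matches_hand_formula(self):
        norm = pd.DataFrame(
            {"c1": [1.0], "c2": [2.0], "c3": [3.0], "k1": [4.0], "k2": [5.0], "k3": [6.0]},
            index=["g"],
        )
        (rec,) = de_ttest(norm, ["c1", "c2", "c3"], ["k1", "k2", "k3"])
        t_exp, p_exp = pooled_t_by_hand([1, 2, 3], [4, 5, 6])
        assert rec.t_stat == pytest.approx(t_exp, abs=1e-10)
        assert rec.p_value == pytest.approx(p_exp, abs=1e-10)
        assert rec.t_stat == pytest.approx(-3.674, abs=1e-3)
        assert rec.p_value == pytest.approx(0.021, abs=5e-4)

    def test_t_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(25):
            case = rng.normal(10, 3, size=4)
            ctrl = rng.normal(12, 2, size=5)
            norm = pd.DataFrame(
                [np.concatenate([case, ctrl])],
                columns=[f"c{i}" for i in range(4)] + [f"k{i}" for i in range(5)],
                index=["g"],
            )
            (rec,) = de_ttest(norm, [f"c{i}" for i in range(4)], [f"k{i}" for i in range(5)])
            t_exp, p_exp = pooled_t_by_hand(case, ctrl)
            assert rec.t_stat == pytest.approx(t_exp, abs=1e-10)
            assert rec.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_identical_groups_symmetric(self):
        norm = pd.DataFrame(
            {"c1": [1.0], "c2": [2.0], "k1": [1.0], "k2": [2.0]}, index=["g"]
        )
        (rec,) = de_ttest(norm, ["c1", "c2"], ["k1", "k2"])
        assert rec.fold_change == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged_degenerate(self):
        norm = pd.DataFrame(
            {"c1": [4.0], "c2": [4.0], "k1": [2.0], "k2": [2.0]}, index=["g"]
        )
        (rec,) = de_ttest(norm, ["c1", "c2"], ["k1", "k2"])
        assert rec.degenerate
        assert math.isnan(rec.p_value)
        assert rec.direction == "ns"

    def test_fold_change_equivariance(self):
        norm = pd.DataFrame(
            {"c1": [3.0], "c2": [5.0], "k1": [2.0], "k2": [4.0]}, index=["g"]
        )
        (base,) = de_ttest(norm, ["c1", "c2"], ["k1", "k2"])
        scaled = norm.copy()
        scaled[["c1", "c2"]] *= 7.0
        (after,) = de_ttest(scaled, ["c1", "c2"], ["k1", "k2"])
        assert after.fold_change == pytest.approx(7.0 * base.fold_change)

    def test_too_few_samples_rejected(self):
        norm = pd.DataFrame({"c1": [1.0], "k1": [2.0], "k2": [3.0]}, index=["g"])
        with pytest.raises(ValueError, match="two samples"):
            de_ttest(norm, ["c1"], ["k1", "k2"])


class TestNominate:
    def _hss_records(self, values):
        frame = pd.DataFrame(
            {"heart": list(values.values())} | {f"t{i}": [1.0] * len(values) for i in range(4)},
            index=list(values),
        )
        return compute_hss(frame, "heart", epsilon=0.0)

    def _de_records(self, spec):
        cols = {}
        for gene, (fc, noise) in spec.items():
            cols[gene] = fc
        case = {f"c{i}": [] for i in range(3)}
        ctrl = {f"k{i}": [] for i in range(3)}
        rng = np.random.default_rng(7)
        genes = list(spec)
        for gene in genes:
            fc, sd = spec[gene]
            for i in range(3):
                case[f"c{i}"].append(10.0 * fc + rng.normal(0, sd))
                ctrl[f"k{i}"].append(10.0 + rng.normal(0, sd))
        norm = pd.DataFrame({**case, **ctrl}, index=genes)
        return de_ttest(norm, list(case), list(ctrl))

    def test_threshold_logic(self):
        hss = self._hss_records({"hit": 5.0, "flat": 1.0})
        de = self._de_records({"hit": (1.9, 0.1), "flat": (1.9, 0.1)})
        cands = {c.gene_id: c for c in nominate_candidates(hss, de)}
        assert cands["hit"].verdict
        assert not cands["flat"].verdict  # regulated but not enriched

    def test_enriched_but_not_regulated(self):
        # the heart-restricted-but-stable pattern: high HSS, flat expression
        hss = self._hss_records({"restricted": 11.4})
        de = self._de_records({"restricted": (1.0, 1.0)})
        (cand,) = nominate_candidates(hss, de)
        assert cand.enriched and not cand.regulated and not cand.verdict

    def test_empty_join_rejected(self):
        hss = self._hss_records({"a": 5.0})
        de = self._de_records({"b": (2.0, 0.1)})
        with pytest.raises(ValueError, match="shared"):
            nominate_candidates(hss, de)

    def test_sorted_by_p_then_effect(self):
        hss = self._hss_records({"a": 5.0, "b": 5.0, "c": 5.0})
        de = self._de_records({"a": (1.1, 0.5), "b": (3.0, 0.1), "c": (2.0, 0.1)})
        cands = nominate_candidates(hss, de)
        ps = [c.p_value for c in cands]
        assert ps == sorted(ps)

    def test_regulation_counts(self):
        hss = self._hss_records({"up": 5.0, "down": 5.0})
        de = self._de_records({"up": (2.0, 0.05), "down": (0.5, 0.05)})
        counts = regulation_counts(nominate_candidates(hss, de))
        assert counts == {"up": 1, "down": 1}


class TestNormalization:
    def test_normalization_removes_library_size_differences(self, rng):
        base = rng.uniform(10, 200, size=400)
        depth = np.array([1.0, 2.5, 0.7, 1.8])
        counts = pd.DataFrame(
            rng.poisson(base[:, None] * depth[None, :]),
            columns=[f"s{i}" for i in range(4)],
        )
        norm = normalize_counts(counts, size_factors(counts))
        col_means = norm.mean(axis=0)
        assert col_means.max() / col_means.min() < 1.1


@pytest.mark.parametrize(
    "target,ref,expected",
    [(25, 20, 0.03125), (20, 20, 1.0), (20, 25, 32.0)],
)
def test_delta_ct_closed_form(target, ref, expected):
    assert delta_ct(target, ref) == pytest.approx(expected)


def test_delta_ct_rejects_non_finite():
    with pytest.raises(ValueError):
        delta_ct(float("nan"), 20)
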