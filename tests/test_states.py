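import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txstate.io import SampleMetadata
from txstate.states import (
    benchmark_concordance,
    discretize,
    expression_breadth,
    find_exclusive_markers,
    find_group_markers,
    replicate_concordance,
)


def _probs(data, cells=None):
    cells = cells or [f"c{i}" for i in range(np.shape(data)[1])]
    genes = [f"g{i}" for i in range(np.shape(data)[0])]
    return pd.DataFrame(data, index=genes, columns=cells)


class TestDiscretize:
    def test_threshold_boundaries(self):
        p = _probs([[0.80, 0.20, 0.50, 1.0, 0.0]], cells=list("abcde"))
        st_ = discretize(p)
        assert list(st_.iloc[0]) == ["on", "off", "ambiguous", "on", "off"]

    def test_na_propagates(self):
        p = _probs([[np.nan], [0.9]])
        st_ = discretize(p)
        assert pd.isna(st_.iloc[0, 0]) and st_.iloc[1, 0] == "on"

    def test_invalid_cuts_rejected(self):
        with pytest.raises(ValueError):
            discretize(_probs([[0.5]]), on_cut=0.2, off_cut=0.8)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_idempotent_through_canonical_probabilities(self, values):
        """Mapping labels back to {1, 0.5, 0} and re-discretizing is stable."""
        p = _probs([[v] for v in values], cells=["c"])
        once = discretize(p)
        canon = once.replace({"on": 1.0, "ambiguous": 0.5, "off": 0.0}).astype(float)
        twice = discretize(canon)
        pd.testing.assert_frame_equal(once, twice)


class TestReplicateConcordance:
    @staticmethod
    def _meta(rows):
        return SampleMetadata(
            pd.DataFrame(rows, columns=["sample_id", "driver_id", "cell_type_id", "replicate", "sample_class"])
        )

    def test_identical_replicates_score_one(self):
        states = pd.DataFrame(
            {"d1_r1": ["on", "off"], "d1_r2": ["on", "off"]}, index=["g1", "g2"]
        )
        meta = self._meta([("d1_r1", "d1", "c", 1, "cell_catalog"), ("d1_r2", "d1", "c", 2, "cell_catalog")])
        per_driver, median = replicate_concordance(states, meta)
        assert per_driver["d1"] == 1.0 and median == 1.0

    def test_partial_agreement_counts_genes(self):
        states = pd.DataFrame(
            {
                "d1_r1": ["on", "off", "ambiguous", "on"],
                "d1_r2": ["on", "off", "on", "on"],
            },
            index=[f"g{i}" for i in range(4)],
        )
        meta = self._meta([("d1_r1", "d1", "c", 1, "cell_catalog"), ("d1_r2", "d1", "c", 2, "cell_catalog")])
        per_driver, _ = replicate_concordance(states, meta)
        assert per_driver["d1"] == pytest.approx(0.75)

    def test_single_replicate_drivers_excluded(self):
        states = pd.DataFrame({"d1_r1": ["on"], "d1_r2": ["on"], "d2_r1": ["off"]}, index=["g"])
        meta = self._meta(
            [
                ("d1_r1", "d1", "c", 1, "cell_catalog"),
                ("d1_r2", "d1", "c", 2, "cell_catalog"),
                ("d2_r1", "d2", "c2", 1, "cell_catalog"),
            ]
        )
        per_driver, _ = replicate_concordance(states, meta)
        assert "d2" not in per_driver.index


class TestBenchmarkConcordance:
    def test_perfect_match(self):
        states = _probs([["on", "off"], ["off", "on"]]).astype(object)
        probs = _probs([[0.95, 0.05], [0.1, 0.99]])
        bench = pd.DataFrame(
            {"gene": ["g0", "g1"], "cell_type": ["c0", "c1"], "expected_state": ["on", "on"]}
        )
        res = benchmark_concordance(states, probs, bench)
        assert res.concordance == 1.0
        assert len(res.positive_probability_cdf) == 2

    def test_three_of_four_match_with_ambiguous_excluded(self):
        states = _probs(
            [["on", "off"], ["off", "on"], ["ambiguous", "on"]]
        ).astype(object)
        probs = _probs([[0.9, 0.1], [0.1, 0.9], [0.5, 0.9]])
        bench = pd.DataFrame(
            {
                "gene": ["g0", "g0", "g1", "g2", "g2", "missing"],
                "cell_type": ["c0", "c1", "c0", "c0", "c1", "c0"],
                "expected_state": ["on", "on", "on", "on", "on", "on"],
            }
        )
        res = benchmark_concordance(states, probs, bench)
        # judged: g0/c0 on=on, g0/c1 off!=on, g1/c0 off!=on, g2/c1 on=on
        assert res.concordance == pytest.approx(0.5)
        assert len(res.ambiguous) == 1
        assert len(res.unresolved) == 1

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            benchmark_concordance(_probs([["on"]]), _probs([[0.9]]), pd.DataFrame(columns=["gene", "cell_type", "expected_state"]))


class TestGroupMarkers:
    def test_marker_satisfying_all_three_rules(self):
        probs = _probs([[0.95, 0.95, 0.1, 0.1], [0.95, 0.95, 0.95, 0.95]], cells=list("ABCD"))
        tpm = _probs([[100, 90, 5, 3], [50, 60, 55, 70]], cells=list("ABCD"))
        out = find_group_markers(probs, tpm, {"A", "B"})
        assert list(out.index) == ["g0"]
        assert out.loc["g0", "n_outside_on"] == 0
        assert out.loc["g0", "abundance_margin"] == pytest.approx(85)

    def test_too_many_outside_cells_excluded(self):
        probs = _probs([[0.95] * 2 + [0.95, 0.95, 0.95, 0.1]], cells=list("ABCDEF"))
        tpm = _probs([[100, 90, 5, 3, 2, 1]], cells=list("ABCDEF"))
        out = find_group_markers(probs, tpm, {"A", "B"}, max_outside=2)
        assert out.empty

    def test_group_of_all_cells_reduces_to_on_everywhere(self):
        probs = _probs([[0.95, 0.92], [0.95, 0.2]], cells=["A", "B"])
        tpm = _probs([[1, 1], [1, 1]], cells=["A", "B"])
        out = find_group_markers(probs, tpm, {"A", "B"})
        assert list(out.index) == ["g0"]

    @given(
        in_cut=st.floats(0.5, 0.99),
        tighter=st.floats(0.001, 0.2),
    )
    def test_marker_set_shrinks_with_stricter_cut(self, in_cut, tighter):
        rng = np.random.default_rng(6)
        probs = _probs(rng.random((40, 6)), cells=list("ABCDEF"))
        tpm = _probs(rng.random((40, 6)) * 100, cells=list("ABCDEF"))
        loose = set(find_group_markers(probs, tpm, {"A", "B"}, in_cut=in_cut).index)
        tight = set(find_group_markers(probs, tpm, {"A", "B"}, in_cut=min(in_cut + tighter, 1.0)).index)
        assert tight <= loose
        fewer_outside = set(find_group_markers(probs, tpm, {"A", "B"}, in_cut=in_cut, max_outside=1).index)
        assert fewer_outside <= set(find_group_markers(probs, tpm, {"A", "B"}, in_cut=in_cut, max_outside=2).index)


class TestExclusiveMarkers:
    def test_on_in_targets_off_in_background(self):
        probs = _probs([[0.9, 0.95, 0.1, 0.05], [0.9, 0.5, 0.1, 0.1], [0.9, 0.9, 0.5, 0.1]], cells=["t1", "t2", "b1", "b2"])
        out = find_exclusive_markers(probs, {"t1", "t2"}, {"b1", "b2"})
        assert out == ["g0"]  # g1 not on in t2; g2 ambiguous in b1

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            find_exclusive_markers(_probs([[0.9]]), {"c0"}, {"c0"})

    def test_empty_result_when_nothing_qualifies(self):
        probs = _probs([[0.5, 0.5]], cells=["t", "b"])
        assert find_exclusive_markers(probs, {"t"}, {"b"}) == []


class TestExpressionBreadth:
    def test_counts_on_cells(self):
        states = _probs([["on"] * 7 + ["off"] * 13]).astype(object)
        states.columns = [f"c{i}" for i in range(20)]
        breadth, _ = expression_breadth(states)
        assert breadth.iloc[0] == 7

    def test_small_groups_excluded_from_summaries(self):
        rng = np.random.default_rng(3)
        states = _probs(np.where(rng.random((30, 5)) < 0.5, "on", "off")).astype(object)
        groups = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(19)], "group": ["big"] * 10 + ["small"] * 9}
        )
        _, by_group = expression_breadth(states, groups, min_group_size=10)
        assert "big" in by_group and "small" not in by_group

    def test_breadth_sum_equals_total_on_entries(self, rng):
        states = _probs(np.where(rng.random((25, 6)) < 0.4, "on", "off")).astype(object)
        breadth, _ = expression_breadth(states)
        assert breadth.sum() == (states == "on").to_numpy().sum()
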