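"""Differential expression: CPM arithmetic, DET rules, ordination transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralmeta import (
    DataError,
    DesignError,
    ExpressionMatrix,
    bray_curtis,
    call_dets,
    cpm,
    ordination_transform,
    pairwise_de,
)
from coralmeta.diffexpr import LOGFC_CUTOFF, P_THRESHOLDS
from coralmeta.simulate import COMPARISONS


def _counts(values, samples=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(
        "coral",
        "count",
        pd.DataFrame(
            np.asarray(values, dtype=float),
            index=[f"t{i}" for i in range(np.asarray(values).shape[0])],
            columns=samples,
        ),
    )


class TestCpm:
    def test_column_arithmetic(self):
        out = cpm(_counts([[1.0], [1.0], [2.0]]))
        assert out.data["s0"].tolist() == [250000.0, 250000.0, 500000.0]

    def test_zero_row_stays_zero_and_columns_sum_to_a_million(self):
        out = cpm(_counts([[0, 0], [5, 2], [5, 8]]))
        assert (out.data.loc["t0"] == 0).all()
        assert out.data.sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6])

    def test_zero_library_names_sample(self):
        with pytest.raises(DataError, match="s1"):
            cpm(_counts([[1, 0], [2, 0]]))

    def test_rejects_cpm_input(self, tiny_cpm):
        with pytest.raises(DataError):
            cpm(tiny_cpm)


class TestPairwiseDE:
    @staticmethod
    def _design():
        return pd.DataFrame(
            {
                "sample_id": ["c1", "c2", "c3", "t1", "t2", "t3"],
                "treatment": ["control"] * 3 + ["40"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )

    def _mat(self, ctrl, treat):
        data = pd.DataFrame(
            {
                "c1": ctrl,
                "c2": ctrl,
                "c3": ctrl,
                "t1": treat,
                "t2": treat,
                "t3": treat,
            },
            index=[f"t{i}" for i in range(len(ctrl))],
        )
        return ExpressionMatrix("coral", "cpm", data)

    def test_logfc_is_log2_ratio_of_group_means(self):
        res = pairwise_de(self._mat([100.0], [400.0]), self._design(), "40", prior=0.0)
        assert res["logFC"].iloc[0] == pytest.approx(2.0)

    def test_identical_groups_never_significant(self):
        res = pairwise_de(self._mat([250.0, 30.0], [250.0, 30.0]), self._design(), "40")
        assert res["logFC"].to_numpy() == pytest.approx([0.0, 0.0])
        assert not res["significant"].any()

    def test_logfc_exactly_one_is_not_significant(self):
        # strict "more than 1": boundary value fails even at tiny p
        res = pairwise_de(
            self._mat([100.0], [200.0]),
            self._design(),
            "40",
            test=lambda a, b: 1e-6,
            prior=0.0,
        )
        assert res["logFC"].iloc[0] == pytest.approx(1.0)
        assert not res["significant"].iloc[0]

    def test_just_above_cutoff_with_small_p_is_significant(self):
        res = pairwise_de(
            self._mat([100.0], [210.0]),
            self._design(),
            "40",
            test=lambda a, b: 1e-6,
            prior=0.0,
        )
        assert res["significant"].iloc[0]

    def test_treatment_must_not_be_control(self, tiny_cpm):
        with pytest.raises(DesignError):
            pairwise_de(tiny_cpm, self._design(), "control")

    def test_missing_group_raises(self, tiny_cpm):
        with pytest.raises(DesignError):
            pairwise_de(self._mat([1.0], [2.0]), self._design(), "10")


def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["transcript_id", "comparison", "logFC", "p_value", "significant"]
    )


class TestCallDets:
    def test_set_algebra_and_shared_region(self):
        per = {
            "control_vs_5": {"a", "b"},
            "control_vs_10": {"b"},
            "control_vs_20": {"b", "c"},
            "control_vs_40": {"b"},
        }
        rows = []
        for comp in COMPARISONS:
            for tid in ("a", "b", "c"):
                rows.append((tid, comp, 2.0, 1e-6, tid in per[comp]))
        dets = call_dets(_results_frame(rows), "coral")
        assert dets.union == {"a", "b", "c"}
        assert dets.shared_all == {"b"}
        assert dets.venn_counts["&".join(sorted(COMPARISONS))] == 1
        assert sum(dets.venn_counts.values()) == len(dets.union)

    def test_empty_results(self):
        dets = call_dets(_results_frame([]), "coral")
        assert dets.union == set()
        assert dets.venn_counts == {}

    def test_up_down_counts(self):
        rows = []
        for comp in COMPARISONS:
            rows.append(("up1", comp, 2.0, 1e-6, True))
            rows.append(("dn1", comp, -2.0, 1e-6, True))
        dets = call_dets(_results_frame(rows), "coral")
        table = dets.up_down.set_index("comparison")
        assert (table["up"] == 1).all() and (table["down"] == 1).all()

    @given(
        sig=st.lists(
            st.tuples(st.sampled_from(list(COMPARISONS)), st.integers(0, 30)),
            max_size=60,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_venn_counts_always_sum_to_union(self, sig):
        rows = [(f"t{i}", comp, 2.0, 1e-6, True) for comp, i in sig]
        for comp in COMPARISONS:  # ensure all comparisons appear
            rows.append(("anchor", comp, 0.0, 1.0, False))
        dets = call_dets(_results_frame(rows), "coral")
        assert sum(dets.venn_counts.values()) == len(dets.union)

    @given(
        logfc=st.floats(-4, 4, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_significance_is_exactly_the_conjunction(self, logfc, p):
        mat = ExpressionMatrix(
            "coral",
            "cpm",
            pd.DataFrame(
                {
                    "c1": [100.0],
                    "c2": [100.0],
                    "t1": [100.0 * 2**logfc],
                    "t2": [100.0 * 2**logfc],
                },
                index=["t0"],
            ),
        )
        design = pd.DataFrame(
            {
                "sample_id": ["c1", "c2", "t1", "t2"],
                "treatment": ["control", "control", "40", "40"],
                "replicate": [1, 2, 1, 2],
            }
        )
        res = pairwise_de(mat, design, "40", test=lambda a, b: p, prior=0.0)
        expected = (abs(res["logFC"].iloc[0]) > LOGFC_CUTOFF) and (
            p <= P_THRESHOLDS["coral"]
        )
        assert bool(res["significant"].iloc[0]) == expected


class TestOrdination:
    def test_transform_value(self):
        mat = ExpressionMatrix(
            "coral", "cpm", pd.DataFrame({"s": [1.0]}, index=["t"])
        )
        out = ordination_transform(mat)
        assert out.iloc[0, 0] == pytest.approx(1.0)  # sqrt(log2(1+1)) = 1

    def test_identical_samples_distance_zero(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["t0", "t1"])
        d = bray_curtis(t)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        t = pd.DataFrame({"a": [3.0, 0.0], "b": [0.0, 5.0]}, index=["t0", "t1"])
        assert bray_curtis(t).loc["a", "b"] == pytest.approx(1.0)

    @given(
        vals=st.lists(
            st.lists(st.floats(0, 1e4, allow_nan=False), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_braycurtis_bounds_symmetry_diagonal(self, vals):
        t = pd.DataFrame(
            np.asarray(vals, dtype=float).T,
            index=[f"t{i}" for i in range(3)],
            columns=[f"s{i}" for i in range(len(vals))],
        )
        d = bray_curtis(t).to_numpy()
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(DataError):
            bray_curtis(pd.DataFrame({"a": [-1.0], "b": [1.0]}))
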