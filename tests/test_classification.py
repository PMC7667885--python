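import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaprime.differential_classification import (
    ClassParams,
    ContrastSpec,
    call_dependent,
    intersect_calls,
    per_window_fold,
    rank_windows,
    select_invariant,
)
from chromaprime.errors import ConfigError, InsufficientWindows, WindowSetMismatch
from chromaprime.windows_counting import CountMatrix


def norm_matrix(data: dict, ids=None) -> CountMatrix:
    df = pd.DataFrame(data, dtype=float)
    df.index = ids or [f"w{i:03d}" for i in range(len(df))]
    return CountMatrix(df, raw=False)


CONTRAST = ContrastSpec("c", (("a1", "b1"), ("a2", "b2")))


def rule_oracle(df, pairs, params):
    """Literal per-window evaluation of the calling rule."""
    members = []
    for w in df.index:
        ok = True
        for a, b in pairs:
            fc = (df.loc[w, a] + params.pseudocount) / (df.loc[w, b] + params.pseudocount)
            if not (fc >= params.fold_threshold and max(df.loc[w, a], df.loc[w, b]) >= params.min_count):
                ok = False
                break
        if ok:
            members.append(w)
    return members


class TestPerWindowFold:
    def test_equal_counts_give_unit_fold(self):
        m = norm_matrix({"a1": [5, 10], "b1": [5, 10]})
        assert (per_window_fold(m, ("a1", "b1")) == 1.0).all()

    def test_pseudocounted_arithmetic(self):
        m = norm_matrix({"a1": [20], "b1": [9]})
        assert per_window_fold(m, ("a1", "b1"), 1.0).iloc[0] == pytest.approx(2.1)

    def test_double_zero_with_pseudocount_is_one(self):
        m = norm_matrix({"a1": [0], "b1": [0]})
        assert per_window_fold(m, ("a1", "b1"), 1.0).iloc[0] == 1.0

    def test_zero_pseudocount_zero_denominator_is_inf(self):
        m = norm_matrix({"a1": [3, 0], "b1": [0, 0]})
        fc = per_window_fold(m, ("a1", "b1"), 0.0)
        assert np.isinf(fc.iloc[0])
        assert fc.iloc[1] == 1.0


class TestCallDependent:
    def test_identical_conditions_call_nothing(self):
        m = norm_matrix({"a1": [50, 60], "b1": [50, 60], "a2": [50, 60], "b2": [50, 60]})
        assert call_dependent(m, CONTRAST).members == []

    def test_toy_rule_evaluation(self):
        """w1 passes both replicates; w2 fails replicate 2's fold; w3 fails
        the background cutoff despite large folds."""
        m = norm_matrix({
            "a1": [41, 41, 8], "b1": [9, 9, 1],
            "a2": [61, 25, 9], "b2": [19, 19, 1],
        }, ids=["w1", "w2", "w3"])
        params = ClassParams(fold_threshold=2.0, pseudocount=1.0, min_count=10.0)
        cs = call_dependent(m, CONTRAST, params)
        assert cs.members == ["w1"]
        assert cs.folds.loc["w1"].tolist() == pytest.approx([42 / 10, 62 / 20])

    def test_fold_threshold_one_keeps_all_above_min_count(self):
        m = norm_matrix({"a1": [50, 5], "b1": [50, 5], "a2": [50, 5], "b2": [50, 5]})
        cs = call_dependent(m, CONTRAST, ClassParams(1.0, 1.0, 20.0))
        assert cs.members == ["w000"]

    def test_threshold_boundary_is_closed(self):
        # fold exactly 2.0 with pseudocount: (39+1)/(19+1) = 2.0 -> member
        m = norm_matrix({"a1": [39], "b1": [19], "a2": [39], "b2": [19]})
        cs = call_dependent(m, CONTRAST, ClassParams(2.0, 1.0, 10.0))
        assert cs.members == ["w000"]

    def test_unknown_sample_raises(self):
        m = norm_matrix({"a1": [1]})
        with pytest.raises(ConfigError):
            call_dependent(m, CONTRAST)

    def test_raw_matrix_rejected(self):
        df = pd.DataFrame({"a1": [1], "b1": [1], "a2": [1], "b2": [1]})
        with pytest.raises(ValueError):
            call_dependent(CountMatrix(df, raw=True), CONTRAST)

    @settings(max_examples=80, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(1.0, 4.0),
        st.floats(0.0, 2.0),
        st.floats(0.0, 40.0),
    )
    def test_matches_rule_oracle_on_random_matrices(self, seed, fold, pseudo, min_count):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        df = pd.DataFrame(
            rng.integers(0, 120, size=(n, 4)).astype(float),
            columns=["a1", "b1", "a2", "b2"],
            index=[f"w{i:03d}" for i in range(n)],
        )
        m = CountMatrix(df, raw=False)
        params = ClassParams(fold, pseudo, min_count)
        assert call_dependent(m, CONTRAST, params).members == rule_oracle(
            df, CONTRAST.pairs, params
        )

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_thresholds(self, seed):
        """Raising fold_threshold or min_count never adds members."""
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.integers(0, 100, size=(40, 4)).astype(float),
            columns=["a1", "b1", "a2", "b2"],
            index=[f"w{i:03d}" for i in range(40)],
        )
        m = CountMatrix(df, raw=False)
        loose = set(call_dependent(m, CONTRAST, ClassParams(1.5, 1.0, 10.0)).members)
        tighter_fold = set(call_dependent(m, CONTRAST, ClassParams(2.5, 1.0, 10.0)).members)
        tighter_count = set(call_dependent(m, CONTRAST, ClassParams(1.5, 1.0, 30.0)).members)
        assert tighter_fold <= loose
        assert tighter_count <= loose


class TestIntersectCalls:
    def _cs(self, members, label="x"):
        m = norm_matrix({"a1": [50] * 4, "b1": [1] * 4, "a2": [50] * 4, "b2": [1] * 4},
                        ids=["w1", "w2", "w3", "w4"])
        cs = call_dependent(m, CONTRAST)
        cs.members = members
        cs.label = label
        return cs

    def test_self_intersection_is_identity(self):
        a = self._cs(["w1", "w2"])
        assert intersect_calls(a, a).members == ["w1", "w2"]

    def test_set_semantics(self):
        a = self._cs(["w1", "w2", "w3"], "a")
        b = self._cs(["w2", "w3", "w4"], "b")
        got = intersect_calls(a, b)
        assert got.members == ["w2", "w3"]
        assert got.provenance == ("a", "b")

    def test_disjoint_sets_empty(self):
        assert intersect_calls(self._cs(["w1"]), self._cs(["w4"])).members == []

    def test_window_set_mismatch_raises(self):
        a = self._cs(["w1"])
        m = norm_matrix({"a1": [50], "b1": [1], "a2": [50], "b2": [1]}, ids=["other"])
        b = call_dependent(m, CONTRAST)
        with pytest.raises(WindowSetMismatch):
            intersect_calls(a, b)


class TestSelectInvariant:
    def _key(self, ids, chroms=None, starts=None):
        return pd.DataFrame(
            {"chrom": chroms or ["chr1"] * len(ids),
             "start": starts or list(range(len(ids)))},
            index=ids,
        )

    def test_perfectly_invariant_ties_break_by_coordinate(self):
        ids = [f"w{i}" for i in range(8)]
        df = pd.DataFrame({c: [50.0] * 8 for c in ["a1", "b1", "a2", "b2"]}, index=ids)
        m = CountMatrix(df, raw=False, window_key=self._key(ids))
        got = select_invariant(m, [CONTRAST], 5)
        assert got.members == ids[:5]

    def test_matches_exhaustive_sort_oracle(self):
        ids = [f"w{i}" for i in range(6)]
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.integers(20, 200, size=(6, 4)).astype(float),
                          columns=["a1", "b1", "a2", "b2"], index=ids)
        m = CountMatrix(df, raw=False, window_key=self._key(ids))
        got = select_invariant(m, [CONTRAST], 3)
        scores = {}
        for w in ids:
            worst = max(
                abs(np.log2((df.loc[w, a] + 1) / (df.loc[w, b] + 1)))
                for a, b in CONTRAST.pairs
            )
            scores[w] = worst
        expected = sorted(sorted(ids), key=lambda w: scores[w])[:3]
        assert sorted(got.members) == sorted(expected)

    def test_n_zero_empty(self):
        ids = ["w0"]
        df = pd.DataFrame({c: [50.0] for c in ["a1", "b1", "a2", "b2"]}, index=ids)
        m = CountMatrix(df, raw=False, window_key=self._key(ids))
        assert select_invariant(m, [CONTRAST], 0).members == []

    def test_low_coverage_windows_ineligible(self):
        ids = ["w0", "w1"]
        df = pd.DataFrame({"a1": [50.0, 5.0], "b1": [50.0, 5.0],
                           "a2": [50.0, 5.0], "b2": [50.0, 5.0]}, index=ids)
        m = CountMatrix(df, raw=False, window_key=self._key(ids))
        with pytest.raises(InsufficientWindows):
            select_invariant(m, [CONTRAST], 2)


class TestRankWindows:
    def test_orders_by_increasing_fold(self):
        m = norm_matrix({"a1": [9, 39, 19], "b1": [19, 19, 19]},
                        ids=["w1", "w2", "w3"])
        assert rank_windows(m, ("a1", "b1")) == ["w1", "w3", "w2"]

    def test_equal_folds_fall_back_to_coordinate_order(self):
        ids = ["w2", "w1"]  # matrix rows deliberately out of coordinate order
        df = pd.DataFrame({"a1": [10.0, 10.0], "b1": [10.0, 10.0]}, index=ids)
        key = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [500, 100]}, index=ids)
        m = CountMatrix(df, raw=False, window_key=key)
        assert rank_windows(m, ("a1", "b1")) == ["w1", "w2"]

    def test_reversed_pair_reverses_order_without_pseudocount(self):
        m = norm_matrix({"a1": [10, 40, 20], "b1": [40, 10, 20]},
                        ids=["w1", "w2", "w3"])
        fwd = rank_windows(m, ("a1", "b1"), pseudocount=0.0)
        rev = rank_windows(m, ("b1", "a1"), pseudocount=0.0)
        assert fwd == list(reversed(rev))
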