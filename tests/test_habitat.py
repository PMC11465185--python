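"""P_epi classification, persistence, Welch t and the summary report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from stratovir.config import STRATIFIED_MONTHS
from stratovir.habitat import (EPI, GENERALIST, HYPO, UNCLASSIFIED,
                               HabitatCall, classify_habitat,
                               gene_sharing_partition, p_epi, persistence,
                               persistence_cohort, summary_report, welch_t)

MONTH8 = list(STRATIFIED_MONTHS)


def series(values, months=MONTH8):
    return dict(zip(months, values))


class TestPEpi:
    def test_epilimnion_only(self):
        p = p_epi(series([5, 0, 0, 0, 0, 0, 0, 0]),
                  series([0] * 8), MONTH8)
        assert p == 1.0

    def test_boundary_value_is_generalist(self):
        p = p_epi(series([19, 0, 0, 0, 0, 0, 0, 0]),
                  series([1, 0, 0, 0, 0, 0, 0, 0]), MONTH8)
        assert p == pytest.approx(0.95)
        assert classify_habitat(p) == GENERALIST  # strict > 0.95

    def test_undefined_when_absent(self):
        assert p_epi(series([0] * 8), series([0] * 8), MONTH8) is None
        assert classify_habitat(None) == UNCLASSIFIED

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            p_epi(series([1] * 7, MONTH8[:7]), series([1] * 8), MONTH8)

    @given(st.lists(st.floats(0, 100), min_size=8, max_size=8),
           st.lists(st.floats(0, 100), min_size=8, max_size=8))
    def test_complement_symmetry(self, epi, hypo):
        p1 = p_epi(series(epi), series(hypo), MONTH8)
        p2 = p_epi(series(hypo), series(epi), MONTH8)
        if p1 is not None:
            assert p1 + p2 == pytest.approx(1.0)


class TestClassify:
    @pytest.mark.parametrize("p,label", [
        (0.96, EPI), (0.04, HYPO), (0.50, GENERALIST),
        (0.95, GENERALIST), (0.05, GENERALIST), (None, UNCLASSIFIED),
    ])
    def test_labels(self, p, label):
        assert classify_habitat(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_habitat(1.2)


def persistence_oracle(values, threshold=0.20):
    best = run = 0
    for v in values:
        run = run + 1 if v > threshold else 0
        best = max(best, run)
    return best


class TestPersistence:
    def test_run_scan_example(self):
        vals = [0.25, 0.30, 0.15, 0.21, 0.22, 0.23, 0.05, 0.90]
        assert persistence(series(vals), MONTH8) == 3

    def test_threshold_is_strict(self):
        assert persistence(series([0.20] * 8), MONTH8) == 0
        assert persistence(series([0.21] * 8), MONTH8) == 8

    def test_months_outside_stratification_ignored(self):
        months = MONTH8 + ["Jan"]
        vals = series([0.0] * 8, MONTH8)
        vals["Jan"] = 0.99
        assert persistence(vals, MONTH8) == 0

    def test_empty_stratified_period_rejected(self):
        with pytest.raises(ValueError):
            persistence(series([0.5] * 8), [])

    def test_exhaustive_binary_series(self):
        """All 4096 binary occupancy patterns of a 12-month year."""
        months = [f"m{i}" for i in range(12)]
        for mask in range(2 ** 12):
            vals = [(0.5 if (mask >> i) & 1 else 0.0) for i in range(12)]
            assert persistence(dict(zip(months, vals)), months) == \
                persistence_oracle(vals)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=5e-4)
        assert df == pytest.approx(2.941, abs=5e-4)

    def test_antisymmetry(self):
        t1, _, p1 = welch_t([1, 5, 2, 8], [4, 4, 9])
        t2, _, p2 = welch_t([4, 4, 9], [1, 5, 2, 8])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_cases(self):
        _, _, p_eq = welch_t([2, 2, 2], [2, 2])
        assert p_eq == 1.0
        t, _, p_ne = welch_t([2, 2, 2], [3, 3])
        assert p_ne > 0.0 and np.isinf(t)

    def test_matches_high_precision_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           int(rng.integers(2, 40)))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           int(rng.integers(2, 40)))
            t, df, p = welch_t(a, b)
            ref = sstats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


def _covfrac_grid(rows):
    cols = pd.MultiIndex.from_tuples(
        [(m, layer) for m in MONTH8 for layer in
         ("epilimnion", "hypolimnion")], names=["month", "layer"])
    data = []
    for epi_vals, hypo_vals in rows.values():
        row = []
        for e, h in zip(epi_vals, hypo_vals):
            row += [e, h]
        data.append(row)
    return pd.DataFrame(data, index=list(rows), columns=cols)


class TestPersistenceCohort:
    def test_single_epi_specialist(self):
        grid = _covfrac_grid({"m1": ([0.5, 0.5, 0, 0, 0, 0, 0, 0],
                                     [0] * 8)})
        calls = [HabitatCall("m1", 0.99, EPI)]
        out = persistence_cohort(calls, grid, MONTH8)
        assert out["groups"][EPI] == [2]
        assert out["medians"][EPI] == 2
        assert out["welch_p"] is None  # groups too small for the test

    def test_specialists_scored_in_own_layer(self):
        grid = _covfrac_grid({"h1": ([0.9] * 8, [0.5] * 4 + [0] * 4)})
        calls = [HabitatCall("h1", 0.01, HYPO)]
        out = persistence_cohort(calls, grid, MONTH8)
        assert out["groups"][HYPO] == [4]  # epilimnion series ignored

    def test_generalists_excluded_by_default(self):
        grid = _covfrac_grid({"g": ([0.9] * 8, [0.9] * 8),
                              "e": ([0.5] * 2 + [0] * 6, [0] * 8),
                              "h": ([0] * 8, [0.5] * 8)})
        calls = [HabitatCall("g", 0.5, GENERALIST),
                 HabitatCall("e", 0.99, EPI),
                 HabitatCall("h", 0.01, HYPO)]
        out = persistence_cohort(calls, grid, MONTH8)
        assert sum(len(v) for v in out["groups"].values()) == 2
        out2 = persistence_cohort(calls, grid, MONTH8,
                                  include_generalists=True)
        assert out2["groups"][GENERALIST] == [8]


class TestGeneSharing:
    def test_set_algebra_by_hand(self):
        shared, excl = gene_sharing_partition({
            EPI: {"a", "b", "c"}, HYPO: {"b", "d"},
            GENERALIST: {"b", "c", "e"}})
        assert shared == 2
        assert excl[EPI] == 1 and excl[HYPO] == 1

    def test_disjoint_sets(self):
        shared, excl = gene_sharing_partition({
            EPI: {"a"}, HYPO: {"b"}, GENERALIST: {"c"}})
        assert shared == 0
        assert excl == {EPI: 1, HYPO: 1, GENERALIST: 1}

    def test_identical_sets(self):
        s = {"x", "y"}
        shared, excl = gene_sharing_partition(
            {EPI: set(s), HYPO: set(s), GENERALIST: set(s)})
        assert shared == 2
        assert all(v == 0 for v in excl.values())

    def test_missing_class_rejected(self):
        with pytest.raises(KeyError):
            gene_sharing_partition({EPI: {"a"}, HYPO: {"b"}})


class TestSummaryReport:
    def test_classification_is_a_partition(self):
        calls = [HabitatCall("a", 0.99, EPI), HabitatCall("b", 0.01, HYPO),
                 HabitatCall("c", 0.5, GENERALIST),
                 HabitatCall("d", None, UNCLASSIFIED)]
        quality = pd.DataFrame(
            {"tier": ["high", "low", "low", "low"],
             "marker_count": [7, 1, 2, 0], "n_contigs": [1, 3, 4, 5]},
            index=list("abcd"))
        rep = summary_report(calls, quality)
        assert (rep["n_epilimnion_specific"] + rep["n_hypolimnion_specific"]
                + rep["n_generalist"] + rep["n_unclassified"]) == \
            rep["n_total"]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            summary_report([], pd.DataFrame(
                columns=["tier", "marker_count", "n_contigs"]))

    def test_denominator_mode_excluding_unclassified(self):
        calls = [HabitatCall("a", 0.99, EPI),
                 HabitatCall("b", None, UNCLASSIFIED)]
        quality = pd.DataFrame(
            {"tier": ["low", "low"], "marker_count": [1, 0],
             "n_contigs": [1, 1]}, index=list("ab"))
        rep_all = summary_report(calls, quality)
        rep_cls = summary_report(calls, quality,
                                 exclude_unclassified_from_denominator=True)
        assert rep_all["pct_epilimnion_specific"] == 50.0
        assert rep_cls["pct_epilimnion_specific"] == 100.0
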