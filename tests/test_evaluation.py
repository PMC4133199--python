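import math

import numpy as np
import pandas as pd
import pytest

from strokeatlas.build import build_psm, NoContributingCasesError
from strokeatlas.core import CaseRecord, ContourFile, SelectionSpec, OUTCOME_PARAMETERS
from strokeatlas.evaluation import (
    TABLE_COLUMNS,
    best_selection_variables,
    compare_variants,
    dichotomized_auc,
    enumerate_grid,
    error_reduction_ratio,
    plan_loo,
    reference_grid,
    reference_nihss_ranges,
    reference_volume_ranges,
    run_loo,
    selection_of_row,
    summarize_by_variant,
)
from strokeatlas.prediction import UncoveredError, extract_distribution
from strokeatlas.weighting import BUILTIN_WEIGHT_IDS

from conftest import micro_cohort

INF = math.inf


def make_row(
    case_id="c0", parameter="mRS90", weight_id=1,
    vol=(0.0, INF), na=(0, 42), n7=(0, 42),
    predicted=3.0, actual=3.0, covered=True,
):
    err = abs(predicted - actual) if covered and actual is not None else None
    return (
        case_id, parameter, weight_id,
        vol[0], vol[1], na[0], na[1], n7[0], n7[1],
        predicted if covered else None, actual, err, covered,
    )


def table_of(rows):
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


class TestEnumerateGrid:
    def test_reference_grid_is_512_cells(self):
        grid = enumerate_grid(
            BUILTIN_WEIGHT_IDS,
            reference_volume_ranges(),
            reference_nihss_ranges(),
            reference_nihss_ranges(),
        )
        assert len(grid) == 512
        assert grid == reference_grid()

    def test_single_cell(self):
        grid = enumerate_grid([1], [(0.0, INF)], [(0, 42)], [(0, 42)])
        assert len(grid) == 1
        assert grid[0] == (1, SelectionSpec.all_cases())

    def test_product_size(self):
        grid = enumerate_grid(
            [1, 2], [(0.0, 1.0), (0.0, 2.0), (0.0, INF)], [(0, 42)], [(0, 42)]
        )
        assert len(grid) == 6

    def test_deterministic_order(self):
        assert reference_grid() == reference_grid()

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid([], [(0.0, INF)], [(0, 42)], [(0, 42)])


class TestPlanLoo:
    def test_reference_scale_bookkeeping(self):
        wl = plan_loo(128, OUTCOME_PARAMETERS, reference_grid())
        assert wl.n_grid_cells == 512
        assert wl.n_psm_builds == 589_824
        assert wl.n_case_processings == 74_907_648

    def test_tiny_counts(self):
        wl = plan_loo(3, ["mRS90"], [(1, SelectionSpec.all_cases())])
        assert wl.n_psm_builds == 3
        assert wl.n_case_processings == 6


class TestRunLoo:
    def test_requires_two_cases(self, small_space):
        rng = np.random.default_rng(0)
        cases, contours = micro_cohort(rng, 1, small_space)
        with pytest.raises(ValueError):
            run_loo(cases, contours, ["mRS90"], [(1, SelectionSpec.all_cases())])

    def test_identical_cases_zero_error_w1(self, small_space):
        mask = np.zeros(small_space.dims, bool)
        mask[2:6, 2:6, 1:4] = True
        contours = {
            "a": ContourFile("a", mask, small_space),
            "b": ContourFile("b", mask, small_space),
        }
        cases = [
            CaseRecord("a", infarct_volume_cm3=1.0, mrs={90: 4}),
            CaseRecord("b", infarct_volume_cm3=1.0, mrs={90: 4}),
        ]
        tab = run_loo(cases, contours, ["mRS90"], [(1, SelectionSpec.all_cases())])
        assert (tab["abs_error"] == 0.0).all()

    def test_equals_direct_composition_oracle(self, small_space):
        rng = np.random.default_rng(8)
        cases, contours = micro_cohort(rng, 5, small_space, density=0.35)
        grid = enumerate_grid(
            [1, 2, 3, 5], [(0.0, INF), (0.0, 0.05)], [(0, 42), (0, 10)], [(0, 42)]
        )
        tab = run_loo(cases, contours, ["mRS90"], grid)
        for _, row in tab.iterrows():
            c = next(c for c in cases if c.case_id == row["case_id"])
            others = [x for x in cases if x.case_id != c.case_id]
            sel = selection_of_row(row)
            try:
                psm = build_psm(
                    others, contours, "mRS90", int(row["weight_id"]),
                    selection=sel,
                    predicted_contour=contours[c.case_id],
                    space=small_space,
                )
                res = extract_distribution(psm, contours[c.case_id])
            except (NoContributingCasesError, UncoveredError):
                assert not row["covered"]
                continue
            assert row["covered"]
            assert row["predicted"] == pytest.approx(res.predicted_mean, rel=1e-9)

    def test_predicted_case_never_in_its_own_atlas(self, small_space):
        # poison one case's value: its own prediction must not move
        rng = np.random.default_rng(12)
        cases, contours = micro_cohort(rng, 6, small_space)
        grid = [(1, SelectionSpec.all_cases())]
        base = run_loo(cases, contours, ["mRS90"], grid)
        poisoned = [
            CaseRecord(
                c.case_id, infarct_volume_cm3=c.infarct_volume_cm3,
                nihss_admission=c.nihss_admission, nihss_day7=c.nihss_day7,
                mrs={90: 6 if c.case_id == "c0" else c.mrs[90]},
            )
            for c in cases
        ]
        after = run_loo(poisoned, contours, ["mRS90"], grid)
        row_b = base[base["case_id"] == "c0"].iloc[0]
        row_a = after[after["case_id"] == "c0"].iloc[0]
        assert row_b["predicted"] == row_a["predicted"]

    def test_micro_cohort_composition_three_cases(self, small_space):
        rng = np.random.default_rng(30)
        cases, contours = micro_cohort(rng, 3, small_space, density=0.5)
        grid = [(1, SelectionSpec.all_cases())]
        tab = run_loo(cases, contours, ["mRS90"], grid)
        assert len(tab) == 3
        for _, row in tab.iterrows():
            others = [x for x in cases if x.case_id != row["case_id"]]
            psm = build_psm(others, contours, "mRS90", 1, space=small_space)
            res = extract_distribution(psm, contours[row["case_id"]])
            assert row["predicted"] == pytest.approx(res.predicted_mean, rel=1e-12)


class TestSummaries:
    def test_equal_errors(self):
        tab = table_of([make_row(case_id=f"c{i}", predicted=4.0, actual=3.0)
                        for i in range(5)])
        s = summarize_by_variant(tab, "all")
        assert s.loc[1, "mean"] == 1.0
        assert s.loc[1, "sd"] == 0.0

    def test_hand_computed_pool(self):
        # errors {0, 2}: mean 1, sample SD sqrt(2)
        tab = table_of([
            make_row(case_id="c0", predicted=3.0, actual=3.0),
            make_row(case_id="c1", predicted=5.0, actual=3.0),
        ])
        s = summarize_by_variant(tab, "all")
        assert s.loc[1, "mean"] == 1.0
        assert s.loc[1, "sd"] == pytest.approx(math.sqrt(2.0))

    def test_single_row_sd_zero_with_n_flag(self):
        tab = table_of([make_row(predicted=4.5, actual=3.0)])
        s = summarize_by_variant(tab, "all")
        assert s.loc[1, "sd"] == 0.0
        assert s.loc[1, "n"] == 1

    def test_uncovered_rows_excluded(self):
        tab = table_of([
            make_row(case_id="c0", predicted=4.0, actual=3.0),
            make_row(case_id="c1", covered=False),
        ])
        assert summarize_by_variant(tab, "all").loc[1, "n"] == 1

    def test_mode_filters_cells(self):
        tab = table_of([
            make_row(case_id="c0", predicted=4.0, actual=3.0),            # all cell
            make_row(case_id="c0", vol=(0.0, 8.0), predicted=3.5, actual=3.0),
            make_row(case_id="c0", na=(0, 5), predicted=5.0, actual=3.0),
        ])
        assert summarize_by_variant(tab, "all").loc[1, "n"] == 1
        assert summarize_by_variant(tab, "volume").loc[1, "n"] == 2
        assert summarize_by_variant(tab, "volume_nihssa_nihss7").loc[1, "n"] == 3

    def test_unknown_mode(self):
        with pytest.raises(KeyError):
            summarize_by_variant(table_of([make_row()]), "banana")


class TestErrorReductionRatio:
    def test_identity_ratio(self):
        tab = table_of([make_row(predicted=4.0, actual=3.0)])
        assert error_reduction_ratio(tab, "all", "all") == 1.0

    def test_half_ratio(self):
        tab = table_of([
            make_row(case_id="c0", predicted=4.0, actual=3.0),              # baseline 1.0
            make_row(case_id="c0", vol=(0.0, 8.0), predicted=3.5, actual=3.0,
                     na=(0, 5), n7=(0, 5)),                                  # 0.5
        ])
        ratio = error_reduction_ratio(tab, "volume_nihssa_nihss7", "all")
        # constrained pool = both rows (mean 0.75) over baseline 1.0
        assert ratio == pytest.approx(0.75)

    def test_zero_baseline_raises(self):
        tab = table_of([make_row(predicted=3.0, actual=3.0)])
        with pytest.raises(ZeroDivisionError):
            error_reduction_ratio(tab, "all", "all")


class TestBestSelectionVariables:
    def test_dominating_spec_wins(self):
        good = dict(vol=(0.0, 8.0), na=(0, 5), n7=(0, 5))
        rows = [make_row(case_id=f"c{i}", predicted=3.0, actual=3.0, **good)
                for i in range(4)]
        rows += [make_row(case_id=f"d{i}", predicted=5.0, actual=3.0)
                 for i in range(4)]
        spec, mean, sd = best_selection_variables(table_of(rows), 3.0)
        assert spec == SelectionSpec(
            volume_range=(0.0, 8.0), nihssa_range=(0, 5), nihss7_range=(0, 5)
        )
        assert mean == 0.0 and sd == 0.0

    def test_hand_counted_quartile_membership(self):
        # 8 rows, errors 0..7 -> q25 = 1.75, first-quartile rows = errors {0, 1}
        specs = [dict(vol=(0.0, 8.0))] * 2 + [dict(na=(0, 5))] * 6
        rows = [
            make_row(case_id=f"c{i}", predicted=3.0 + i, actual=3.0, **specs[i])
            for i in range(8)
        ]
        spec, _, _ = best_selection_variables(table_of(rows), 3.0)
        assert spec.volume_range == (0.0, 8.0)

    def test_tie_breaks_toward_wider_range(self):
        rows = [
            make_row(case_id="c0", vol=(0.0, 8.0), predicted=3.0, actual=3.0),
            make_row(case_id="c1", vol=(0.0, INF), predicted=3.0, actual=3.0),
            make_row(case_id="c2", vol=(0.0, 8.0), predicted=4.0, actual=3.0),
            make_row(case_id="c3", vol=(0.0, INF), predicted=4.0, actual=3.0),
        ]
        spec, _, _ = best_selection_variables(table_of(rows), 3.0)
        assert spec.volume_range == (0.0, INF)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            best_selection_variables(table_of([make_row()] * 3), 3.0)


class TestCompareVariants:
    def _tab(self, errors_by_weight):
        rows = []
        for k, errs in errors_by_weight.items():
            for i, e in enumerate(errs):
                rows.append(
                    make_row(case_id=f"c{k}_{i}", weight_id=k,
                             predicted=3.0 + e, actual=3.0)
                )
        return table_of(rows)

    def test_identical_samples_p_one(self):
        p = compare_variants(self._tab({1: [1, 2, 3], 2: [1, 2, 3]}))
        assert p.loc[1, 2] == pytest.approx(1.0)
        assert p.loc[1, 1] == 1.0

    def test_complete_separation_p_zero(self):
        p = compare_variants(self._tab({1: [0, 0, 0, 0], 2: [1, 1, 1, 1]}))
        assert p.loc[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_equal_constants(self):
        p = compare_variants(self._tab({1: [1, 1], 2: [1, 1]}))
        assert p.loc[1, 2] == 1.0

    def test_symmetry(self):
        p = compare_variants(
            self._tab({1: [0.1, 0.4, 0.9], 2: [0.2, 0.3, 1.4], 3: [0.5, 0.6, 0.7]})
        )
        assert np.allclose(p.values, p.values.T)

    def test_requires_two_errors_per_variant(self):
        with pytest.raises(ValueError):
            compare_variants(self._tab({1: [1.0], 2: [1.0, 2.0]}))


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestDichotomizedAuc:
    def test_perfect_separation(self):
        res = dichotomized_auc([0.1, 0.2, 5.0, 6.0], [0, 1, 5, 6], "mrs_0_2")
        assert res.auc == 1.0

    def test_constant_score_is_half(self):
        res = dichotomized_auc([3.0] * 6, [0, 1, 2, 4, 5, 6], "mrs_0_2")
        assert res.auc == 0.5

    def test_known_small_instance(self):
        # labels via mrs_0_2: actual {2,4,2,4} -> neg, pos, neg, pos
        res = dichotomized_auc([0.2, 0.4, 0.6, 0.8], [2, 4, 2, 4], "mrs_0_2")
        assert res.auc == pytest.approx(0.75)

    def test_bi_scheme_orientation(self):
        # lower predicted BI must score as more unfavourable
        res = dichotomized_auc([20.0, 30.0, 80.0, 90.0], [10, 40, 80, 95], "bi_0_45")
        assert res.auc == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            dichotomized_auc([1.0, 2.0], [0, 1], "mrs_0_2")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pairwise_concordance_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        actual = rng.integers(0, 7, size=n)
        if (actual >= 3).all() or (actual < 3).all():
            actual[0], actual[-1] = 0, 6
        predicted = np.round(rng.uniform(0, 6, size=n), 1)
        res = dichotomized_auc(predicted, actual, "mrs_0_2", method="delong")
        assert res.auc == pytest.approx(
            brute_force_auc(predicted, actual >= 3), abs=1e-12
        )

    def test_bootstrap_ci_reproducible_and_ordered(self):
        rng = np.random.default_rng(3)
        actual = rng.integers(0, 7, size=40)
        predicted = actual + rng.normal(0, 1.5, size=40)
        a = dichotomized_auc(predicted, actual, "mrs_0_2", seed=11)
        b = dichotomized_auc(predicted, actual, "mrs_0_2", seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high

    def test_unknown_scheme(self):
        with pytest.raises(KeyError):
            dichotomized_auc([1.0], [1.0], "nope")
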