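"""Calibration curves, summary-statistic ANOVA, Duncan letters, grouping."""

import numpy as np
import pytest
from scipy import stats

from trflp.chemistry import (
    CalibrationCurve,
    anova_oneway,
    chem_groups,
    chem_letters,
    duncan_critical_range,
    duncan_letters,
    fit_calibration,
    fold_excess,
    group_by_letters,
    invert_calibration,
)


class TestCalibration:
    def test_exact_line_recovered(self):
        amounts = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        points = [(x, 10.264 * x + 70.082) for x in amounts]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(10.264)
        assert curve.intercept == pytest.approx(70.082)
        assert curve.r_squared == pytest.approx(1.0)

    def test_horizontal_data_not_invertible(self):
        curve = fit_calibration([(0, 5.0), (1, 5.0), (2, 5.0)])
        assert curve.slope == pytest.approx(0.0)
        assert not curve.invertible
        with pytest.raises(ValueError, match="zero slope"):
            invert_calibration(curve, 5.0)

    def test_noisy_line_matches_closed_form_ols(self, rng):
        x = np.linspace(0, 5, 12)
        y = 3.1 * x + 0.7 + rng.normal(0, 0.2, x.size)
        curve = fit_calibration(list(zip(x, y)))
        xc = x - x.mean()
        slope = float((xc * (y - y.mean())).sum() / (xc**2).sum())
        intercept = float(y.mean() - slope * x.mean())
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_inversion_identities(self):
        curve = CalibrationCurve(10.264, 70.082, 0.9994)
        assert invert_calibration(curve, 70.082) == pytest.approx(0.0)
        assert invert_calibration(curve, 70.082 + 10.264) == pytest.approx(1.0)
        for amount in (0.3, 1.7, 12.0):
            assert invert_calibration(curve, curve.predict(amount)) == pytest.approx(amount, abs=1e-12)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1, 2), (2, 3)])
        with pytest.raises(ValueError, match="amounts equal"):
            fit_calibration([(1, 2), (1, 3), (1, 4)])


class TestAnovaOneway:
    def test_identical_groups_give_zero_f(self):
        result = anova_oneway([5.0, 5.0], [1.0, 1.0], [3, 3])
        assert result.f == pytest.approx(0.0)

    def test_agrees_with_raw_data_anova(self, rng):
        groups = []
        for _ in range(4):
            raw = rng.normal(rng.uniform(0, 10), rng.uniform(0.5, 2), size=6)
            groups.append(raw)
        result = anova_oneway(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups], [6] * 4
        )
        expected = stats.f_oneway(*groups)
        assert result.f == pytest.approx(expected.statistic, abs=1e-9)
        assert result.p_value == pytest.approx(expected.pvalue, abs=1e-9)

    def test_hand_computed_three_group_case(self):
        # groups: n=3 each, means 2, 4, 9; sds 1, 1, 2
        # SSB = 3[(2-5)^2+(4-5)^2+(9-5)^2] = 78; SSW = 2(1+1+4) = 12
        # F = (78/2)/(12/6) = 19.5
        result = anova_oneway([2, 4, 9], [1, 1, 2], [3, 3, 3])
        assert result.f == pytest.approx(19.5)
        assert (result.df_between, result.df_within) == (2, 6)

    def test_zero_variance_flags(self):
        degenerate = anova_oneway([5.0, 5.0], [0.0, 0.0], [3, 3])
        assert degenerate.degenerate
        separated = anova_oneway([1.0, 2.0], [0.0, 0.0], [3, 3])
        assert np.isinf(separated.f) and separated.p_value == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0], [0.1], [3])
        with pytest.raises(ValueError):
            anova_oneway([1, 2], [0.1, 0.1], [1, 3])


class TestDuncanLetters:
    def test_well_separated_means_all_distinct(self):
        display = duncan_letters(["a", "b", "c"], [0.0, 10.0, 20.0], [1, 1, 1], [3, 3, 3])
        assert display.n_classes() == 3
        # oracle: every pairwise range exceeds its critical range
        se = np.sqrt(1.0 / 3)
        for span, diff in [(2, 10.0), (3, 20.0)]:
            assert diff > duncan_critical_range(span, 6, se)

    def test_identical_groups_share_one_letter(self):
        display = duncan_letters(list("abcd"), [5.0] * 4, [1.0] * 4, [3] * 4)
        assert display.n_classes() == 1

    def test_critical_range_monotone_in_span(self):
        ranges = [duncan_critical_range(p, 24, 0.3) for p in range(2, 13)]
        assert all(r2 >= r1 for r1, r2 in zip(ranges, ranges[1:]))

    def test_letters_contiguous_over_sorted_means(self, rng):
        means = rng.uniform(0, 10, 8)
        display = duncan_letters([f"s{i}" for i in range(8)], means, [0.8] * 8, [3] * 8)
        order = np.argsort(means, kind="stable")
        letters_in_order = [display.letters[f"s{i}"] for i in order]
        for letter in set("".join(letters_in_order)):
            positions = [i for i, ls in enumerate(letters_in_order) if letter in ls]
            assert positions == list(range(positions[0], positions[-1] + 1))

    def test_shift_invariance(self, rng):
        means = rng.uniform(0, 10, 6)
        base = duncan_letters([f"s{i}" for i in range(6)], means, [0.5] * 6, [3] * 6)
        shifted = duncan_letters([f"s{i}" for i in range(6)], means + 100.0, [0.5] * 6, [3] * 6)
        assert base.letters == shifted.letters

    def test_zero_error_contract(self):
        display = duncan_letters(["a", "b", "c"], [1.0, 1.0, 2.0], [0.0] * 3, [3] * 3)
        assert display.letters["a"] == display.letters["b"] != display.letters["c"]

    def test_all_pairs_against_critical_range_oracle(self, rng):
        labels = [f"s{i}" for i in range(6)]
        means = np.sort(rng.uniform(0, 5, 6))
        sds = rng.uniform(0.3, 1.0, 6)
        display = duncan_letters(labels, means, sds, [4] * 6)
        anova = anova_oneway(means, sds, [4] * 6)
        se = np.sqrt(anova.ms_within / 4)
        # a pair sharing a letter must lie inside SOME non-significant stretch,
        # i.e. the stretch spanning them passes its critical-range test
        for i in range(6):
            for j in range(i + 1, 6):
                shared = set(display.letters[labels[i]]) & set(display.letters[labels[j]])
                if shared:
                    covered = any(
                        means[j2] - means[i2] <= duncan_critical_range(j2 - i2 + 1, anova.df_within, se)
                        for i2 in range(0, i + 1)
                        for j2 in range(j, 6)
                    )
                    assert covered


class TestGroupByLetters:
    def test_four_classes_get_content_labels(self, chem_table):
        groups = chem_groups(chem_table, "volatile_oil")
        assert set(groups.group_order) == {"High", "Sub-high", "Intermediate", "Low"}
        assert groups.groups["LT-4-RZ"] == "High"

    def test_single_class_single_group(self):
        display = duncan_letters(["a", "b"], [5.0, 5.0], [1.0, 1.0], [3, 3])
        groups = group_by_letters(display, {"a": 5.0, "b": 5.0})
        assert groups.group_order == ("G1",)

    def test_planted_groups_recovered_in_most_seeds(self):
        # Monte-Carlo at the planted-group level: one summary per content
        # group, well separated means -> the 4 classes come back reliably
        from trflp.simulate import GROUP_CHEMISTRY, simulate_chemistry

        design = {g: g for g in GROUP_CHEMISTRY}
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            table = simulate_chemistry(GROUP_CHEMISTRY, design, 3, seed)
            assignment = chem_groups(table, "galangin")
            if len(assignment.group_order) == 4 and all(
                assignment.groups[g] == g for g in GROUP_CHEMISTRY
            ):
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_sample_level_recovery_matches_protection_level_theory(self):
        # with 12 samples (true-null within-group differences), Duncan's
        # protected levels alpha_p = 1 - 0.95^(p-1) fix the chance of a
        # spurious split inside a size-p group at ~alpha_p, independent of
        # the noise scale; exact recovery of groups sized (5, 3, 3, 1) is
        # therefore expected in ~0.95^(4+2+2) = 66% of seeds, not more
        from trflp.simulate import GROUP_CHEMISTRY, SAMPLE_GROUPS, simulate_chemistry

        n_seeds = 50
        hits = sum(
            chem_groups(
                simulate_chemistry(GROUP_CHEMISTRY, SAMPLE_GROUPS, 3, seed), "galangin"
            ).groups
            == SAMPLE_GROUPS
            for seed in range(n_seeds)
        )
        expected = 0.95**8
        sigma = np.sqrt(expected * (1 - expected) / n_seeds)
        assert abs(hits / n_seeds - expected) < 3 * sigma


class TestFoldExcess:
    def test_reference_table_values(self, chem_table):
        assert fold_excess("LT-4-RZ", chem_table, "volatile_oil") == (0.40, 3.92)
        assert fold_excess("LT-4-RZ", chem_table, "galangin") == (0.30, 2.29)

    def test_equal_means_give_zero(self, chem_table):
        table = chem_table.copy()
        table["mean"] = 5.0
        assert fold_excess("LT-4-RZ", table, "galangin") == (0.0, 0.0)

    def test_scale_invariance(self, chem_table):
        table = chem_table.copy()
        table["mean"] *= 7.3
        assert fold_excess("LT-4-RZ", table, "galangin") == (0.30, 2.29)

    def test_errors(self, chem_table):
        with pytest.raises(KeyError):
            fold_excess("NOPE", chem_table, "galangin")
        with pytest.raises(KeyError):
            fold_excess("LT-4-RZ", chem_table, "caffeine")
        bad = chem_table.copy()
        bad.loc[bad["sample_id"] == "HA-RZ", "mean"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fold_excess("LT-4-RZ", bad, "galangin")


def test_chem_letters_unknown_analyte(chem_table):
    with pytest.raises(KeyError):
        chem_letters(chem_table, "caffeine")
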