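"""Growth-rate statistics, agreement metrics, and mixed models."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gaber import ber, stats, workflow
from gaber.geometry import morphometrics
from gaber.stats import (
    dice,
    eccentricity_lmm,
    friedman_test,
    icc_two_way_single,
    perimeter_adjusted_growth_rate,
    univariable_lmm,
)


class TestPerimeterAdjustedRate:
    def test_concentric_circles_analytic(self):
        # r 1.0 -> 1.2 mm: dA = 0.44*pi, mean P = 2.2*pi -> 0.2 mm/y
        value = perimeter_adjusted_growth_rate(
            math.pi, 1.44 * math.pi, 2 * math.pi, 2.4 * math.pi, 1.0
        )
        assert value == pytest.approx(0.2)

    def test_no_area_change_gives_zero(self):
        assert perimeter_adjusted_growth_rate(2.0, 2.0, 5.0, 6.0, 1.0) == 0.0

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ValueError, match="perimeter"):
            perimeter_adjusted_growth_rate(0.0, 1.0, 0.0, 0.0, 1.0)

    def test_agrees_with_eye_ber_for_uniform_circular_growth(
        self, concentric_disk_pair
    ):
        eye = ber.measure_pair(concentric_disk_pair)
        m0 = morphometrics(concentric_disk_pair.baseline)
        m1 = morphometrics(concentric_disk_pair.followup)
        pagr = perimeter_adjusted_growth_rate(
            m0.area_mm2, m1.area_mm2, m0.perimeter_mm, m1.perimeter_mm, 1.0
        )
        assert pagr == pytest.approx(eye.eye_specific_ber_mm_per_yr, abs=0.01)


class TestDice:
    def test_identical_masks(self, rng):
        mask = rng.random((40, 40)) < 0.3
        assert dice(mask, mask) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:3], b[5:] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlapping_equal_squares(self):
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[:, 0:10] = True
        b[:, 5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_perfect_agreement(self):
        assert dice(np.zeros((5, 5), bool), np.zeros((5, 5), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((5, 5), bool), np.zeros((6, 5), bool))


class TestICC:
    def test_identical_raters_give_one(self, rng):
        a = rng.normal(size=30)
        assert icc_two_way_single(np.column_stack([a, a])) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=(200, 2))
        assert abs(icc_two_way_single(x)) < 0.15

    def test_constant_offset_penalized(self, rng):
        a = rng.normal(size=40)
        x = np.column_stack([a, a + 1.0])
        value = icc_two_way_single(x)
        assert value < 1.0
        # consistency would be perfect; absolute agreement is not
        assert value < np.corrcoef(x[:, 0], x[:, 1])[0, 1]

    def test_matches_independent_anova_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1))
        table = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 3),
                "rater": np.tile(np.arange(3), 25),
                "score": x.ravel(),
            }
        )
        reference = pingouin.intraclass_corr(
            table, targets="subject", raters="rater", ratings="score"
        )
        by_type = reference.set_index("Type")["ICC"]
        icc2 = by_type.get("ICC2", by_type.get("ICC(A,1)"))
        assert icc_two_way_single(x) == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_two_way_single(np.ones((10, 2)))


class TestFriedman:
    def test_identical_columns_carry_no_signal(self):
        m = np.tile([[1.0], [2.0], [3.0]], (1, 4))
        assert friedman_test(m) == (0.0, 1.0)

    def test_perfectly_consistent_ranking(self):
        # 3 blocks x 3 treatments, same order in every block:
        # chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1) = 6.0
        m = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [2.0, 3.0, 4.0]])
        statistic, p = friedman_test(m)
        assert statistic == pytest.approx(6.0)
        assert 0 < p < 0.06

    def test_block_permutation_invariance(self, rng):
        m = rng.normal(size=(8, 4))
        s1, _ = friedman_test(m)
        s2, _ = friedman_test(m[rng.permutation(8)])
        assert s1 == pytest.approx(s2)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            friedman_test(m)


def _tabular_cohort(rng, n_patients=40, slope=0.0, patient_sd=0.1, noise=0.1):
    rows = []
    for p in range(n_patients):
        offset = rng.normal(0, patient_sd)
        for e in range(rng.integers(1, 3)):
            x = rng.normal()
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "eye_id": f"P{p}-{e}",
                    "x": x,
                    "y": 1.0 + slope * x + offset + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestUnivariableLMM:
    def test_outcome_equal_to_predictor_recovers_slope_one(self, rng):
        table = _tabular_cohort(rng)
        table["y"] = table["x"] + rng.normal(0, 1e-3, len(table))
        result = univariable_lmm(table, "y", "x")
        term = result.term("x")
        assert term["estimate"] == pytest.approx(1.0, abs=1e-3)
        assert term["p"] < 1e-10

    def test_degenerates_to_ols_with_one_eye_per_patient(self, rng):
        # No replication within patients and no patient variance: the
        # mixed model must agree with ordinary least squares.
        n = 60
        x = rng.normal(size=n)
        y = 0.5 + 0.3 * x + rng.normal(0, 0.2, size=n)
        table = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "x": x, "y": y}
        )
        lmm = univariable_lmm(table, "y", "x").term("x")["estimate"]
        ols = sm.OLS(y, sm.add_constant(x)).fit().params[1]
        assert lmm == pytest.approx(ols, abs=1e-6)

    def test_null_slope_ci_covers_zero_in_most_replicates(self):
        rng = np.random.default_rng(11)
        covered = 0
        n_reps = 60
        for _ in range(n_reps):
            table = _tabular_cohort(rng, n_patients=30)
            term = univariable_lmm(table, "y", "x").term("x")
            covered += term["ci_low"] <= 0.0 <= term["ci_high"]
        assert covered >= 0.90 * n_reps

    def test_unknown_columns_rejected(self, rng):
        table = _tabular_cohort(rng, n_patients=4)
        with pytest.raises(ValueError):
            univariable_lmm(table, "y", "nope")


class TestEccentricityLMM:
    def test_single_zone_per_eye_rejected(self):
        rows = pd.DataFrame(
            {
                "patient_id": ["P1", "P2"],
                "eye_id": ["P1-OD", "P2-OD"],
                "eccentricity_mm": [0.75, 0.75],
                "mean_ber_mm_per_yr": [0.1, 0.12],
                "baseline_area_mm2": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="eccentricity"):
            eccentricity_lmm(rows)

    def test_recovers_slope_on_tabular_zone_data(self, rng):
        rows = []
        for p in range(30):
            patient_off = rng.normal(0, 0.02)
            for e in range(2):
                eye_off = rng.normal(0, 0.01)
                for zone, ecc in enumerate([0.25, 0.75, 1.25, 1.75]):
                    rows.append(
                        {
                            "patient_id": f"P{p}",
                            "eye_id": f"P{p}-{e}",
                            "eccentricity_mm": ecc,
                            "mean_ber_mm_per_yr": 0.10 + 0.04 * ecc
                            + patient_off + eye_off + rng.normal(0, 0.005),
                            "baseline_area_mm2": 1.0 + p % 3,
                        }
                    )
        result = eccentricity_lmm(pd.DataFrame(rows))
        term = result.term("eccentricity_mm")
        assert term["estimate"] == pytest.approx(0.04, abs=0.005)
        assert term["ci_low"] <= 0.04 <= term["ci_high"]


def test_table_one_layout(rng):
    table = _tabular_cohort(rng, n_patients=25)
    table = table.rename(columns={"x": "baseline_area_mm2"})
    table["eye_ber_mm_per_yr"] = table["y"]
    table["area_growth_rate_mm2_per_yr"] = table["y"] * 2
    table["baseline_perimeter_mm"] = rng.normal(size=len(table))
    table["baseline_lesion_count"] = 1
    table["baseline_circularity"] = rng.uniform(0.3, 1.0, len(table))
    table["baseline_multifocal"] = 0
    table["fellow_eye_ga"] = np.nan
    table["border_fovea_dist_mm"] = rng.uniform(0.5, 2.0, len(table))
    result = stats.table_one(table)
    assert set(result["outcome"]) == set(stats.COHORT_OUTCOMES)
    assert {"estimate", "ci_low", "ci_high", "p"} <= set(result.columns)
    # constant predictors (lesion count) are skipped or fit; either way
    # every reported row must have a CI bracketing its estimate
    assert (result["ci_low"] <= result["estimate"]).all()
    assert (result["estimate"] <= result["ci_high"]).all()
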