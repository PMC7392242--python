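"""Outlier flagging, valence split, within-individual z-scoring and the
descriptive fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odornet.exceptions import ClassificationError, ValidationError
from odornet.preprocessing import (
    fit_quadratic_va,
    flag_outlier_participants,
    intensity_homogeneity,
    split_by_valence,
    standardize_within_individual,
)
from odornet.synthetic import inject_outlier


def _profiles_ratings(odor_profiles):
    """Table of one 'participant' per odor profile row (single-row ratings)."""
    return pd.DataFrame({
        "participant_id": 1,
        "odor_id": [p.odor_id for p in odor_profiles],
        "valence": [p.valence_mean for p in odor_profiles],
        "arousal": [p.arousal_mean for p in odor_profiles],
        "intensity": [p.intensity_mean for p in odor_profiles],
        "familiarity": [p.familiarity_mean for p in odor_profiles],
    })


class TestOutlierFlagging:
    def test_single_extreme_intensity_flagged(self, tiny_ratings):
        # 9 participants at 50, one at 0: z = (0 - 45) / 15.81 = -2.85
        report = flag_outlier_participants(tiny_ratings, z_threshold=2.0)
        assert report.flagged == (7,)
        row = report.evidence.iloc[0]
        assert row["variable"] == "intensity"
        assert row["z"] == pytest.approx(-2.846, abs=0.001)

    def test_identical_ratings_no_flags(self, tiny_ratings):
        flat = tiny_ratings.copy()
        flat["intensity"] = 50.0
        report = flag_outlier_participants(flat)
        assert report.flagged == ()

    def test_infinite_threshold_flags_nothing(self, tiny_ratings):
        report = flag_outlier_participants(tiny_ratings, z_threshold=np.inf)
        assert report.flagged == ()

    def test_injected_outlier_detected(self, small_study):
        ratings, _ = small_study
        spiked = inject_outlier(ratings, 3, 5, "valence", -3.0)
        report = flag_outlier_participants(spiked, z_threshold=2.0)
        assert 3 in report.flagged
        hits = report.evidence.query("participant_id == 3 and odor_id == 5")
        assert (hits["variable"] == "valence").any()

    def test_too_few_participants_per_odor(self):
        df = pd.DataFrame({"participant_id": [1, 2], "odor_id": [1, 1],
                           "valence": [0.0, 1.0], "arousal": [0.0, 0.0],
                           "intensity": [50.0, 50.0], "familiarity": [50.0, 50.0]})
        with pytest.raises(ValidationError):
            flag_outlier_participants(df)


class TestSplitByValence:
    def test_reference_profiles_split_16_24(self, odor_profiles):
        unpleasant, pleasant = split_by_valence(_profiles_ratings(odor_profiles))
        assert len(unpleasant) == 16
        assert len(pleasant) == 24
        assert unpleasant == [4, 7, 11, 12, 14, 15, 19, 21, 26, 27, 28, 35,
                              37, 38, 39, 40]

    def test_single_positive_odor(self):
        df = pd.DataFrame({"participant_id": [1, 2, 3], "odor_id": 1,
                           "valence": 1.0, "arousal": 0.0,
                           "intensity": 50.0, "familiarity": 50.0})
        unpleasant, pleasant = split_by_valence(df)
        assert unpleasant == [] and pleasant == [1]

    def test_exact_zero_mean_rejected(self):
        df = pd.DataFrame({"participant_id": [1, 2], "odor_id": 1,
                           "valence": [1.0, -1.0], "arousal": 0.0,
                           "intensity": 50.0, "familiarity": 50.0})
        with pytest.raises(ClassificationError):
            split_by_valence(df)

    def test_partition_complete_and_idempotent(self, small_study):
        ratings, _ = small_study
        u1, p1 = split_by_valence(ratings)
        u2, p2 = split_by_valence(ratings)
        assert (u1, p1) == (u2, p2)
        assert set(u1) | set(p1) == set(ratings["odor_id"].unique())
        assert set(u1) & set(p1) == set()


class TestStandardization:
    def _mini(self):
        ratings = pd.DataFrame({
            "participant_id": [1, 1, 1, 2, 2, 2],
            "odor_id": [1, 2, 3] * 2,
            "valence": [1.0, 2.0, 3.0, 2.0, 2.0, 2.0],
            "arousal": [0.0, 1.0, -1.0, 0.5, 0.0, -0.5],
            "intensity": [10.0, 20.0, 30.0, 50.0, 50.0, 50.0],
            "familiarity": [40.0, 50.0, 60.0, 10.0, 30.0, 50.0],
        })
        participants = pd.DataFrame({
            "participant_id": [1, 2], "baseline_valence": [0.5, -0.5],
            "baseline_arousal": [1.0, 0.0], "threshold": [8.0, 10.0]})
        return ratings, participants

    def test_three_scores_standardize_to_unit_steps(self):
        ratings, participants = self._mini()
        sm = standardize_within_individual(ratings, participants, [1, 2, 3], "set")
        v1 = sm.data.loc[sm.meta["participant_id"] == 1, "V"].to_numpy()
        assert v1 == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_scores_become_zero(self):
        ratings, participants = self._mini()
        sm = standardize_within_individual(ratings, participants, [1, 2, 3], "set")
        v2 = sm.data.loc[sm.meta["participant_id"] == 2, "V"].to_numpy()
        assert np.all(v2 == 0.0)

    def test_participant_columns_pass_through(self):
        ratings, participants = self._mini()
        sm = standardize_within_individual(ratings, participants, [1, 2, 3], "set")
        bv = sm.data.loc[sm.meta["participant_id"] == 1, "BV"]
        assert np.all(bv == 0.5)

    def test_per_participant_mean_zero_audit(self, small_study):
        ratings, participants = small_study
        ids = sorted(ratings["odor_id"].unique())[:10]
        sm = standardize_within_individual(ratings, participants, ids, "audit")
        for col in ("V", "A", "I", "F"):
            means = sm.data.groupby(sm.meta["participant_id"])[col].mean()
            assert np.abs(means).max() < 1e-12
            sds = sm.data.groupby(sm.meta["participant_id"])[col].std(ddof=1)
            assert np.abs(sds - 1.0).max() < 1e-12

    def test_row_order_invariance(self, small_study):
        ratings, participants = small_study
        ids = sorted(ratings["odor_id"].unique())[:6]
        sm1 = standardize_within_individual(ratings, participants, ids, "s")
        shuffled = ratings.sample(frac=1.0, random_state=0).reset_index(drop=True)
        sm2 = standardize_within_individual(shuffled, participants, ids, "s")
        pd.testing.assert_frame_equal(sm1.data, sm2.data)

    def test_single_row_participant_excluded(self):
        ratings, participants = self._mini()
        ratings = pd.concat([ratings, pd.DataFrame([{
            "participant_id": 3, "odor_id": 1, "valence": 0.0, "arousal": 0.0,
            "intensity": 50.0, "familiarity": 50.0}])], ignore_index=True)
        participants = pd.concat([participants, pd.DataFrame([{
            "participant_id": 3, "baseline_valence": 0.0,
            "baseline_arousal": 0.0, "threshold": 8.0}])], ignore_index=True)
        sm = standardize_within_individual(ratings, participants, [1, 2], "s")
        assert set(sm.meta["participant_id"]) == {1, 2}  # participant 3 dropped


class TestQuadraticFit:
    def test_exact_parabola(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        fit = fit_quadratic_va(x, x**2)
        assert fit.beta2 == pytest.approx(1.0, abs=1e-10)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_points_interpolated_exactly(self):
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([2.0, -1.0, 4.0])
        fit = fit_quadratic_va(x, y)
        assert fit.predict(x) == pytest.approx(y, abs=1e-9)

    def test_reference_means_r_squared(self, odor_profiles):
        fit = fit_quadratic_va([p.valence_mean for p in odor_profiles],
                               [p.arousal_mean for p in odor_profiles])
        assert fit.r_squared == pytest.approx(0.59, abs=0.01)

    def test_too_few_distinct_points(self):
        with pytest.raises(ValidationError):
            fit_quadratic_va([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_r_squared_invariant_to_affine_predictor_rescale(self, scale, shift):
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, size=20)
        y = 0.3 * x**2 - 0.5 * x + rng.normal(0, 0.3, size=20)
        r2a = fit_quadratic_va(x, y).r_squared
        r2b = fit_quadratic_va(scale * x + shift, y).r_squared
        assert r2a == pytest.approx(r2b, abs=1e-7)


class TestIntensityHomogeneity:
    def test_reference_profiles(self, odor_profiles):
        value = intensity_homogeneity([p.intensity_mean for p in odor_profiles])
        assert value == pytest.approx(28.0, abs=1.0)

    def test_equal_intensities(self):
        assert intensity_homogeneity([50.0, 50.0, 50.0]) == 0.0

    def test_hand_computed(self):
        assert intensity_homogeneity([40.0, 60.0, 80.0]) == pytest.approx(33.3333, abs=1e-3)

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValidationError):
            intensity_homogeneity([1.0, -1.0])
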