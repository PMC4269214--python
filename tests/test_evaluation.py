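"""LODO / LOPO protocols and the study harness."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stresspipe.config import PipelineConfig
from stresspipe.evaluation import (
    leave_one_day_out_cv,
    leave_one_participant_out_cv,
    run_study,
)
from stresspipe.model import StressLogit
from stresspipe.scores import map_score_to_class
from stresspipe.synth import CohortSpec, EffectSpec, generate_cohort
from stresspipe.types import ValidationError

FEATS = ["sleep_duration_h", "mean_rr_ms", "n_calls", "audio_length_s"]


def _latent_cohort(n_users=4, n_days=20, seed=3, effect=None):
    spec = CohortSpec(n_users=n_users, n_days=n_days, seed=seed,
                      effect=effect or EffectSpec())
    df, truth = generate_cohort(spec, features_only=True)
    df = df.copy()
    df["stress_class"] = [map_score_to_class(s) for s in df["stress_score"]]
    return df, truth


class TestLODO:
    def test_degenerate_single_class_user(self):
        df = pd.DataFrame(
            {"f": np.linspace(0, 1, 6), "stress_class": [1] * 6}
        )
        cv = leave_one_day_out_cv(df, ["f"])
        assert cv.accuracy == 1.0

    def test_fold_count_equals_days(self):
        df = pd.DataFrame({"f": np.arange(5.0), "stress_class": [0, 1, 2, 1, 0]})
        cv = leave_one_day_out_cv(df, ["f"])
        assert cv.n_folds == 5
        assert len(cv.per_fold_outcomes) == 5

    def test_strong_signal_user_beats_chance(self):
        df, _ = _latent_cohort(n_users=1, n_days=20, seed=11)
        cv = leave_one_day_out_cv(df, FEATS)
        assert cv.accuracy > 0.6

    def test_too_few_days(self):
        df = pd.DataFrame({"f": [1.0, 2.0], "stress_class": [0, 1]})
        with pytest.raises(ValidationError):
            leave_one_day_out_cv(df, ["f"])

    def test_no_leakage_training_model_identical_without_held_out_row(self):
        df, _ = _latent_cohort(n_users=1, n_days=12, seed=2)
        X = df[FEATS].to_numpy()
        y = df["stress_class"].to_numpy()
        mask = np.ones(len(df), bool)
        mask[4] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = StressLogit(y[mask], X[mask], feature_names=FEATS).fit()
            again = StressLogit(y[mask], X[mask], feature_names=FEATS).fit()
        assert np.array_equal(direct.coef, again.coef)


class TestLOPO:
    def test_one_fold_per_user(self):
        df, _ = _latent_cohort(n_users=5, n_days=8, seed=4)
        cv = leave_one_participant_out_cv(df, FEATS)
        assert cv.n_folds == 5

    def test_shared_structure_above_chance(self):
        df, _ = _latent_cohort(n_users=6, n_days=15, seed=8)
        cv = leave_one_participant_out_cv(df, FEATS)
        prior = df["stress_class"].value_counts(normalize=True).max()
        assert cv.accuracy > prior

    def test_requires_three_users(self):
        df, _ = _latent_cohort(n_users=2, n_days=8, seed=4)
        with pytest.raises(ValidationError):
            leave_one_participant_out_cv(df, FEATS)

    def test_user_specific_opposite_effects_hurt_lopo(self, rng):
        # users whose feature-class association flips sign cannot share a model
        rows = []
        for u in range(4):
            sign = 1.0 if u % 2 == 0 else -1.0
            x = rng.standard_normal(20)
            eta = np.column_stack([np.zeros(20), 3 * sign * x, 6 * sign * x - 2])
            p = np.exp(eta - eta.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            y = [rng.choice(3, p=row) for row in p]
            rows.append(pd.DataFrame({"subject_id": f"u{u}", "f": x, "stress_class": y}))
        df = pd.concat(rows, ignore_index=True)
        lopo = leave_one_participant_out_cv(df, ["f"])
        lodo = np.mean(
            [
                leave_one_day_out_cv(df[df.subject_id == u], ["f"]).accuracy
                for u in df.subject_id.unique()
            ]
        )
        assert lopo.accuracy <= lodo


class TestRunStudy:
    @pytest.fixture(scope="class")
    @staticmethod
    def study():
        df, _ = _latent_cohort(n_users=4, n_days=14, seed=9)
        # latent table only carries the 4 driving features; pad the remaining
        # batteries with uninformative columns so the harness sees both kinds
        rng = np.random.default_rng(0)
        df = df.rename(columns={})
        for extra in ("gps_distance_m", "speech_energy"):
            df[extra] = rng.standard_normal(len(df))
        df["lf_hf"] = rng.standard_normal(len(df))
        cfg = PipelineConfig(min_nights=10, seed=2)
        return run_study(df, cfg), df

    def test_report_contains_six_accuracies(self, study):
        report, _ = study
        assert set(report["user_specific"]) == {"M_P", "M_H", "M"}
        assert set(report["general"]) == {"M_P", "M_H", "M"}
        for tag in ("M_P", "M_H", "M"):
            assert 0.0 <= report["user_specific"][tag]["accuracy"] <= 1.0
            assert 0.0 <= report["general"][tag]["accuracy"] <= 1.0

    def test_days_without_hrv_are_excluded(self, study):
        report, df = study
        df2 = df.copy()
        hrv_cols = [c for c in df2.columns if c in ("sleep_duration_h", "mean_rr_ms", "lf_hf")]
        extra = df2.iloc[:3].copy()
        extra[hrv_cols] = np.nan
        extra["date"] = "2012-09-0" + pd.Series(["1", "2", "3"]).values
        df3 = pd.concat([df2, extra], ignore_index=True)
        report3 = run_study(df3, PipelineConfig(min_nights=10, seed=2))
        assert report3["n_days"] == report["n_days"]

    def test_rerun_identical(self, study):
        report, df = study
        again = run_study(df, PipelineConfig(min_nights=10, seed=2))
        assert again == report

    def test_no_eligible_user_warns(self):
        df, _ = _latent_cohort(n_users=3, n_days=5, seed=1)
        df["lf_hf"] = 0.0
        df["gps_distance_m"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_study(df, PipelineConfig(min_nights=10, seed=0))
        assert report["user_specific"] == {}
        assert any("user-specific" in w for w in report["warnings"])
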