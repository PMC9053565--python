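"""Screening stage: features, gain ratio, grouped CV, synthetic cohort."""

from dataclasses import replace
from math import isclose

import numpy as np
import pytest

import cogniscore as cs
from cogniscore.errors import (
    CohortIntegrityError,
    CohortSettingsError,
    FoldError,
    UndefinedRankingError,
)
from cogniscore.screening import FEATURE_NAMES, NOMINAL_FEATURES, feature_matrix

from oracles import brute_gain_ratio


def profile(uid="u1", impairment="absent", **kw):
    defaults = dict(
        age_band=2, focus=True, stress=False, studies=False, technology=True
    )
    defaults.update(kw)
    return cs.ParticipantProfile(user_id=uid, impairment=impairment, **defaults)


def five_sessions(uid="u1", q4=(0.4, 0.7, 0.1, 0.5, 0.3), length=40):
    return [
        cs.SessionRecord(
            user_id=uid,
            session_index=i + 1,
            sim_scores=(0.2, 0.2, 0.2, q4[i]),
            response_lengths=(length,) * 4,
        )
        for i in range(5)
    ]


class TestFeatureExtraction:
    def test_question4_sims_pass_through(self):
        vec = cs.extract_features(profile(), five_sessions())
        assert (
            vec.sim_s1q4,
            vec.sim_s2q4,
            vec.sim_s3q4,
            vec.sim_s4q4,
            vec.sim_s5q4,
        ) == (0.4, 0.7, 0.1, 0.5, 0.3)
        assert vec.num_chars == 40.0
        assert vec.label == "absent"

    def test_all_empty_responses(self):
        sessions = [
            cs.SessionRecord(
                user_id="u1",
                session_index=i + 1,
                sim_scores=(0.0,) * 4,
                response_lengths=(0,) * 4,
            )
            for i in range(5)
        ]
        vec = cs.extract_features(profile(), sessions)
        assert vec.num_chars == 0.0 and vec.sim_s3q4 == 0.0

    def test_sessions_for_unknown_user_rejected(self):
        with pytest.raises(CohortIntegrityError):
            cs.extract_features(profile(uid="u1"), five_sessions(uid="u2"))

    def test_mild_and_severe_collapse_to_present(self):
        for level in ("mild", "severe"):
            vec = cs.extract_features(
                profile(impairment=level), five_sessions()
            )
            assert vec.label == "present"


def hand_cohort(rows):
    """Rows of (focus, num_chars, sim1, label) -> feature vectors with
    the remaining features held constant."""
    return [
        cs.FeatureVector(
            user_id=f"u{i}",
            focus=f,
            stress=False,
            studies=False,
            technology=False,
            age=1,
            num_chars=nc,
            sim_s1q4=s1,
            sim_s2q4=0.5,
            sim_s3q4=0.5,
            sim_s4q4=0.5,
            sim_s5q4=0.5,
            label=lab,
        )
        for i, (f, nc, s1, lab) in enumerate(rows)
    ]


class TestGainRatio:
    def test_perfect_predictor_scores_one(self):
        rows = [(True, 10.0, 0.1, "present")] * 4 + [
            (False, 10.0, 0.1, "absent")
        ] * 4
        ranking = dict(cs.gain_ratio_rank(hand_cohort(rows)))
        assert isclose(ranking["focus"], 1.0)

    def test_independent_balanced_feature_scores_zero(self):
        rows = [
            (True, 10.0, 0.1, "present"),
            (False, 10.0, 0.1, "present"),
            (True, 10.0, 0.1, "absent"),
            (False, 10.0, 0.1, "absent"),
        ]
        ranking = dict(cs.gain_ratio_rank(hand_cohort(rows)))
        assert ranking["focus"] == 0.0

    def test_eight_row_table_matches_entropy_oracle(self):
        """Every feature's score equals an exhaustive entropy
        recomputation on a small mixed nominal/numeric table."""
        rows = [
            (True, 55.0, 0.45, "absent"),
            (True, 60.0, 0.40, "absent"),
            (False, 52.0, 0.38, "absent"),
            (True, 38.0, 0.30, "present"),
            (False, 35.0, 0.25, "present"),
            (False, 30.0, 0.10, "present"),
            (True, 41.0, 0.28, "present"),
            (False, 58.0, 0.33, "absent"),
        ]
        vectors = hand_cohort(rows)
        X, y, _ = feature_matrix(vectors)
        expected = {
            name: brute_gain_ratio(
                list(X[:, j]), list(y), name in NOMINAL_FEATURES
            )
            for j, name in enumerate(FEATURE_NAMES)
        }
        for name, score in cs.gain_ratio_rank(vectors):
            assert isclose(score, expected[name], abs_tol=1e-12)

    def test_ranking_is_descending(self):
        profiles, sessions = cs.simulate_cohort(n_users=40, seed=3)
        scores = [s for _, s in cs.gain_ratio_rank(cs.cohort_features(profiles, sessions))]
        assert scores == sorted(scores, reverse=True)

    def test_single_class_rejected(self):
        rows = [(True, 10.0, 0.1, "present")] * 4
        with pytest.raises(UndefinedRankingError):
            cs.gain_ratio_rank(hand_cohort(rows))


class _ColumnRule:
    """Predicts from the focus column: a perfect stub when labels are
    derived from focus."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.where(X[:, 0] > 0.5, "present", "absent")


class _MajorityStub:
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority)


class _SplitRecorder:
    """Records which user indices appear in train and test calls."""

    def __init__(self):
        self.train_ids: list[set] = []
        self.test_ids: list[set] = []

    def fit(self, X, y):
        self.train_ids.append(set(X[:, 5]))  # num_chars encodes the user
        return self

    def predict(self, X):
        self.test_ids.append(set(X[:, 5]))
        return np.full(len(X), "absent")


class TestGroupedCV:
    def _focus_cohort(self, n=20):
        rows = [
            (i % 2 == 0, float(i), 0.1, "present" if i % 2 == 0 else "absent")
            for i in range(n)
        ]
        return hand_cohort(rows)

    def test_perfect_stub_scores_100(self):
        report = cs.grouped_kfold_evaluate(self._focus_cohort(), _ColumnRule(), k=5)
        assert report.accuracy == 1.0
        for cls in ("present", "absent"):
            assert report.per_class[cls]["f_measure"] == 1.0
            assert report.per_class[cls]["recall"] == 1.0

    def test_majority_stub_on_60_40_cohort(self):
        rows = [(True, float(i), 0.1, "absent") for i in range(30)] + [
            (True, float(100 + i), 0.1, "present") for i in range(20)
        ]
        report = cs.grouped_kfold_evaluate(hand_cohort(rows), _MajorityStub(), k=5)
        assert isclose(report.accuracy, 0.6)

    def test_no_user_in_both_train_and_test(self):
        recorder = _SplitRecorder()
        cs.grouped_kfold_evaluate(self._focus_cohort(), recorder, k=5, seed=2)
        for train, test in zip(recorder.train_ids, recorder.test_ids):
            assert not train & test

    def test_confusion_totals_equal_user_count(self):
        vectors = self._focus_cohort()
        report = cs.grouped_kfold_evaluate(vectors, "dt", k=5, seed=0)
        total = sum(sum(row.values()) for row in report.confusion.values())
        assert total == report.n_evaluated == len(vectors)
        correct = sum(report.confusion[c][c] for c in report.labels)
        assert isclose(report.accuracy, correct / total)

    def test_folds_partition_users(self):
        report = cs.grouped_kfold_evaluate(self._focus_cohort(), "dt", k=5)
        assert sorted(report.fold_assignment) == sorted(f"u{i}" for i in range(20))
        assert set(report.fold_assignment.values()) == set(range(5))

    def test_too_many_folds_rejected(self):
        with pytest.raises(FoldError):
            cs.grouped_kfold_evaluate(self._focus_cohort(4), "dt", k=10)


class TestSyntheticCohort:
    def test_deterministic_per_seed(self):
        a = cs.simulate_cohort(n_users=15, seed=9)
        b = cs.simulate_cohort(n_users=15, seed=9)
        assert a == b

    def test_single_user(self):
        profiles, sessions = cs.simulate_cohort(n_users=1, seed=0)
        assert len(profiles) == 1 and len(sessions) == 5

    def test_group_means_ordered_by_impairment(self):
        profiles, sessions = cs.simulate_cohort(n_users=200, seed=1)
        by_level = {level: [] for level in ("absent", "mild", "severe")}
        level_of = {p.user_id: p.impairment for p in profiles}
        for s in sessions:
            by_level[level_of[s.user_id]].extend(s.sim_scores)
        means = {lv: np.mean(v) for lv, v in by_level.items()}
        assert means["severe"] < means["mild"] < means["absent"]

    def test_marginal_means_match_settings_within_3_se(self):
        """Per-level marginal means track the configured means.  Draws
        within a user are correlated (shared focus/stress effect), so
        the standard error is taken over per-user means."""
        settings = cs.CohortSettings()
        profiles, sessions = cs.simulate_cohort(settings, n_users=300, seed=4)
        level_of = {p.user_id: p.impairment for p in profiles}
        per_user: dict[str, list[float]] = {}
        for s in sessions:
            per_user.setdefault(s.user_id, []).extend(s.sim_scores)
        for level, (mean, _) in settings.sim_by_level.items():
            user_means = np.array(
                [np.mean(v) for u, v in per_user.items() if level_of[u] == level]
            )
            se = user_means.std(ddof=1) / np.sqrt(len(user_means))
            assert abs(user_means.mean() - mean) <= 3 * se

    def test_lengths_shrink_with_impairment(self):
        profiles, sessions = cs.simulate_cohort(n_users=200, seed=2)
        level_of = {p.user_id: p.impairment for p in profiles}
        by_level = {level: [] for level in ("absent", "mild", "severe")}
        for s in sessions:
            by_level[level_of[s.user_id]].extend(s.response_lengths)
        assert (
            np.mean(by_level["severe"])
            < np.mean(by_level["mild"])
            < np.mean(by_level["absent"])
        )

    def test_invalid_settings_rejected(self):
        bad = replace(
            cs.CohortSettings(),
            level_probs={"absent": 0.7, "mild": 0.7, "severe": -0.4},
        )
        with pytest.raises(CohortSettingsError):
            cs.simulate_cohort(bad, n_users=2, seed=0)
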