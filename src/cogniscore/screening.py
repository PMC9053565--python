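"""Cognitive-impairment screening from session-derived features.

A participant's five assessment sessions (one news dialogue each, four
questions per session) are condensed into an 11-feature vector:

====================  =========  ==========================================
feature               type       meaning
====================  =========  ==========================================
focus                 boolean    user was focused during the experiments
stress                boolean    user was stressed
studies               boolean    superior level of education
technology            boolean    basic technological skills
age                   nominal    1..4 for [60,70], (70,80], (80,90], (90,100]
num_chars             numeric    average characters per response
sim_s1q4..sim_s5q4    numeric    answer similarity of question 4, per session
====================  =========  ==========================================

The label collapses mild and severe impairment into ``present`` versus
``absent``.  Features are ranked by **gain ratio** (information gain
over split information, numeric features discretized by the supervised
midpoint split that maximizes information gain), and classifiers are
evaluated with **grouped k-fold cross-validation**: all records of one
user live in the same fold, so no user is simultaneously used for
training and evaluation.

Because real cohort data cannot be redistributed, the module ships a
synthetic cohort generator whose defaults mirror the impairment-level
conditioned score structure observed in practice (per-level answer
similarity means and spreads, shorter answers with higher impairment,
stress hurting and focus helping, and per-session difficulty shifts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log2
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .errors import (
    CohortIntegrityError,
    CohortSettingsError,
    FoldError,
    UndefinedRankingError,
)

IMPAIRMENT_LEVELS = ("absent", "mild", "severe")
LABELS = ("absent", "present")
N_SESSIONS = 5
N_QUESTIONS = 4

FEATURE_NAMES = (
    "focus",
    "stress",
    "studies",
    "technology",
    "age",
    "num_chars",
    "sim_s1q4",
    "sim_s2q4",
    "sim_s3q4",
    "sim_s4q4",
    "sim_s5q4",
)
NOMINAL_FEATURES = frozenset(
    {"focus", "stress", "studies", "technology", "age"}
)


@dataclass(frozen=True)
class ParticipantProfile:
    user_id: str
    age_band: int  # 1..4
    focus: bool
    stress: bool
    studies: bool
    technology: bool
    impairment: str  # absent | mild | severe

    def __post_init__(self) -> None:
        if self.age_band not in (1, 2, 3, 4):
            raise ValueError("age_band must be in {1, 2, 3, 4}")
        if self.impairment not in IMPAIRMENT_LEVELS:
            raise ValueError(f"invalid impairment level {self.impairment!r}")

    @property
    def label(self) -> str:
        return "absent" if self.impairment == "absent" else "present"


@dataclass(frozen=True)
class SessionRecord:
    user_id: str
    session_index: int  # 1..5
    sim_scores: tuple[float, ...]  # one per question
    response_lengths: tuple[int, ...]  # characters, one per question

    def __post_init__(self) -> None:
        if not 1 <= self.session_index <= N_SESSIONS:
            raise ValueError("session_index must be 1..5")
        if any(not 0.0 <= s <= 1.0 for s in self.sim_scores):
            raise ValueError("sim scores must lie in [0, 1]")
        if any(n < 0 for n in self.response_lengths):
            raise ValueError("response lengths are non-negative")


@dataclass(frozen=True)
class FeatureVector:
    user_id: str
    focus: bool
    stress: bool
    studies: bool
    technology: bool
    age: int
    num_chars: float
    sim_s1q4: float
    sim_s2q4: float
    sim_s3q4: float
    sim_s4q4: float
    sim_s5q4: float
    label: str  # present | absent

    def values(self) -> tuple:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def extract_features(
    profile: ParticipantProfile, sessions: Sequence[SessionRecord]
) -> FeatureVector:
    """Condense one participant's sessions into the screening features.

    ``num_chars`` averages the response length over every answered
    question in every session; the five similarity features are the
    question-4 score of each session (0 when a session is missing).
    """
    for s in sessions:
        if s.user_id != profile.user_id:
            raise CohortIntegrityError(
                f"session for user {s.user_id!r} attached to profile "
                f"{profile.user_id!r}"
            )
    lengths = [n for s in sessions for n in s.response_lengths]
    q4 = {s.session_index: s.sim_scores[N_QUESTIONS - 1] for s in sessions
          if len(s.sim_scores) >= N_QUESTIONS}
    return FeatureVector(
        user_id=profile.user_id,
        focus=profile.focus,
        stress=profile.stress,
        studies=profile.studies,
        technology=profile.technology,
        age=profile.age_band,
        num_chars=float(np.mean(lengths)) if lengths else 0.0,
        sim_s1q4=q4.get(1, 0.0),
        sim_s2q4=q4.get(2, 0.0),
        sim_s3q4=q4.get(3, 0.0),
        sim_s4q4=q4.get(4, 0.0),
        sim_s5q4=q4.get(5, 0.0),
        label=profile.label,
    )


def feature_matrix(
    vectors: Sequence[FeatureVector],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numeric design matrix, label array and user-group array."""
    X = np.array([[float(v) for v in vec.values()] for vec in vectors])
    y = np.array([vec.label for vec in vectors])
    groups = np.array([vec.user_id for vec in vectors])
    return X, y, groups


# -- gain-ratio feature ranking ------------------------------------------


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _partition_scores(y: np.ndarray, parts: list[np.ndarray]) -> tuple[float, float]:
    """(information gain, split information) of a label partition."""
    n = len(y)
    cond = sum(len(p) / n * _entropy(p) for p in parts if len(p))
    sizes = np.array([len(p) for p in parts if len(p)], dtype=float)
    w = sizes / n
    split_info = float(-(w * np.log2(w)).sum())
    return _entropy(y) - cond, split_info


def _best_numeric_partition(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Supervised binary discretization: the midpoint threshold between
    consecutive distinct values that maximizes information gain."""
    values = np.unique(x)
    if len(values) < 2:
        return [y]
    best_gain, best_parts = -1.0, [y]
    for lo, hi in zip(values[:-1], values[1:]):
        t = (lo + hi) / 2.0
        parts = [y[x <= t], y[x > t]]
        gain, _ = _partition_scores(y, parts)
        if gain > best_gain:
            best_gain, best_parts = gain, parts
    return best_parts


def gain_ratio_rank(
    vectors: Sequence[FeatureVector],
) -> list[tuple[str, float]]:
    """Rank the screening features by gain ratio against the label.

    Nominal features partition by value; numeric features are
    discretized by the supervised midpoint split.  Features whose split
    information is zero (constant) get a gain ratio of 0.  Raises
    :class:`UndefinedRankingError` when only one class is present.
    """
    X, y, _ = feature_matrix(vectors)
    if len(np.unique(y)) < 2:
        raise UndefinedRankingError("gain ratio needs at least two classes")
    scores: list[tuple[str, float]] = []
    for j, name in enumerate(FEATURE_NAMES):
        x = X[:, j]
        if name in NOMINAL_FEATURES:
            parts = [y[x == v] for v in np.unique(x)]
        else:
            parts = _best_numeric_partition(x, y)
        gain, split_info = _partition_scores(y, parts)
        ratio = 0.0 if split_info == 0.0 or gain <= 0.0 else gain / split_info
        scores.append((name, ratio))
    return sorted(scores, key=lambda kv: -kv[1])


# -- grouped cross-validation --------------------------------------------


class ClassifierBackend(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierBackend": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


def make_backend(name: str, random_state: int = 0) -> ClassifierBackend:
    """Thin adapters to established learners behind the fit/predict
    contract.  Tree learners are depth-capped at 5."""
    name = name.lower()
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(max_depth=5, random_state=random_state)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=100, max_depth=5, random_state=random_state
        )
    if name == "svm":
        from sklearn.svm import LinearSVC

        return LinearSVC(random_state=random_state)
    if name in ("bn", "nb"):
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    raise ValueError(f"unknown backend {name!r} (expected dt, rf, svm or bn)")


@dataclass
class EvalReport:
    """Pooled grouped-CV evaluation: every user is predicted exactly
    once, so the confusion-matrix total equals the user count."""

    accuracy: float
    per_class: dict[str, dict[str, float]]
    confusion: dict[str, dict[str, int]]
    fold_assignment: dict[str, int]
    n_evaluated: int
    labels: tuple[str, ...] = LABELS

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "n_evaluated": self.n_evaluated,
            "fold_assignment": self.fold_assignment,
        }


def grouped_kfold_evaluate(
    vectors: Sequence[FeatureVector],
    backend: ClassifierBackend | str = "dt",
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Evaluate a classifier with user-grouped k-fold cross-validation.

    Users are shuffled (seeded) and partitioned into ``k`` folds; each
    fold's vectors are predicted by a model trained on the rest.
    """
    X, y, groups = feature_matrix(vectors)
    users = sorted(set(groups))
    if k > len(users):
        raise FoldError(f"cannot make {k} folds from {len(users)} users")
    rng = np.random.default_rng(seed)
    order = list(users)
    rng.shuffle(order)
    folds = np.array_split(np.array(order), k)
    fold_of = {u: i for i, chunk in enumerate(folds) for u in chunk}

    y_true = np.empty(len(y), dtype=object)
    y_pred = np.empty(len(y), dtype=object)
    for i in range(k):
        test_mask = np.array([fold_of[u] == i for u in groups])
        if isinstance(backend, str):
            model = make_backend(backend, random_state=seed)
        else:
            model = backend
        model.fit(X[~test_mask], y[~test_mask])
        y_true[test_mask] = y[test_mask]
        y_pred[test_mask] = model.predict(X[test_mask])

    labels = list(LABELS)
    cm = confusion_matrix(y_true.astype(str), y_pred.astype(str), labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true.astype(str), y_pred.astype(str), labels=labels, zero_division=0
    )
    return EvalReport(
        accuracy=float(accuracy_score(y_true.astype(str), y_pred.astype(str))),
        per_class={
            lab: {
                "precision": float(prec[i]),
                "recall": float(rec[i]),
                "f_measure": float(f1[i]),
            }
            for i, lab in enumerate(labels)
        },
        confusion={
            t: {p: int(cm[i, j]) for j, p in enumerate(labels)}
            for i, t in enumerate(labels)
        },
        fold_assignment=fold_of,
        n_evaluated=len(y),
    )


# -- synthetic cohort ----------------------------------------------------


@dataclass(frozen=True)
class CohortSettings:
    """Generator knobs: per-impairment-level score distributions and the
    cohort composition.  Defaults reproduce the observed structure:
    healthy users average an answer similarity of 0.42 +/- 0.17 against
    0.29 +/- 0.17 (mild) and 0.08 +/- 0.10 (severe); answers shorten
    with impairment (54.2 / 37.8 / 30.8 characters on average); stress
    depresses and focus lifts performance; sessions differ in
    difficulty.  Effects are mean-centred so the marginal per-level
    similarity means stay at the configured values."""

    sim_by_level: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "absent": (0.42, 0.17),
            "mild": (0.29, 0.17),
            "severe": (0.08, 0.10),
        }
    )
    length_by_level: dict[str, float] = field(
        default_factory=lambda: {"absent": 54.20, "mild": 37.75, "severe": 30.84}
    )
    length_sd: float = 18.0
    level_probs: dict[str, float] = field(
        default_factory=lambda: {"absent": 0.43, "mild": 0.40, "severe": 0.17}
    )
    # per-session difficulty shifts on the similarity scale (centred in use)
    session_shifts: tuple[float, ...] = (-0.02, 0.12, -0.09, -0.02, 0.01)
    focus_effect: float = 0.10  # added when focused, centred by p_focus
    stress_effect: float = -0.10  # added when stressed, centred by p_stress
    p_focus: float = 0.73
    p_stress: float = 0.25
    p_studies: float = 0.47
    p_technology: float = 0.57
    age_band_probs: tuple[float, ...] = (0.20, 0.50, 0.28, 0.02)

    def validate(self) -> None:
        for level in IMPAIRMENT_LEVELS:
            m, sd = self.sim_by_level[level]
            if not 0.0 <= m <= 1.0 or sd <= 0.0:
                raise CohortSettingsError(
                    f"level {level!r}: mean must be in [0,1] and SD positive"
                )
            if self.length_by_level[level] < 0:
                raise CohortSettingsError("mean lengths are non-negative")
        if self.length_sd <= 0:
            raise CohortSettingsError("length_sd must be positive")
        probs = [self.level_probs[level] for level in IMPAIRMENT_LEVELS]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise CohortSettingsError("level probabilities must sum to 1")
        if len(self.session_shifts) != N_SESSIONS:
            raise CohortSettingsError("need one session shift per session")
        for p in (self.p_focus, self.p_stress, self.p_studies, self.p_technology):
            if not 0.0 <= p <= 1.0:
                raise CohortSettingsError("probabilities must lie in [0, 1]")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise CohortSettingsError("age band probabilities must sum to 1")


DEFAULT_COHORT = CohortSettings()

_loc_cache: dict[tuple[float, float], float] = {}


def _truncnorm_loc(target_mean: float, sd: float) -> float:
    """Location parameter of a [0, 1]-truncated normal whose mean equals
    ``target_mean`` (solved numerically, cached)."""
    key = (round(target_mean, 6), round(sd, 6))
    if key not in _loc_cache:

        def gap(loc: float) -> float:
            a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
            return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

        _loc_cache[key] = brentq(gap, -5.0, 6.0, xtol=1e-10)
    return _loc_cache[key]


def _draw_sims(
    rng: np.random.Generator, target_mean: float, sd: float, size: int
) -> np.ndarray:
    """Mean-matched truncated-normal draws on [0, 1] via rejection."""
    loc = _truncnorm_loc(target_mean, sd)
    out = rng.normal(loc, sd, size)
    for _ in range(1000):
        bad = (out < 0.0) | (out > 1.0)
        if not bad.any():
            return out
        out[bad] = rng.normal(loc, sd, int(bad.sum()))
    return np.clip(out, 0.0, 1.0)


def simulate_cohort(
    settings: CohortSettings | None = None,
    n_users: int = 200,
    seed: int = 1,
) -> tuple[list[ParticipantProfile], list[SessionRecord]]:
    """Generate a synthetic cohort of participants with five sessions
    each.  Deterministic for a fixed seed."""
    settings = settings or DEFAULT_COHORT
    settings.validate()
    rng = np.random.default_rng(seed)

    shifts = np.asarray(settings.session_shifts, dtype=float)
    shifts = shifts - shifts.mean()  # exact centring

    profiles: list[ParticipantProfile] = []
    sessions: list[SessionRecord] = []
    levels = list(IMPAIRMENT_LEVELS)
    level_p = [settings.level_probs[level] for level in levels]
    for idx in range(n_users):
        level = levels[rng.choice(len(levels), p=level_p)]
        profile = ParticipantProfile(
            user_id=f"u{idx:04d}",
            age_band=int(rng.choice([1, 2, 3, 4], p=settings.age_band_probs)),
            focus=bool(rng.random() < settings.p_focus),
            stress=bool(rng.random() < settings.p_stress),
            studies=bool(rng.random() < settings.p_studies),
            technology=bool(rng.random() < settings.p_technology),
            impairment=level,
        )
        profiles.append(profile)

        mean, sd = settings.sim_by_level[level]
        personal = (
            settings.focus_effect * (float(profile.focus) - settings.p_focus)
            + settings.stress_effect * (float(profile.stress) - settings.p_stress)
        )
        # centred effects shrink near the scale edges so the [0, 1]
        # clamp stays inactive and marginal level means are preserved
        effect_scale = min(1.0, 4.0 * mean * (1.0 - mean))
        mean_len = settings.length_by_level[level]
        for s in range(N_SESSIONS):
            target = mean + effect_scale * (shifts[s] + personal)
            target = float(np.clip(target, 0.02, 0.98))
            sims = _draw_sims(rng, target, sd, N_QUESTIONS)
            lengths = np.maximum(
                rng.normal(mean_len, settings.length_sd, N_QUESTIONS), 0.0
            )
            sessions.append(
                SessionRecord(
                    user_id=profile.user_id,
                    session_index=s + 1,
                    sim_scores=tuple(float(v) for v in sims),
                    response_lengths=tuple(int(round(v)) for v in lengths),
                )
            )
    return profiles, sessions


def cohort_features(
    profiles: Sequence[ParticipantProfile], sessions: Sequence[SessionRecord]
) -> list[FeatureVector]:
    """Feature vectors for a whole cohort (one per participant)."""
    by_user: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        by_user.setdefault(s.user_id, []).append(s)
    return [
        extract_features(p, sorted(by_user.get(p.user_id, []),
                                   key=lambda s: s.session_index))
        for p in profiles
    ]


def permute_labels(
    vectors: Sequence[FeatureVector], seed: int = 0
) -> list[FeatureVector]:
    """Shuffle labels across vectors — the null cohort for sanity checks."""
    rng = np.random.default_rng(seed)
    labels = [v.label for v in vectors]
    perm = rng.permutation(len(labels))
    return [replace(v, label=labels[perm[i]]) for i, v in enumerate(vectors)]
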