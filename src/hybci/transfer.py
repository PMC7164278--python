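"""Cross-subject transfer learning via Bhattacharyya similarity.

The calibration-reduction strategy: project each prior subject's trials and
the current subject's few training trials to (EEG, fTCD) evidence scores
with subject-specific pipelines, summarize each subject by four
class-conditional score densities, and measure subject similarity as the
sum of the four Bhattacharyya distances between corresponding densities.
The current subject's training set is then augmented with the trials of the
top-k most similar prior subjects (k <= 3, chosen by cross-validation), and
the whole pipeline is refitted on the augmented set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .fusion import ClassConditionalDensity
from .pipeline import (FittedDecoder, PipelineConfig, ProblemData,
                       extract_problem_data, fit_decoder)

__all__ = ["SubjectProfile", "DiscretizedDensityPair", "SimilarityRecord",
           "build_profile", "profile_from_data", "bhattacharyya_distance",
           "bhattacharyya_from_masses", "discretize_pair", "subject_distance",
           "rank_similar", "select_augmentation", "tl_train_predict"]

log = logging.getLogger(__name__)

GRID_POINTS = 512
MASS_FLOOR = 1e-12
GRID_PAD_BANDWIDTHS = 3.0
K_MAX = 3


@dataclass
class SubjectProfile:
    """Four class-conditional evidence densities summarizing one subject."""

    densities: dict                  # (modality, class_label) -> density
    subject_id: str
    n_trials: int
    paradigm: str
    problem: str

    def __post_init__(self) -> None:
        mods = {m for m, _ in self.densities}
        classes = {c for _, c in self.densities}
        if len(self.densities) != 4 or mods != {"EEG", "fTCD"} or len(classes) != 2:
            raise ValueError("a profile needs 2 modalities x 2 classes densities")

    @property
    def classes(self) -> tuple:
        return tuple(dict.fromkeys(c for _, c in self.densities))


@dataclass
class DiscretizedDensityPair:
    """Two densities discretized to probability masses on a shared grid."""

    grid: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    @property
    def N(self) -> int:
        return self.grid.size


@dataclass
class SimilarityRecord:
    candidate_id: str
    distances: dict                  # (modality, class_label) -> distance
    total: float

    @staticmethod
    def from_components(candidate_id: str, distances: dict) -> "SimilarityRecord":
        return SimilarityRecord(candidate_id=candidate_id, distances=dict(distances),
                                total=float(sum(distances.values())))


#: fixed bandwidth (in reference-class noise units) of the profile
#: densities; evidence scores are normalized to that scale, so a common
#: bandwidth makes the four densities of different subjects directly
#: comparable and keeps their distances insensitive to the sampling noise
#: of per-density spread estimates
PROFILE_BANDWIDTH = 1.0


def profile_from_data(data: ProblemData, config: PipelineConfig,
                      subject_id: str,
                      profile_bandwidth: float = PROFILE_BANDWIDTH) -> SubjectProfile:
    """Profile a subject from cached problem data (self-contained pipeline).

    The subject's own trials train the projection SVMs whose scores feed
    the four KDEs; a prior subject uses all of its problem trials, the
    current subject only its training split.
    """
    pos, neg = config.labels
    for c in (pos, neg):
        if int(np.sum(data.labels == c)) < 2:
            raise ValueError(f"class {c!r} needs at least 2 trials to profile")
    # profiling needs scores and densities only, so skip the alpha search
    decoder = fit_decoder(data, replace(config, assumption="A2", alpha=None))
    pairs, y = decoder.train_pairs, decoder.train_labels
    densities = {}
    for c in config.labels:
        m = y == c
        densities[("EEG", c)] = ClassConditionalDensity(
            sample_scores=pairs[m, 0], bandwidth=profile_bandwidth)
        densities[("fTCD", c)] = ClassConditionalDensity(
            sample_scores=pairs[m, 1], bandwidth=profile_bandwidth)
    return SubjectProfile(densities=densities, subject_id=subject_id,
                          n_trials=data.n_trials, paradigm=config.paradigm,
                          problem=config.problem)


def build_profile(trials, labels, config: PipelineConfig,
                  subject_id: str = "current",
                  t_seconds: float | None = None) -> SubjectProfile:
    """Convenience wrapper: extract problem data, then profile."""
    data = extract_problem_data(list(trials), list(labels) if labels is not None
                                else None, config, t_seconds)
    return profile_from_data(data, config, subject_id)


# ---------------------------------------------------------------------------
# Bhattacharyya distance
# ---------------------------------------------------------------------------

def bhattacharyya_from_masses(P: np.ndarray, Q: np.ndarray,
                              form: str = "sqrt") -> float:
    """Distance between two discrete probability mass vectors.

    ``form='sqrt'`` is the standard coefficient -ln sum(sqrt(P_i Q_i));
    ``form='printed'`` evaluates -ln sum(P_i Q_i) instead (kept for
    comparison with a variant that omits the square root).
    """
    P = np.maximum(np.asarray(P, float), MASS_FLOOR)
    Q = np.maximum(np.asarray(Q, float), MASS_FLOOR)
    if form == "sqrt":
        bc = float(np.sum(np.sqrt(P * Q)))
    elif form == "printed":
        bc = float(np.sum(P * Q))
    else:
        raise ValueError(f"unknown distance form {form!r}")
    return max(0.0, -np.log(min(bc, 1.0)))


def discretize_pair(p: ClassConditionalDensity, q: ClassConditionalDensity,
                    n_grid: int = GRID_POINTS) -> DiscretizedDensityPair:
    """Evaluate both densities on a shared grid and normalize to masses.

    The grid spans the union of the two score ranges padded by 3x the
    larger bandwidth, so both tails carry (floored) mass.
    """
    pad = GRID_PAD_BANDWIDTHS * max(p.bandwidth, q.bandwidth)
    lo = min(p.sample_scores.min(), q.sample_scores.min()) - pad
    hi = max(p.sample_scores.max(), q.sample_scores.max()) + pad
    grid = np.linspace(lo, hi, n_grid)

    def _masses(d: ClassConditionalDensity) -> np.ndarray:
        # normalize from the log domain so very narrow densities (floored
        # bandwidths) cannot underflow to an all-zero mass vector
        logp = d.log_evaluate(grid)
        w = np.exp(logp - logp.max())
        return w / w.sum()

    return DiscretizedDensityPair(grid=grid, P=_masses(p), Q=_masses(q))


def bhattacharyya_distance(p: ClassConditionalDensity,
                           q: ClassConditionalDensity,
                           n_grid: int = GRID_POINTS,
                           form: str = "sqrt") -> float:
    """Bhattacharyya distance between two score densities (grid-discretized)."""
    pair = discretize_pair(p, q, n_grid)
    d = bhattacharyya_from_masses(pair.P, pair.Q, form)
    if d > 20.0:
        log.info("near-disjoint score supports (d=%.2f)", d)
    return d


def subject_distance(a: SubjectProfile, b: SubjectProfile,
                     n_grid: int = GRID_POINTS,
                     form: str = "sqrt") -> SimilarityRecord:
    """Total distance = sum of the 4 per-(modality, class) distances."""
    if a.paradigm != b.paradigm or a.problem != b.problem:
        raise ValueError("profiles come from different paradigms/problems")
    distances = {
        key: bhattacharyya_distance(a.densities[key], b.densities[key],
                                    n_grid, form)
        for key in a.densities
    }
    return SimilarityRecord.from_components(b.subject_id, distances)


def rank_similar(current: SubjectProfile,
                 candidates: list[SubjectProfile],
                 n_grid: int = GRID_POINTS,
                 form: str = "sqrt") -> list[SimilarityRecord]:
    """Ascending by total distance; ties break on candidate id."""
    if not candidates:
        raise ValueError("need at least one candidate profile")
    records = [subject_distance(current, c, n_grid, form) for c in candidates]
    return sorted(records, key=lambda r: (r.total, r.candidate_id))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _cv_accuracy(data: ProblemData, config: PipelineConfig,
                 n_folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold accuracy of the full pipeline on one trial set."""
    y = data.labels
    min_class = min(int(np.sum(y == c)) for c in np.unique(y))
    n_folds = max(2, min(n_folds, min_class))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, va in skf.split(np.zeros(y.size), y):
        decoder = fit_decoder(data.subset(tr), config)
        correct += int(np.sum(decoder.predict(data.subset(va)) == y[va]))
    return correct / y.size


def select_augmentation(current_train: ProblemData,
                        ranked_candidates: list[ProblemData],
                        config: PipelineConfig,
                        k_max: int = K_MAX,
                        allow_k0: bool = False,
                        n_folds: int = 10,
                        seed: int = 0) -> tuple[int, list[float]]:
    """Choose how many of the top-ranked datasets to pool into training.

    Each k in 1..min(k_max, available) is scored by stratified
    cross-validated accuracy of the refitted pipeline on the pooled trial
    set; the best k wins, ties going to the smallest k (and to k=0, the
    unaugmented set, when ``allow_k0``).
    """
    if not ranked_candidates:
        raise ValueError("no candidate datasets to select from")
    ks = list(range(0 if allow_k0 else 1, min(k_max, len(ranked_candidates)) + 1))
    scores = []
    for k in ks:
        combined = ProblemData.concatenate([current_train] + ranked_candidates[:k])
        scores.append(_cv_accuracy(combined, config, n_folds, seed))
    best = ks[int(np.argmax(scores))]    # first max -> smallest k on ties
    return best, scores


def tl_train_predict(current_train: ProblemData,
                     augmentation: list[ProblemData],
                     current_test: ProblemData,
                     config: PipelineConfig) -> tuple[np.ndarray, np.ndarray, FittedDecoder]:
    """Refit the whole pipeline on the augmented set and predict test trials.

    With an empty augmentation list this is exactly the no-transfer (NTL)
    path. Returns (predictions, evidence pairs, fitted decoder); the test
    set is never touched by the augmentation.
    """
    train = (ProblemData.concatenate([current_train] + list(augmentation))
             if augmentation else current_train)
    decoder = fit_decoder(train, config)
    pairs = decoder.evidence_pairs(current_test)
    preds = decoder.predict(current_test)
    return preds, pairs, decoder
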