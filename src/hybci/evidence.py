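"""Feature selection and SVM score projection.

Each modality's feature vector is reduced to a single scalar "evidence"
per trial: significant features are kept by a two-sided Wilcoxon rank-sum
test (p < 0.05) on the training set, the retained features are z-scored
with training statistics and fed to a linear SVM, and the signed
decision-function value is the evidence. Motor-imagery CSP features bypass
selection (the feature vector is already the chosen 2f log-variances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from scipy.stats import rankdata
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["EvidencePair", "SelectionMask", "ranksum_select",
           "ScoreProjector", "svm_score_projection"]

log = logging.getLogger(__name__)


@dataclass
class EvidencePair:
    """The two scalar scores of one trial (EEG evidence e, fTCD evidence f)."""

    e: float
    f: float
    trial_index: int = -1
    true_label: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e) and np.isfinite(self.f)):
            raise ValueError("evidence scores must be finite")


@dataclass
class SelectionMask:
    kept: np.ndarray        # indices of retained feature columns
    p_values: np.ndarray    # per-column rank-sum p-values
    threshold: float = 0.05

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.kept]

    @property
    def n_kept(self) -> int:
        return self.kept.size


def ranksum_select(features: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.05) -> SelectionMask:
    """Keep feature columns whose two-sided rank-sum p-value is < threshold.

    Constant columns get p = 1 and are never selected. The mask is learned
    on training trials only and reused unchanged on test trials.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 label values, got {classes.size}")
    mask_a = y == classes[0]
    n1, n2 = int(mask_a.sum()), int((~mask_a).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per class")
    # vectorized rank-sum (normal approximation, no tie correction) across
    # all feature columns at once; agrees with scipy.stats.ranksums
    ranks = rankdata(X, axis=0)
    w = ranks[mask_a].sum(axis=0)
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - expected) / sd
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p[np.ptp(X, axis=0) == 0] = 1.0    # constant column: exchangeable
    kept = np.flatnonzero(p < threshold)
    return SelectionMask(kept=kept, p_values=p, threshold=threshold)


class ScoreProjector:
    """z-scoring + binary SVM whose signed decision value is the evidence.

    The kernel and regularization are not constrained by the decision rule
    downstream (the scores feed a KDE, which adapts to any monotone score
    scale), so the defaults are a linear kernel with C = 1.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0):
        self.kernel = kernel
        self.C = C
        self._scaler: StandardScaler | None = None
        self._svm: SVC | None = None
        self._degenerate = False

    def fit(self, X: np.ndarray, y: np.ndarray, positive_label=None) -> "ScoreProjector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("ScoreProjector needs exactly two classes")
        if positive_label is None:
            positive_label = classes[0]
        # encode positive class as 1 so decision_function > 0 <=> positive
        y01 = (y == positive_label).astype(int)
        if X.shape[1] == 0:
            log.warning("empty feature set after selection; scores will be 0")
            self._degenerate = True
            return self
        self._scaler = StandardScaler().fit(X)
        self._svm = SVC(kernel=self.kernel, C=self.C)
        self._svm.fit(self._scaler.transform(X), y01)
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._degenerate:
            return np.zeros(X.shape[0])
        return self._svm.decision_function(self._scaler.transform(X))


def svm_score_projection(train_features: np.ndarray, train_labels: np.ndarray,
                         eval_features: np.ndarray, *, kernel: str = "linear",
                         C: float = 1.0, standardize: bool = True,
                         positive_label=None) -> np.ndarray:
    """Fit the projection SVM on training rows, return eval decision values.

    With ``standardize=False`` the SVM is fitted on the raw feature scale
    (used by closed-form tests); the default z-scores with training stats.
    """
    proj = ScoreProjector(kernel=kernel, C=C)
    if not standardize:
        X = np.asarray(train_features, dtype=float)
        y = np.asarray(train_labels)
        classes = np.unique(y)
        if positive_label is None:
            positive_label = classes[0]
        y01 = (y == positive_label).astype(int)
        svm = SVC(kernel=kernel, C=C).fit(X, y01)
        return svm.decision_function(np.asarray(eval_features, dtype=float))
    proj.fit(train_features, train_labels, positive_label=positive_label)
    return proj.decision_values(eval_features)
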