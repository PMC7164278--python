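"""KDE-based Bayesian evidence fusion.

Per binary problem, four class-conditional densities are estimated from
training-trial evidence scores with a Gaussian-kernel KDE (Silverman
bandwidth): p(e|class) and p(f|class) for the EEG and fTCD evidences.
A test trial's intent is the class maximizing the fused likelihood, under
one of two independence assumptions:

* ``A2`` — equal contribution:  p(e|x) * p(f|x)
* ``A3`` — weighted contribution:  p(e|x)^alpha * p(f|x)^(1-alpha),
  with alpha found by a 0..1 grid search (step 0.01) under
  cross-validation on the training evidences.

Uniform intent priors are assumed (trials are presented in randomized
order), so the posterior argmax reduces to the likelihood argmax. All
products are evaluated in the log domain with densities floored at 1e-300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

__all__ = ["ClassConditionalDensity", "FusionConfig", "silverman_bandwidth",
           "kde_fit", "fuse_classify", "fuse_classify_arrays", "alpha_search",
           "ALPHA_GRID"]

log = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-300
BANDWIDTH_FLOOR = 1e-6
ALPHA_GRID = np.round(np.arange(0, 101) * 0.01, 2)


def silverman_bandwidth(scores: np.ndarray, rule: str = "silverman_robust") -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE.

    ``silverman_robust``: 0.9 * min(sigma, IQR/1.34) * n^(-1/5);
    ``silverman_simple``: 1.06 * sigma * n^(-1/5). Floored at 1e-6 so
    degenerate (constant) score sets still yield a usable density.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("bandwidth needs at least 2 scores")
    sigma = float(np.std(x, ddof=1))
    if rule == "silverman_robust":
        iqr = float(np.subtract(*np.percentile(x, [75, 25])))
        spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
        h = 0.9 * spread * n ** (-0.2)
    elif rule == "silverman_simple":
        h = 1.06 * sigma * n ** (-0.2)
    else:
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    if h < BANDWIDTH_FLOOR:
        log.warning("degenerate score set; bandwidth floored at %g", BANDWIDTH_FLOOR)
        h = BANDWIDTH_FLOOR
    return h


@dataclass
class ClassConditionalDensity:
    """Gaussian-kernel KDE of one modality's scores for one class."""

    sample_scores: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.sample_scores = np.asarray(self.sample_scores, dtype=float).ravel()
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def log_evaluate(self, x) -> np.ndarray:
        """log density at point(s) x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.sample_scores[None, :]) / self.bandwidth
        log_kernel = -0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)
        return logsumexp(log_kernel, axis=1) - np.log(
            self.sample_scores.size * self.bandwidth)

    def evaluate(self, x) -> np.ndarray:
        return np.exp(self.log_evaluate(x))

    def support(self, pad_bandwidths: float = 5.0) -> tuple[float, float]:
        lo = float(self.sample_scores.min() - pad_bandwidths * self.bandwidth)
        hi = float(self.sample_scores.max() + pad_bandwidths * self.bandwidth)
        return lo, hi


def kde_fit(scores: np.ndarray, rule: str = "silverman_robust",
            bandwidth_scale: float = 1.0) -> ClassConditionalDensity:
    """Fit the Gaussian-kernel KDE with a (optionally scaled) Silverman bandwidth.

    ``bandwidth_scale > 1`` oversmooths; density *comparison* (profile
    similarity) uses this to cut the sampling noise of distances between
    fitted densities, at the cost of detail irrelevant there.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 2:
        raise ValueError("KDE needs at least 2 scores")
    h = bandwidth_scale * silverman_bandwidth(scores, rule)
    return ClassConditionalDensity(sample_scores=scores, bandwidth=h)


@dataclass
class FusionConfig:
    """Fusion assumption and its weight; A3 carries alpha, A2 does not."""

    assumption: str = "A2"
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.assumption not in ("A2", "A3"):
            raise ValueError("assumption must be 'A2' or 'A3'")
        if self.assumption == "A3":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("A3 requires alpha in [0, 1]")
        elif self.alpha is not None:
            raise ValueError("alpha is only meaningful under A3")

    @staticmethod
    def default_for_paradigm(paradigm: str, alpha: float | None = None) -> "FusionConfig":
        # MI fuses under the weighted assumption; MR/WG under equal weights
        if paradigm == "MI":
            return FusionConfig(assumption="A3", alpha=0.5 if alpha is None else alpha)
        return FusionConfig(assumption="A2")


DensityBank = dict  # keys (modality, class_label) -> ClassConditionalDensity


def _fused_loglik(e: np.ndarray, f: np.ndarray, densities: DensityBank,
                  classes: tuple, weight_e: float, weight_f: float) -> np.ndarray:
    """(n_trials, n_classes) weighted log-likelihood matrix."""
    cols = []
    for c in classes:
        lpe = densities[("EEG", c)].log_evaluate(e)
        lpf = densities[("fTCD", c)].log_evaluate(f)
        lpe = np.maximum(lpe, np.log(DENSITY_FLOOR))
        lpf = np.maximum(lpf, np.log(DENSITY_FLOOR))
        cols.append(weight_e * lpe + weight_f * lpf)
    return np.column_stack(cols)


def _weights(config: FusionConfig) -> tuple[float, float]:
    if config.assumption == "A2":
        return 1.0, 1.0
    return float(config.alpha), 1.0 - float(config.alpha)


def fuse_classify_arrays(e: np.ndarray, f: np.ndarray, densities: DensityBank,
                         config: FusionConfig, classes: tuple) -> np.ndarray:
    """Vectorized intent inference for arrays of evidence pairs.

    Ties in the fused likelihood resolve deterministically to the class
    listed first (class 1 of the problem).
    """
    ll = _fused_loglik(np.asarray(e, float), np.asarray(f, float),
                       densities, classes, *_weights(config))
    # argmax takes the first maximum -> deterministic class-1 tie-break
    idx = np.argmax(ll, axis=1)
    return np.asarray([classes[i] for i in idx])


def fuse_classify(pair, densities: DensityBank, config: FusionConfig,
                  classes: tuple | None = None):
    """Infer the intent of a single trial from its evidence pair."""
    if classes is None:
        classes = tuple(dict.fromkeys(c for (_, c) in densities))
    if len(classes) != 2 or any((m, c) not in densities
                                for m in ("EEG", "fTCD") for c in classes):
        raise ValueError("densities must cover both classes x both modalities")
    return fuse_classify_arrays([pair.e], [pair.f], densities, config, classes)[0]


def alpha_search(train_pairs: np.ndarray, train_labels: np.ndarray,
                 seed: int = 0, n_folds: int = 10,
                 rule: str = "silverman_robust") -> float:
    """Grid-search the A3 weight on the 101-point grid 0.00..1.00.

    Each candidate alpha is scored by stratified cross-validated fusion
    accuracy on the training evidences (KDEs refit per fold); ties resolve
    to the smallest alpha. Folds shrink below 10 when a class has fewer
    trials than folds.
    """
    pairs = np.asarray(train_pairs, dtype=float)
    y = np.asarray(train_labels)
    if pairs.shape[0] < 10:
        raise ValueError("alpha search needs at least 10 labeled pairs")
    classes = tuple(np.unique(y))
    min_class = min(int(np.sum(y == c)) for c in classes)
    n_folds = max(2, min(n_folds, min_class))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = np.zeros(ALPHA_GRID.size)
    total = 0
    for tr, va in skf.split(pairs, y):
        densities = {}
        ok = True
        for c in classes:
            m = y[tr] == c
            if m.sum() < 2:
                ok = False
                break
            densities[("EEG", c)] = kde_fit(pairs[tr][m, 0], rule)
            densities[("fTCD", c)] = kde_fit(pairs[tr][m, 1], rule)
        if not ok:
            continue
        lpe = np.column_stack([
            np.maximum(densities[("EEG", c)].log_evaluate(pairs[va, 0]),
                       np.log(DENSITY_FLOOR)) for c in classes])
        lpf = np.column_stack([
            np.maximum(densities[("fTCD", c)].log_evaluate(pairs[va, 1]),
                       np.log(DENSITY_FLOOR)) for c in classes])
        truth = np.array([list(classes).index(l) for l in y[va]])
        for i, a in enumerate(ALPHA_GRID):
            pred = np.argmax(a * lpe + (1.0 - a) * lpf, axis=1)
            correct[i] += int(np.sum(pred == truth))
        total += va.size
    if total == 0:
        raise RuntimeError("no usable folds in alpha search")
    # first argmax on the ascending grid = smallest alpha among ties
    return float(ALPHA_GRID[int(np.argmax(correct))])
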