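"""Modality-specific feature extraction.

Three schemes, matched to paradigm and modality:

* **CSP log-variance** (MI EEG) — common spatial patterns found by
  simultaneous diagonalization of the two class-average trial covariances;
  features are log-variances of the trial filtered with ``f`` eigenvectors
  from each end of the transformation matrix.
* **Template matching** (MRWG EEG) — per class and electrode, the maximum
  over all lags of the normalized cross-correlation between a trial segment
  and the class template (the electrode-wise average of training trials).
* **Wavelet statistics** (fTCD) — 5-level db4 discrete wavelet transform of
  each velocity-envelope segment; mean/variance/skewness/kurtosis of the six
  sub-bands (D1..D5, A5), 24 features per segment, 48 per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
import scipy.linalg
import scipy.signal

from .synth import TrialMatrix

__all__ = [
    "CSPModel",
    "TemplateBank",
    "truncate_trial",
    "csp_fit",
    "csp_fit_from_covariances",
    "csp_transform",
    "template_fit",
    "template_transform",
    "ftcd_wavelet_features",
    "wavelet_subbands",
]

#: ridge added (times trace) when the pooled covariance is singular
COV_RIDGE = 1e-9
#: variances below this are clamped before taking logs
LOG_VAR_FLOOR = 1e-12
#: sub-band variance below this zeroes skewness/kurtosis
MOMENT_FLOOR = 1e-12

WAVELET = "db4"
WAVELET_LEVELS = 5
WAVELET_MODE = "symmetric"


# ---------------------------------------------------------------------------
# trial truncation
# ---------------------------------------------------------------------------

def truncate_trial(trial: TrialMatrix, t_seconds: float) -> TrialMatrix:
    """Keep the first ``t_seconds`` of both modalities (label unchanged).

    Accuracy/ITR are evaluated on the 1..10 s grid of truncations; ``t``
    beyond the recorded duration is rejected.
    """
    if t_seconds <= 0:
        raise ValueError("t_seconds must be positive")
    n_eeg = int(round(t_seconds * trial.eeg_rate))
    n_ftcd = int(round(t_seconds * trial.ftcd_rate))
    if n_eeg > trial.eeg.shape[1] or n_ftcd > trial.ftcd.shape[1]:
        raise ValueError(
            f"t_seconds={t_seconds} exceeds trial duration {trial.duration:.3f} s")
    if n_eeg == trial.eeg.shape[1] and n_ftcd == trial.ftcd.shape[1]:
        return trial
    return TrialMatrix(
        eeg=trial.eeg[:, :n_eeg],
        ftcd=trial.ftcd[:, :n_ftcd],
        label=trial.label,
        eeg_rate=trial.eeg_rate,
        ftcd_rate=trial.ftcd_rate,
    )


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """Common-spatial-pattern filters for one binary problem.

    ``W`` columns are generalized eigenvectors of (Sigma_+, Sigma_+ +
    Sigma_-) sorted by the positive-class eigenvalue lambda_+ descending;
    W^T (Sigma_+ + Sigma_-) W = I, and lambda_+ + lambda_- = 1 columnwise.
    """

    W: np.ndarray              # (n_channels, n_channels)
    eigvals_pos: np.ndarray    # (n_channels,), descending, in [0, 1]
    class_order: tuple[str, str] = ("+", "-")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def trial_covariance(eeg: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance S = R R^T / tr(R R^T)."""
    s = eeg @ eeg.T
    return s / np.trace(s)


def csp_fit_from_covariances(cov_pos: np.ndarray, cov_neg: np.ndarray,
                             class_order: tuple[str, str] = ("+", "-")) -> CSPModel:
    """Solve the simultaneous-diagonalization problem for two class covariances."""
    pooled = cov_pos + cov_neg
    # symmetrize; regularize if the pooled covariance is (near-)singular
    pooled = 0.5 * (pooled + pooled.T)
    if np.linalg.matrix_rank(pooled) < pooled.shape[0]:
        warnings.warn("pooled covariance is rank-deficient; adding ridge",
                      RuntimeWarning, stacklevel=2)
        pooled = pooled + COV_RIDGE * np.trace(pooled) * np.eye(pooled.shape[0])
    evals, evecs = scipy.linalg.eigh(0.5 * (cov_pos + cov_pos.T), pooled)
    # eigh returns ascending eigenvalues with evecs^T pooled evecs = I
    order = np.argsort(-evals, kind="stable")
    W = evecs[:, order]
    lam = np.clip(evals[order], 0.0, 1.0)
    return CSPModel(W=W, eigvals_pos=lam, class_order=class_order)


def csp_fit(trials_pos: list, trials_neg: list,
            class_order: tuple[str, str] = ("+", "-")) -> CSPModel:
    """Fit CSP from two lists of trials (or raw channel-by-sample arrays)."""
    def _avg_cov(trials):
        if len(trials) < 2:
            raise ValueError("CSP needs at least 2 trials per class")
        mats = [t.eeg if isinstance(t, TrialMatrix) else np.asarray(t) for t in trials]
        if any(m.shape[1] < 2 for m in mats):
            raise ValueError("CSP needs at least 2 samples per channel")
        return np.mean([trial_covariance(m) for m in mats], axis=0)

    return csp_fit_from_covariances(_avg_cov(trials_pos), _avg_cov(trials_neg),
                                    class_order=class_order)


def csp_filter_indices(n_channels: int, f: int) -> np.ndarray:
    """Column indices of the 2f filters taken from both ends of W."""
    if not 1 <= f <= 8:
        raise ValueError("f must be in 1..8")
    if 2 * f > n_channels:
        raise ValueError(f"2f={2 * f} exceeds {n_channels} channels")
    return np.concatenate([np.arange(f), np.arange(n_channels - f, n_channels)])


def csp_transform(trial, model: CSPModel, f: int) -> np.ndarray:
    """2f log-variance features of a trial under the fitted CSP filters."""
    eeg = trial.eeg if isinstance(trial, TrialMatrix) else np.asarray(trial)
    if eeg.shape[0] != model.n_channels:
        raise ValueError("channel count does not match CSP model")
    idx = csp_filter_indices(model.n_channels, f)
    filtered = model.W[:, idx].T @ eeg
    var = np.var(filtered, axis=1, ddof=1)
    return np.log(np.maximum(var, LOG_VAR_FLOOR))


# ---------------------------------------------------------------------------
# SSVEP template matching
# ---------------------------------------------------------------------------

@dataclass
class TemplateBank:
    """Per-class electrode-wise average templates (16 per class)."""

    templates: dict[str, np.ndarray]   # label -> (16, template_len)
    class_order: tuple[str, str]

    @property
    def template_length(self) -> int:
        return next(iter(self.templates.values())).shape[1]


def template_fit(training_trials_by_class: dict[str, list]) -> TemplateBank:
    """Average each class's training trials electrode-wise into templates."""
    templates: dict[str, np.ndarray] = {}
    lengths = set()
    for label, trials in training_trials_by_class.items():
        if len(trials) < 1:
            raise ValueError(f"class {label!r} has no training trials")
        mats = [t.eeg if isinstance(t, TrialMatrix) else np.asarray(t) for t in trials]
        if len({m.shape for m in mats}) != 1:
            raise ValueError("training trials must share the same shape")
        templates[label] = np.mean(mats, axis=0)
        lengths.add(templates[label].shape[1])
    if len(lengths) != 1:
        raise ValueError("templates of different classes have different lengths")
    return TemplateBank(templates=templates,
                        class_order=tuple(training_trials_by_class.keys()))


def max_normalized_xcorr(x: np.ndarray, t: np.ndarray, mode: str = "normalized") -> float:
    """Max over all lags of the (norm-product–normalized) cross-correlation."""
    c = scipy.signal.correlate(x, t, mode="full", method="auto")
    if mode == "normalized":
        denom = np.linalg.norm(x) * np.linalg.norm(t)
        if denom < 1e-30:
            return 0.0
        c = c / denom
    return float(np.max(c))


def template_transform(trial, bank: TemplateBank,
                       mode: str = "normalized") -> np.ndarray:
    """32 features: per class (bank order), per electrode, the best-lag
    normalized cross-correlation between trial segment and template."""
    eeg = trial.eeg if isinstance(trial, TrialMatrix) else np.asarray(trial)
    feats = []
    for label in bank.class_order:
        tpl = bank.templates[label]
        if tpl.shape[0] != eeg.shape[0]:
            raise ValueError("electrode count mismatch with template bank")
        for ch in range(eeg.shape[0]):
            feats.append(max_normalized_xcorr(eeg[ch], tpl[ch], mode=mode))
    return np.asarray(feats)


# ---------------------------------------------------------------------------
# fTCD wavelet statistics
# ---------------------------------------------------------------------------

def wavelet_subbands(segment: np.ndarray) -> list[np.ndarray]:
    """5-level db4 coefficients ordered D1..D5, A5 (finest detail first)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2 ** WAVELET_LEVELS:
        raise ValueError(
            f"segment of {segment.size} samples is too short for a "
            f"{WAVELET_LEVELS}-level wavelet decomposition")
    with warnings.catch_warnings():
        # short truncated segments trip pywt's boundary-effect warning
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(segment, WAVELET, level=WAVELET_LEVELS,
                              mode=WAVELET_MODE)
    a5, details = coeffs[0], coeffs[1:]   # details are D5..D1
    return list(details[::-1]) + [a5]


def _subband_stats(c: np.ndarray) -> np.ndarray:
    n = c.size
    mean = float(np.mean(c))
    var = float(np.var(c, ddof=1)) if n > 1 else 0.0
    if var < MOMENT_FLOOR:
        return np.array([mean, var, 0.0, 0.0])
    d = c - mean
    m2 = float(np.mean(d ** 2))
    skew = float(np.mean(d ** 3)) / m2 ** 1.5
    kurt = float(np.mean(d ** 4)) / m2 ** 2      # non-excess
    return np.array([mean, var, skew, kurt])


def ftcd_wavelet_features(trial) -> np.ndarray:
    """48 features: per segment (left, right), per sub-band (D1..D5, A5),
    the mean, variance, skewness and kurtosis of the coefficients."""
    ftcd = trial.ftcd if isinstance(trial, TrialMatrix) else np.asarray(trial)
    feats = []
    for seg in ftcd:
        for band in wavelet_subbands(seg):
            feats.append(_subband_stats(band))
    return np.concatenate(feats)


def ftcd_feature_names() -> list[str]:
    names = []
    bands = [f"D{i}" for i in range(1, 6)] + ["A5"]
    for side in ("left", "right"):
        for band in bands:
            for stat in ("mean", "var", "skew", "kurt"):
                names.append(f"ftcd_{side}_{band}_{stat}")
    return names
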