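"""Feature extraction: CSP algebra, template matching, wavelet statistics."""

import numpy as np
import pytest
import pywt
import scipy.linalg

from hybci.features import (CSPModel, csp_fit, csp_fit_from_covariances,
                            csp_transform, ftcd_wavelet_features,
                            max_normalized_xcorr, template_fit,
                            template_transform, truncate_trial,
                            wavelet_subbands)
from hybci.synth import TrialMatrix


def _trial(eeg, ftcd=None, label="task1", eeg_rate=256.0, ftcd_rate=100.0):
    if ftcd is None:
        ftcd = np.zeros((2, int(eeg.shape[1] * ftcd_rate / eeg_rate)))
    return TrialMatrix(eeg=eeg, ftcd=ftcd, label=label,
                       eeg_rate=eeg_rate, ftcd_rate=ftcd_rate)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def test_truncate_keeps_prefix_and_label(rng):
    eeg = rng.standard_normal((16, 2560))
    ftcd = rng.standard_normal((2, 1000))
    trial = _trial(eeg, ftcd, label="task2")
    cut = truncate_trial(trial, 1.0)
    assert cut.eeg.shape == (16, 256)
    assert cut.ftcd.shape == (2, 100)
    np.testing.assert_array_equal(cut.eeg, eeg[:, :256])
    assert cut.label == "task2"
    # full-length truncation is the identity
    assert truncate_trial(trial, 10.0) is trial
    with pytest.raises(ValueError):
        truncate_trial(trial, 11.0)


@pytest.mark.parametrize("t", range(1, 11))
def test_truncate_supports_whole_evaluation_grid(t, rng):
    trial = _trial(rng.standard_normal((16, 2560)),
                   rng.standard_normal((2, 1000)))
    cut = truncate_trial(trial, t)
    assert cut.eeg.shape[1] == 256 * t


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def _orth_rows(scales, n_samples=4):
    """A channels x samples matrix with orthogonal rows of given norms."""
    rows = np.zeros((len(scales), n_samples))
    for i, s in enumerate(scales):
        rows[i, i] = s
    return rows


def test_csp_diagonal_closed_form():
    """Trace-normalized class covariances diag(.8,.2) / diag(.2,.8) give
    lambda+ = (0.8, 0.2), and W whitens the pooled covariance."""
    pos = [_orth_rows([np.sqrt(0.8), np.sqrt(0.2)])] * 2
    neg = [_orth_rows([np.sqrt(0.2), np.sqrt(0.8)])] * 2
    model = csp_fit(pos, neg)
    np.testing.assert_allclose(model.eigvals_pos, [0.8, 0.2], atol=1e-12)
    pooled = np.diag([1.0, 1.0])
    np.testing.assert_allclose(model.W.T @ pooled @ model.W, np.eye(2),
                               atol=1e-8)


def test_csp_matches_brute_force_generalized_eigensolver(rng):
    """lambda+ and W agree with an independent solve of
    Sigma+ w = lambda Sigma- w."""
    A = rng.standard_normal((6, 6))
    B = rng.standard_normal((6, 6))
    cov_pos = A @ A.T / np.trace(A @ A.T)
    cov_neg = B @ B.T / np.trace(B @ B.T)
    model = csp_fit_from_covariances(cov_pos, cov_neg)
    # oracle: generalized eigenvalues lambda = l+/l- of (cov_pos, cov_neg)
    gen = np.sort(scipy.linalg.eigvals(cov_pos, cov_neg).real)[::-1]
    lam_oracle = gen / (1.0 + gen)
    np.testing.assert_allclose(model.eigvals_pos, lam_oracle, atol=1e-8)
    # complementarity and simultaneous diagonalization
    lam_neg = np.array([w @ cov_neg @ w for w in model.W.T])
    lam_pos = np.array([w @ cov_pos @ w for w in model.W.T])
    np.testing.assert_allclose(lam_pos + lam_neg, 1.0, atol=1e-10)
    off = model.W.T @ cov_pos @ model.W - np.diag(lam_pos)
    assert np.max(np.abs(off)) < 1e-8


def test_csp_no_separation_gives_half_eigenvalues(rng):
    trials = [rng.standard_normal((4, 200)) for _ in range(40)]
    model = csp_fit(trials[:20], trials[20:])
    assert np.all(np.abs(model.eigvals_pos - 0.5) < 0.1)


def test_csp_transform_identity_filters_log_variance():
    eeg = np.zeros((2, 3))
    eeg[0] = [-1, 0, 1]                      # sample variance 1
    eeg[1] = np.array([-1, 0, 1]) * np.sqrt(np.e)   # sample variance e
    model = CSPModel(W=np.eye(2), eigvals_pos=np.array([1.0, 0.0]))
    feats = csp_transform(eeg, model, f=1)
    np.testing.assert_allclose(feats, [0.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("f,expected", [(1, 2), (4, 8), (8, 16)])
def test_csp_feature_count(f, expected, rng):
    trials = [rng.standard_normal((16, 100)) for _ in range(8)]
    model = csp_fit(trials[:4], trials[4:])
    assert csp_transform(trials[0], model, f).size == expected


def test_csp_transform_scale_invariance_up_to_shift(rng):
    """Scaling a trial by c shifts every log-variance by 2 log c."""
    trials = [rng.standard_normal((4, 120)) for _ in range(8)]
    model = csp_fit(trials[:4], trials[4:])
    x = rng.standard_normal((4, 120))
    base = csp_transform(x, model, f=2)
    scaled = csp_transform(3.0 * x, model, f=2)
    np.testing.assert_allclose(scaled - base, 2 * np.log(3.0), atol=1e-10)


def test_csp_requires_enough_trials(rng):
    with pytest.raises(ValueError):
        csp_fit([rng.standard_normal((4, 50))], [rng.standard_normal((4, 50))])


# ---------------------------------------------------------------------------
# template matching
# ---------------------------------------------------------------------------

def test_template_fit_averages_per_electrode(rng):
    t1 = rng.standard_normal((16, 64))
    t2 = rng.standard_normal((16, 64))
    bank = template_fit({"task1": [t1, t2], "task2": [t1]})
    np.testing.assert_allclose(bank.templates["task1"], (t1 + t2) / 2)
    np.testing.assert_allclose(bank.templates["task2"], t1)
    assert all(v.shape[0] == 16 for v in bank.templates.values())
    # opposite trials cancel
    bank0 = template_fit({"task1": [t1, -t1], "task2": [t2]})
    np.testing.assert_allclose(bank0.templates["task1"], 0.0, atol=1e-12)


def test_template_transform_feature_count_and_self_match(rng):
    x = rng.standard_normal((16, 64))
    y = rng.standard_normal((16, 64))
    bank = template_fit({"task1": [x], "task2": [y]})
    feats = template_transform(x, bank)
    assert feats.size == 32
    # trial identical to class-1 templates: normalized autocorrelation is 1
    np.testing.assert_allclose(feats[:16], 1.0, atol=1e-10)


def test_template_transform_matches_all_lag_loop(rng):
    """Normalized max cross-correlation equals an explicit loop over lags."""
    for _ in range(5):
        x = rng.standard_normal(64)
        t = rng.standard_normal(48)
        got = max_normalized_xcorr(x, t)
        best = -np.inf
        # full correlation: all displacements of t against x
        for lag in range(-(t.size - 1), x.size):
            lo, hi = max(0, lag), min(x.size, lag + t.size)
            seg_x = x[lo:hi]
            seg_t = t[lo - lag:hi - lag]
            best = max(best, float(np.dot(seg_x, seg_t)))
        best /= np.linalg.norm(x) * np.linalg.norm(t)
        assert abs(got - best) < 1e-10


def test_template_delayed_sinusoid_recovers_unit_correlation():
    n = 256
    t = np.arange(n)
    period = 32
    tpl = np.sin(2 * np.pi * t / period)
    delayed = np.sin(2 * np.pi * (t - 7) / period)
    # identical energy, pure delay: best lag realigns them almost perfectly
    got = max_normalized_xcorr(delayed, tpl)
    assert got > 0.97
    # zero-energy input defined as 0
    assert max_normalized_xcorr(np.zeros(16), tpl[:16]) == 0.0


# ---------------------------------------------------------------------------
# fTCD wavelet statistics
# ---------------------------------------------------------------------------

def test_wavelet_features_shape_and_bands(rng):
    seg = rng.standard_normal(1000)
    bands = wavelet_subbands(seg)
    assert len(bands) == 6
    trial = _trial(rng.standard_normal((16, 2560)),
                   np.vstack([seg, seg]))
    feats = ftcd_wavelet_features(trial)
    assert feats.size == 48
    # left and right segments identical -> identical feature halves
    np.testing.assert_allclose(feats[:24], feats[24:])


def test_wavelet_perfect_reconstruction(rng):
    """The six sub-bands reassemble to the original segment."""
    seg = rng.standard_normal(512)
    bands = wavelet_subbands(seg)
    coeffs = [bands[5]] + bands[:5][::-1]     # A5, D5..D1
    rec = pywt.waverec(coeffs, "db4", mode="symmetric")
    np.testing.assert_allclose(rec[:seg.size], seg, atol=1e-8)


def test_wavelet_constant_segment_degenerate_moments():
    trial = _trial(np.zeros((16, 256)), np.full((2, 100), 3.0))
    feats = ftcd_wavelet_features(trial).reshape(2, 6, 4)
    # detail bands of a constant are ~0; skew/kurt zeroed by convention
    assert np.all(np.abs(feats[:, :5, 0]) < 1e-8)    # means of D1..D5
    assert np.all(feats[:, :, 1] < 1e-12)            # variances
    assert np.all(feats[:, :, 2:] == 0.0)            # skew, kurt


def test_wavelet_rejects_too_short_segment():
    with pytest.raises(ValueError):
        ftcd_wavelet_features(np.ones((2, 20)))
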