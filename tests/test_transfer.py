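"""Subject profiles, Bhattacharyya similarity and training-set augmentation."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from hybci.fusion import kde_fit
from hybci.pipeline import ProblemData, fit_decoder
from hybci.transfer import (bhattacharyya_distance, bhattacharyya_from_masses,
                            discretize_pair, profile_from_data, rank_similar,
                            select_augmentation, subject_distance,
                            tl_train_predict)


# ---------------------------------------------------------------------------
# Bhattacharyya distance
# ---------------------------------------------------------------------------

def test_identical_densities_have_zero_distance(rng):
    d = kde_fit(rng.standard_normal(40))
    assert bhattacharyya_distance(d, d) < 1e-9


def test_distance_is_symmetric_and_nonnegative(rng):
    p = kde_fit(rng.normal(0, 1, 30))
    q = kde_fit(rng.normal(1.5, 0.7, 30))
    dpq = bhattacharyya_distance(p, q)
    dqp = bhattacharyya_distance(q, p)
    assert dpq == pytest.approx(dqp, abs=1e-12)
    assert dpq > 0


def test_two_bin_hand_case():
    """P = (1, 0), Q = (.5, .5): d = -ln sqrt(0.5) ~ 0.3466."""
    d = bhattacharyya_from_masses([1.0, 0.0], [0.5, 0.5])
    assert d == pytest.approx(-np.log(np.sqrt(0.5)), abs=1e-3)
    # the literal printed form (no square root) gives -ln(0.5) instead
    d_printed = bhattacharyya_from_masses([1.0, 0.0], [0.5, 0.5], form="printed")
    assert d_printed == pytest.approx(-np.log(0.5), abs=1e-3)


def test_discretized_masses_are_normalized(rng):
    p = kde_fit(rng.normal(0, 1, 25))
    q = kde_fit(rng.normal(3, 2, 25))
    pair = discretize_pair(p, q)
    assert pair.N == 512
    assert pair.P.sum() == pytest.approx(1.0, abs=1e-9)
    assert pair.Q.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(pair.P >= 0) and np.all(pair.Q >= 0)


def test_grid_doubling_changes_distance_less_than_one_percent(rng):
    p = kde_fit(rng.normal(0, 1, 40))
    q = kde_fit(rng.normal(1, 1.3, 40))
    d512 = bhattacharyya_distance(p, q, n_grid=512)
    d1024 = bhattacharyya_distance(p, q, n_grid=1024)
    assert abs(d1024 - d512) / d512 < 0.01


# ---------------------------------------------------------------------------
# profiles and subject distance
# ---------------------------------------------------------------------------

def test_profile_holds_four_densities_and_is_deterministic(tiny_mi_data, mi_config):
    data = tiny_mi_data["S00"]
    p1 = profile_from_data(data, mi_config, "S00")
    p2 = profile_from_data(data, mi_config, "S00")
    assert len(p1.densities) == 4
    assert {m for m, _ in p1.densities} == {"EEG", "fTCD"}
    rec = subject_distance(p1, p2)
    assert rec.total == pytest.approx(0.0, abs=1e-9)


def test_subject_distance_sums_four_components(tiny_mi_data, mi_config):
    pa = profile_from_data(tiny_mi_data["S00"], mi_config, "S00")
    pb = profile_from_data(tiny_mi_data["S01"], mi_config, "S01")
    rec = subject_distance(pa, pb)
    assert len(rec.distances) == 4
    assert rec.total == pytest.approx(sum(rec.distances.values()))
    assert rec.total >= 0
    # symmetry of the total
    assert subject_distance(pb, pa).total == pytest.approx(rec.total)


def test_profile_rejects_class_with_too_few_trials(tiny_mi_data, mi_config):
    data = tiny_mi_data["S00"]
    labels = data.labels
    pos = mi_config.labels[0]
    # keep a single positive trial
    keep = np.concatenate([np.flatnonzero(labels == pos)[:1],
                           np.flatnonzero(labels != pos)])
    with pytest.raises(ValueError):
        profile_from_data(data.subset(keep), mi_config, "S00")


def test_rank_similar_orders_and_preserves_candidates(tiny_mi_data, mi_config):
    profiles = {sid: profile_from_data(d, mi_config, sid)
                for sid, d in tiny_mi_data.items()}
    current = profiles["S01"]
    candidates = [profiles["S00"], profiles["S02"]]
    ranked = rank_similar(current, candidates)
    assert {r.candidate_id for r in ranked} == {"S00", "S02"}
    assert ranked[0].total <= ranked[1].total
    # singleton candidate list
    single = rank_similar(current, [profiles["S02"]])
    assert single[0].candidate_id == "S02"
    with pytest.raises(ValueError):
        rank_similar(current, [])


# ---------------------------------------------------------------------------
# augmentation and end-to-end transfer path
# ---------------------------------------------------------------------------

def _split(data, m):
    idx = np.arange(data.n_trials)
    return data.subset(idx[:m]), data.subset(idx[m:])


def test_select_augmentation_k_bounds_and_oracle(tiny_mi_data, mi_config):
    train, _ = _split(tiny_mi_data["S00"], 8)
    candidates = [tiny_mi_data["S01"], tiny_mi_data["S02"]]
    k, scores = select_augmentation(train, candidates, mi_config, seed=0)
    assert 1 <= k <= 2 and len(scores) == 2

    # exhaustive oracle: independently rebuild each pooled set and CV-score it
    def cv_acc(data):
        y = data.labels
        folds = max(2, min(10, min(int(np.sum(y == c)) for c in np.unique(y))))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=0)
        hits = 0
        for tr, va in skf.split(np.zeros(y.size), y):
            dec = fit_decoder(data.subset(tr), mi_config)
            hits += int(np.sum(dec.predict(data.subset(va)) == y[va]))
        return hits / y.size

    oracle_scores = [cv_acc(ProblemData.concatenate([train] + candidates[:kk]))
                     for kk in (1, 2)]
    np.testing.assert_allclose(scores, oracle_scores, atol=1e-12)
    assert k == 1 + int(np.argmax(oracle_scores))


def test_single_candidate_gives_k_one(tiny_mi_data, mi_config):
    train, _ = _split(tiny_mi_data["S00"], 8)
    k, scores = select_augmentation(train, [tiny_mi_data["S01"]], mi_config)
    assert k == 1 and len(scores) == 1


def test_empty_augmentation_reduces_to_ntl(tiny_mi_data, mi_config):
    """TL with no augmentation is the plain (no-transfer) pipeline."""
    train, test = _split(tiny_mi_data["S00"], 8)
    preds_tl, pairs_tl, _ = tl_train_predict(train, [], test, mi_config)
    dec = fit_decoder(train, mi_config)
    np.testing.assert_array_equal(preds_tl, dec.predict(test))
    np.testing.assert_allclose(pairs_tl, dec.evidence_pairs(test), atol=1e-12)


def test_augmentation_never_touches_test_trials(tiny_mi_data, mi_config):
    train, test = _split(tiny_mi_data["S00"], 8)
    before = (test.labels.copy(), test.eeg_scatter.copy(),
              test.ftcd_features.copy())
    tl_train_predict(train, [tiny_mi_data["S01"]], test, mi_config)
    np.testing.assert_array_equal(test.labels, before[0])
    np.testing.assert_array_equal(test.eeg_scatter, before[1])
    np.testing.assert_array_equal(test.ftcd_features, before[2])


def test_tl_path_is_deterministic(tiny_mi_data, mi_config):
    train, test = _split(tiny_mi_data["S00"], 8)
    aug = [tiny_mi_data["S01"]]
    p1, e1, _ = tl_train_predict(train, aug, test, mi_config)
    p2, e2, _ = tl_train_predict(train, aug, test, mi_config)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(e1, e2)


def test_mismatched_paradigm_profiles_rejected(tiny_mi_data, mi_config,
                                               tiny_mrwg_cohort, mrwg_config):
    from hybci.pipeline import problem_data_for_subject
    pa = profile_from_data(tiny_mi_data["S00"], mi_config, "S00")
    data_b = problem_data_for_subject(tiny_mrwg_cohort[0], mrwg_config)
    pb = profile_from_data(data_b, mrwg_config, "X0")
    with pytest.raises(ValueError):
        subject_distance(pa, pb)
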