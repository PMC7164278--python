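"""Accuracy, information transfer rate, TL-vs-NTL sweeps and calibration
reduction.

For every (training-set size, trial length) cell, the decoder is refitted
on the first-m trials of the current subject (optionally augmented by
transfer learning) and scored on the remaining trials. Per size the maximum
over trial lengths is reported, plus the cross-evaluated series (no-transfer
performance at the transfer-optimal lengths and vice versa) so the two modes
can be compared at equal calibration length.

The calibration-reduction statistic scans training sizes m = 10, 20, ...:
the reported m is the first at which a one-sided Wilcoxon signed-rank test
no longer finds the 90-trial no-transfer accuracies better than the
m-trial transfer accuracies AND the mean transfer accuracy reaches the mean
no-transfer accuracy; the reduction percentage then compares per-subject
calibration lengths (trials x optimal trial length) between the two modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .pipeline import PipelineConfig, ProblemData, problem_data_for_subject
from .synth import SubjectDataset
from .transfer import (profile_from_data, rank_similar, select_augmentation,
                       tl_train_predict)

__all__ = ["accuracy", "itr_per_trial", "itr_per_min", "PerformanceCurve",
           "performance_curves", "ReductionResult", "calibration_reduction",
           "reduction_from_lengths", "DEFAULT_TRAIN_SIZES",
           "DEFAULT_TRIAL_LENGTHS"]

log = logging.getLogger(__name__)

DEFAULT_TRAIN_SIZES = tuple(range(10, 91, 10))
DEFAULT_TRIAL_LENGTHS = tuple(range(1, 11))
SIGNED_RANK_ALPHA = 0.05


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def accuracy(predictions, labels) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    return float(np.mean(predictions == labels))


def itr_per_trial(P_acc: float, N_selections: int = 2) -> float:
    """Bits per selection of an N-ary noisy channel at accuracy P.

    B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with 0 log 0 = 0.
    Algebraically this is the Kullback-Leibler divergence between the
    channel's output row and the uniform distribution, so B >= 0 for every
    P (it vanishes exactly at chance, P = 1/N).
    """
    if not 0.0 <= P_acc <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if N_selections < 2:
        raise ValueError("need at least 2 selections")
    N, P = N_selections, float(P_acc)
    b = np.log2(N)
    if P > 0:
        b += P * np.log2(P)
    if P < 1:
        b += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(max(b, 0.0))


def itr_per_min(B_bits: float, trial_length_s: float) -> float:
    """Scale bits/selection to bits/min at one selection per trial."""
    if trial_length_s <= 0:
        raise ValueError("trial length must be positive")
    return float(B_bits) * 60.0 / float(trial_length_s)


# ---------------------------------------------------------------------------
# TL / NTL sweeps
# ---------------------------------------------------------------------------

@dataclass
class PerformanceCurve:
    """Tidy per-cell results for one mode (``TL`` or ``NTL``).

    ``table`` columns: subject, train_size, trial_length, accuracy,
    itr_bits_per_trial, itr_bits_per_min.
    """

    mode: str
    table: pd.DataFrame

    def subject_matrix(self, value: str = "accuracy") -> pd.DataFrame:
        """(subject x train_size) of the max over trial lengths."""
        best = (self.table.groupby(["subject", "train_size"])[value]
                .max().unstack("train_size"))
        return best

    def best_lengths(self, train_size: int) -> pd.Series:
        """Per subject, the shortest trial length attaining max accuracy."""
        sub = self.table[self.table.train_size == train_size]
        def _pick(g):
            m = g.accuracy.max()
            return g[g.accuracy == m].trial_length.min()
        return sub.groupby("subject").apply(_pick, include_groups=False)

    def mean_curve(self, value: str = "accuracy") -> pd.Series:
        return self.subject_matrix(value).mean(axis=0)

    def at_lengths(self, lengths: pd.Series, train_size: int,
                   value: str = "accuracy") -> pd.Series:
        """Per-subject values at externally prescribed trial lengths."""
        sub = self.table[self.table.train_size == train_size]
        out = {}
        for subject, length in lengths.items():
            row = sub[(sub.subject == subject) & (sub.trial_length == length)]
            out[subject] = float(row[value].iloc[0])
        return pd.Series(out)


def first_m_split(data: ProblemData, m: int) -> tuple[ProblemData, ProblemData]:
    """First m trials (presentation order) train; the rest test.

    If the first m trials happen to contain fewer than 2 trials of a class
    (possible under randomized presentation), calibration is extended by
    the minimum number of trials needed — mirroring how an online protocol
    would keep recording until both classes are represented.
    """
    if not 2 <= m < data.n_trials:
        raise ValueError(f"train size {m} incompatible with {data.n_trials} trials")
    classes = np.unique(data.labels)
    while m < data.n_trials - 1 and any(
            int(np.sum(data.labels[:m] == c)) < 2 for c in classes):
        m += 1
    idx = np.arange(data.n_trials)
    return data.subset(idx[:m]), data.subset(idx[m:])


_first_m_split = first_m_split


def _evaluate_cell(rows: list, subject_id: str, data: ProblemData,
                   pool: dict, config: PipelineConfig, m: int, t_len: float,
                   seed: int, with_tl: bool) -> None:
    """One (subject, train size, trial length) cell: NTL and optionally TL."""
    train, test = _first_m_split(data, m)
    ntl_preds, _, _ = tl_train_predict(train, [], test, config)
    ntl_acc = accuracy(ntl_preds, test.labels)
    _record(rows, subject_id, "NTL", m, t_len, ntl_acc)
    if not with_tl:
        return
    profile = profile_from_data(train, config, subject_id)
    candidates = [p for sid, (_, p) in pool.items() if sid != subject_id]
    ranked = rank_similar(profile, candidates)
    ranked_data = [pool[r.candidate_id][0] for r in ranked]
    k, _ = select_augmentation(train, ranked_data, config, seed=seed)
    tl_preds, _, _ = tl_train_predict(train, ranked_data[:k], test, config)
    tl_acc = accuracy(tl_preds, test.labels)
    _record(rows, subject_id, "TL", m, t_len, tl_acc)
    log.info("subject=%s size=%d len=%gs k=%d ntl=%.3f tl=%.3f",
             subject_id, m, t_len, k, ntl_acc, tl_acc)


def evaluate_subject(current: SubjectDataset, others: list[SubjectDataset],
                     config: PipelineConfig,
                     train_sizes=DEFAULT_TRAIN_SIZES,
                     trial_lengths=DEFAULT_TRIAL_LENGTHS,
                     seed: int = 0,
                     with_tl: bool = True) -> pd.DataFrame:
    """TL and NTL accuracy/ITR for one left-out subject over the whole grid."""
    rows: list = []
    for t_len in trial_lengths:
        data = problem_data_for_subject(current, config, t_seconds=t_len)
        pool = {}
        if with_tl:
            for o in others:
                d = problem_data_for_subject(o, config, t_seconds=t_len)
                pool[o.subject_id] = (d, profile_from_data(d, config, o.subject_id))
        for m in train_sizes:
            _evaluate_cell(rows, current.subject_id, data, pool, config,
                           m, t_len, seed, with_tl)
    return pd.DataFrame(rows)


def _record(rows: list, subject: str, mode: str, m: int, t_len: float,
            acc: float) -> None:
    b = itr_per_trial(acc, 2)
    rows.append({"subject": subject, "mode": mode, "train_size": m,
                 "trial_length": t_len, "accuracy": acc,
                 "itr_bits_per_trial": b,
                 "itr_bits_per_min": itr_per_min(b, t_len)})


def performance_curves(cohort: list[SubjectDataset], config: PipelineConfig,
                       train_sizes=DEFAULT_TRAIN_SIZES,
                       trial_lengths=DEFAULT_TRIAL_LENGTHS,
                       seed: int = 0) -> tuple[PerformanceCurve, PerformanceCurve]:
    """Leave-one-subject-out sweep over the whole cohort.

    Every subject in turn is the current user; the remaining subjects are
    the prior-user pool. Returns the (TL, NTL) curves.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    rows: list = []
    for t_len in trial_lengths:
        # each subject's full problem data and prior-user profile are shared
        # across all leave-one-out evaluations at this trial length
        pool = {}
        datas = {}
        for ds in cohort:
            d = problem_data_for_subject(ds, config, t_seconds=t_len)
            datas[ds.subject_id] = d
            pool[ds.subject_id] = (d, profile_from_data(d, config, ds.subject_id))
        for ds in cohort:
            for m in train_sizes:
                _evaluate_cell(rows, ds.subject_id, datas[ds.subject_id], pool,
                               config, m, t_len, seed, with_tl=True)
    table = pd.DataFrame(rows)
    return (PerformanceCurve("TL", table[table["mode"] == "TL"].copy()),
            PerformanceCurve("NTL", table[table["mode"] == "NTL"].copy()))


# ---------------------------------------------------------------------------
# calibration reduction
# ---------------------------------------------------------------------------

def reduction_from_lengths(N: int, ntl_lengths, m: int, tl_lengths) -> float:
    """Mean per-subject reduction of calibration length, in percent.

    Per subject i: (N * len_NTL(i) - m * len_TL(i)) / (N * len_NTL(i)).
    """
    ntl_lengths = np.asarray(ntl_lengths, float)
    tl_lengths = np.asarray(tl_lengths, float)
    if ntl_lengths.shape != tl_lengths.shape or ntl_lengths.size == 0:
        raise ValueError("length vectors must be equal-size and non-empty")
    num = N * ntl_lengths - m * tl_lengths
    return float(np.mean(num / (N * ntl_lengths)) * 100.0)


def reduction_from_calibration_lengths(cal_ntl, cal_tl) -> float:
    """Equivalent form on raw calibration lengths (trials x seconds)."""
    cal_ntl = np.asarray(cal_ntl, float)
    cal_tl = np.asarray(cal_tl, float)
    return float(np.mean((cal_ntl - cal_tl) / cal_ntl) * 100.0)


@dataclass
class ReductionResult:
    m: int | None                    # qualifying training size (None: none found)
    reduction_pct: float
    N: int
    p_values: dict = field(default_factory=dict)
    mean_tl_at_m: float | None = None
    mean_ntl_at_N: float | None = None


def _one_sided_p(ntl_ref: np.ndarray, tl_m: np.ndarray) -> float:
    """P-value of 'NTL at full calibration beats TL at m' (signed rank)."""
    diff = ntl_ref - tl_m
    if np.allclose(diff, 0):
        return 1.0
    try:
        return float(wilcoxon(ntl_ref, tl_m, alternative="greater",
                              zero_method="zsplit").pvalue)
    except ValueError:
        return 1.0


def calibration_reduction(tl_curve: PerformanceCurve,
                          ntl_curve: PerformanceCurve,
                          alpha: float = SIGNED_RANK_ALPHA) -> ReductionResult:
    """Scan training sizes for the first m at which TL matches full-data NTL."""
    tl_acc = tl_curve.subject_matrix("accuracy")
    ntl_acc = ntl_curve.subject_matrix("accuracy")
    sizes = sorted(tl_acc.columns)
    N = max(ntl_acc.columns)
    ntl_ref = ntl_acc[N]
    p_values = {}
    chosen = None
    for m in sizes:
        tl_m = tl_acc[m].reindex(ntl_ref.index)
        p = _one_sided_p(ntl_ref.to_numpy(), tl_m.to_numpy())
        p_values[m] = p
        # "similar to or outperforms": the mean TL accuracy at m must reach
        # the mean full-calibration NTL accuracy up to one standard error of
        # the paired difference
        diff = (ntl_ref - tl_m).to_numpy()
        se = float(np.std(diff, ddof=1) / np.sqrt(diff.size)) if diff.size > 1 else 0.0
        if p >= alpha and tl_m.mean() >= ntl_ref.mean() - se:
            chosen = m
            break
    if chosen is None:
        log.warning("no training size lets TL match full-calibration NTL")
        return ReductionResult(m=None, reduction_pct=0.0, N=int(N),
                               p_values=p_values,
                               mean_ntl_at_N=float(ntl_ref.mean()))
    ntl_lengths = ntl_curve.best_lengths(N).reindex(ntl_ref.index)
    tl_lengths = tl_curve.best_lengths(chosen).reindex(ntl_ref.index)
    red = reduction_from_lengths(int(N), ntl_lengths.to_numpy(),
                                 int(chosen), tl_lengths.to_numpy())
    return ReductionResult(m=int(chosen), reduction_pct=red, N=int(N),
                           p_values=p_values,
                           mean_tl_at_m=float(tl_acc[chosen].mean()),
                           mean_ntl_at_N=float(ntl_ref.mean()))
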