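"""Study-scale experiment drivers.

These functions run the transfer-learning study end to end on synthetic
cohorts at the study's recording scale (10 subjects, 150 ten-second trials
each, one planted near-identical "clone" pair) and are shared by the
reproducibility script and the statistical test suite.

Problem sizes: similarity and transfer are evaluated at the full 10 s trial
length, the transfer-vs-no-transfer comparison at 10 training trials on a
fixed subset of subjects per cohort, and the calibration-reduction scan on
a few cohorts' pooled subjects over the full 10..90 training-size grid —
large enough for the statistics, small enough to run on a laptop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (PerformanceCurve, ReductionResult, accuracy,
                         calibration_reduction, first_m_split, itr_per_min,
                         itr_per_trial)
from .pipeline import PipelineConfig, problem_data_for_subject
from .synth import CohortConfig, generate_cohort
from .transfer import (profile_from_data, rank_similar, select_augmentation,
                       tl_train_predict)

__all__ = ["StudyResult", "run_study", "study_cohort_config"]

log = logging.getLogger(__name__)

CLONE_PAIR = (0, 3)
#: subjects whose transfer runs enter the TL-vs-NTL comparison (a fixed
#: subset keeps the sweep affordable; one of them is a clone member)
TL_SUBJECTS = ("S00", "S04", "S07")
TRAIN_SIZES = tuple(range(10, 91, 10))


def study_cohort_config(seed: int) -> CohortConfig:
    """The study conditions: 10 subjects, 150 trials, one clone pair."""
    return CohortConfig(n_subjects=10, paradigm="MI", seed=seed,
                        clone_pairs=[CLONE_PAIR])


@dataclass
class StudyResult:
    """Aggregated outcomes of the multi-cohort synthetic study."""

    clone_hits: list = field(default_factory=list)      # per ranking run
    tl_acc_10: list = field(default_factory=list)       # per cohort mean
    ntl_acc_10: list = field(default_factory=list)
    tl_itr_10: list = field(default_factory=list)       # bits/min at 10 s
    ntl_itr_10: list = field(default_factory=list)
    reduction: ReductionResult | None = None

    @property
    def clone_top1_rate(self) -> float:
        return float(np.mean(self.clone_hits))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            ("clone_top1_rate", self.clone_top1_rate),
            ("mean_tl_accuracy_at_10", float(np.mean(self.tl_acc_10))),
            ("mean_ntl_accuracy_at_10", float(np.mean(self.ntl_acc_10))),
            ("mean_tl_itr_bits_per_min_at_10", float(np.mean(self.tl_itr_10))),
            ("mean_ntl_itr_bits_per_min_at_10", float(np.mean(self.ntl_itr_10))),
        ]
        if self.reduction is not None:
            rows += [("calibration_reduction_pct", self.reduction.reduction_pct),
                     ("qualifying_train_size", self.reduction.m or np.nan)]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def _cohort_assets(seed: int, config: PipelineConfig):
    """Generate one cohort and cache problem data + prior-user profiles."""
    cohort = generate_cohort(study_cohort_config(seed))
    datas = {ds.subject_id: problem_data_for_subject(ds, config, t_seconds=10)
             for ds in cohort}
    profiles = {sid: profile_from_data(d, config, sid)
                for sid, d in datas.items()}
    return datas, profiles


def _tl_ntl_for_subject(sid: str, m: int, datas: dict, profiles: dict,
                        config: PipelineConfig) -> tuple[float, float]:
    data = datas[sid]
    train, test = first_m_split(data, m)
    ntl_preds, _, _ = tl_train_predict(train, [], test, config)
    profile = profile_from_data(train, config, sid)
    ranked = rank_similar(profile, [p for s, p in profiles.items() if s != sid])
    ranked_data = [datas[r.candidate_id] for r in ranked]
    k, _ = select_augmentation(train, ranked_data, config, seed=config.seed)
    tl_preds, _, _ = tl_train_predict(train, ranked_data[:k], test, config)
    return (accuracy(tl_preds, test.labels), accuracy(ntl_preds, test.labels))


def run_study(cohort_seeds, *, reduction_seeds=(), config: PipelineConfig | None = None,
              tl_subjects=TL_SUBJECTS, progress=None) -> StudyResult:
    """Run the full synthetic transfer-learning study.

    For every cohort seed: check whether the planted clone is ranked most
    similar (both directions) and measure TL vs NTL accuracy at 10 training
    trials. For the cohorts in ``reduction_seeds`` additionally sweep the
    whole 10..90 training-size grid, then pool those cohorts' subjects into
    one calibration-reduction scan.
    """
    config = config or PipelineConfig(paradigm="MI",
                                      problem="task1-vs-baseline", seed=0)
    result = StudyResult()
    sweep_rows: list[dict] = []
    clone_ids = (f"S{CLONE_PAIR[0]:02d}", f"S{CLONE_PAIR[1]:02d}")
    for seed in cohort_seeds:
        datas, profiles = _cohort_assets(seed, config)
        for a, b in (clone_ids, clone_ids[::-1]):
            ranked = rank_similar(profiles[a],
                                  [p for s, p in profiles.items() if s != a])
            result.clone_hits.append(int(ranked[0].candidate_id == b))
        tl_accs, ntl_accs = [], []
        sizes = TRAIN_SIZES if seed in set(reduction_seeds) else (10,)
        for m in sizes:
            for sid in tl_subjects:
                tl, ntl = _tl_ntl_for_subject(sid, m, datas, profiles, config)
                if m == 10:
                    tl_accs.append(tl)
                    ntl_accs.append(ntl)
                if seed in set(reduction_seeds):
                    subject = f"{seed}:{sid}"
                    for mode, acc in (("TL", tl), ("NTL", ntl)):
                        b = itr_per_trial(acc, 2)
                        sweep_rows.append({
                            "subject": subject, "mode": mode, "train_size": m,
                            "trial_length": 10, "accuracy": acc,
                            "itr_bits_per_trial": b,
                            "itr_bits_per_min": itr_per_min(b, 10)})
        result.tl_acc_10.append(float(np.mean(tl_accs)))
        result.ntl_acc_10.append(float(np.mean(ntl_accs)))
        result.tl_itr_10.append(itr_per_min(itr_per_trial(np.mean(tl_accs), 2), 10))
        result.ntl_itr_10.append(itr_per_min(itr_per_trial(np.mean(ntl_accs), 2), 10))
        if progress is not None:
            progress(seed, result)
        log.info("cohort seed=%s clone_hits=%s tl10=%.3f ntl10=%.3f", seed,
                 result.clone_hits[-2:], result.tl_acc_10[-1],
                 result.ntl_acc_10[-1])
    if sweep_rows:
        table = pd.DataFrame(sweep_rows)
        tl_curve = PerformanceCurve("TL", table[table["mode"] == "TL"].copy())
        ntl_curve = PerformanceCurve("NTL", table[table["mode"] == "NTL"].copy())
        result.reduction = calibration_reduction(tl_curve, ntl_curve)
    return result
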