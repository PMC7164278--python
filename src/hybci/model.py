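"""Model/Results front door for the hybrid decoder and the transfer study.

Two levels of analysis, both in the fit-then-inspect idiom:

* :class:`HybridDecoder` — one subject's binary decoding model. ``fit()``
  trains CSP/templates, feature selection, the two projection SVMs, the
  class-conditional KDEs and (under A3) the fusion weight, and returns a
  :class:`DecoderResults` exposing predictions, evidence scores and a
  ``summary()`` table.
* :class:`TransferExperiment` — a whole-cohort leave-one-subject-out
  transfer-learning study. ``fit()`` runs the TL and no-TL sweeps over
  training sizes and trial lengths and returns :class:`TransferResults`
  with the tidy performance table, the calibration-reduction statistic,
  plotting helpers and a ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation as E
from .pipeline import (FittedDecoder, PipelineConfig, ProblemData,
                       extract_problem_data, fit_decoder,
                       problem_data_for_subject)
from .synth import SubjectDataset, TrialMatrix

__all__ = ["HybridDecoder", "DecoderResults", "TransferExperiment",
           "TransferResults"]


class HybridDecoder:
    """Hybrid EEG+fTCD Bayesian-fusion decoder for one binary problem.

    Parameters
    ----------
    trials, labels
        The subject's training trials and their condition labels; trials
        whose label does not belong to the problem are dropped.
    config
        Pipeline configuration; defaults to motor imagery, task1 vs
        baseline, A3 fusion with grid-searched alpha.
    t_seconds
        Optional truncation applied before feature extraction.
    """

    def __init__(self, trials: list[TrialMatrix], labels=None,
                 config: PipelineConfig | None = None,
                 t_seconds: float | None = None):
        self.config = config or PipelineConfig()
        self.data = extract_problem_data(list(trials), labels, self.config,
                                         t_seconds)

    @classmethod
    def from_dataset(cls, dataset: SubjectDataset,
                     problem: str = "task1-vs-baseline",
                     t_seconds: float | None = None,
                     **config_kwargs) -> "HybridDecoder":
        config = PipelineConfig(paradigm=dataset.paradigm, problem=problem,
                                **config_kwargs)
        return cls(dataset.trials, None, config, t_seconds)

    def fit(self) -> "DecoderResults":
        decoder = fit_decoder(self.data, self.config)
        return DecoderResults(self, decoder)


class DecoderResults:
    """Fitted decoder with its densities, weights and diagnostics."""

    def __init__(self, model: HybridDecoder, decoder: FittedDecoder):
        self.model = model
        self._decoder = decoder
        self.config = model.config
        self.classes = decoder.classes
        self.alpha_ = (decoder.fusion.alpha
                       if decoder.fusion.assumption == "A3" else None)
        self.assumption_ = decoder.fusion.assumption

    @property
    def densities(self) -> dict:
        return self._decoder.densities

    @property
    def train_evidence(self) -> pd.DataFrame:
        pairs = self._decoder.train_pairs
        return pd.DataFrame({"e": pairs[:, 0], "f": pairs[:, 1],
                             "label": self._decoder.train_labels})

    def predict(self, trials, labels=None, t_seconds: float | None = None) -> np.ndarray:
        data = self._as_data(trials, labels, t_seconds)
        return self._decoder.predict(data)

    def evidence(self, trials, labels=None, t_seconds: float | None = None) -> np.ndarray:
        data = self._as_data(trials, labels, t_seconds)
        return self._decoder.evidence_pairs(data)

    def score(self, trials, labels=None, t_seconds: float | None = None) -> float:
        data = self._as_data(trials, labels, t_seconds)
        return float(np.mean(self._decoder.predict(data) == data.labels))

    def _as_data(self, trials, labels, t_seconds) -> ProblemData:
        if isinstance(trials, ProblemData):
            return trials
        return extract_problem_data(list(trials), labels, self.config, t_seconds)

    def training_accuracy(self) -> float:
        return self._decoder.accuracy(self.model.data)

    def summary(self) -> str:
        d = self._decoder
        lines = [
            "Hybrid EEG-fTCD decoder",
            "=" * 47,
            f"paradigm:            {self.config.paradigm}",
            f"problem:             {self.config.problem} "
            f"(+: {self.classes[0]}, -: {self.classes[1]})",
            f"n training trials:   {self.model.data.n_trials}",
            f"fusion assumption:   {self.assumption_}"
            + (f" (alpha = {self.alpha_:.2f})" if self.alpha_ is not None else ""),
        ]
        if self.config.paradigm == "MI":
            lam = d.csp_model.eigvals_pos
            f = self.config.csp_f
            lines.append(f"CSP filters:         2f = {2 * f}; "
                         f"lambda+ ends: {lam[0]:.3f} ... {lam[-1]:.3f}")
        else:
            lines.append(f"EEG features kept:   {d.eeg_mask.n_kept} / "
                         f"{d.eeg_mask.p_values.size} (rank-sum p < "
                         f"{self.config.select_p})")
        lines.append(f"fTCD features kept:  {d.ftcd_mask.n_kept} / "
                     f"{d.ftcd_mask.p_values.size} (rank-sum p < "
                     f"{self.config.select_p})")
        for key in sorted(self.densities):
            cd = self.densities[key]
            lines.append(f"KDE {key[0]:>4}|{key[1]:<12} h = {cd.bandwidth:.4f}, "
                         f"n = {cd.sample_scores.size}")
        lines.append(f"training accuracy:   {self.training_accuracy():.3f}")
        return "\n".join(lines)


class TransferExperiment:
    """Leave-one-subject-out transfer-learning study over a cohort."""

    def __init__(self, cohort: list[SubjectDataset],
                 config: PipelineConfig | None = None):
        if len(cohort) < 2:
            raise ValueError("a transfer experiment needs at least 2 subjects")
        paradigms = {ds.paradigm for ds in cohort}
        if len(paradigms) != 1:
            raise ValueError("cohort mixes paradigms")
        self.cohort = cohort
        self.config = config or PipelineConfig(paradigm=cohort[0].paradigm)
        if self.config.paradigm != cohort[0].paradigm:
            raise ValueError("config paradigm does not match cohort")

    def fit(self, train_sizes=E.DEFAULT_TRAIN_SIZES,
            trial_lengths=E.DEFAULT_TRIAL_LENGTHS,
            seed: int = 0) -> "TransferResults":
        tl, ntl = E.performance_curves(self.cohort, self.config,
                                       train_sizes, trial_lengths, seed)
        return TransferResults(self, tl, ntl)


class TransferResults:
    """TL/NTL performance curves and the calibration-reduction statistic."""

    def __init__(self, experiment: TransferExperiment,
                 tl_curve: E.PerformanceCurve, ntl_curve: E.PerformanceCurve):
        self.experiment = experiment
        self.tl_curve = tl_curve
        self.ntl_curve = ntl_curve

    @property
    def performance(self) -> pd.DataFrame:
        return pd.concat([self.tl_curve.table, self.ntl_curve.table],
                         ignore_index=True)

    def reduction(self, alpha: float = E.SIGNED_RANK_ALPHA) -> E.ReductionResult:
        return E.calibration_reduction(self.tl_curve, self.ntl_curve, alpha)

    def mean_accuracy(self, mode: str) -> pd.Series:
        curve = self.tl_curve if mode == "TL" else self.ntl_curve
        return curve.mean_curve("accuracy")

    def summary(self) -> str:
        tl = self.mean_accuracy("TL")
        ntl = self.mean_accuracy("NTL")
        red = self.reduction()
        lines = [
            "Transfer-learning study (leave-one-subject-out)",
            "=" * 55,
            f"paradigm / problem:  {self.experiment.config.paradigm} / "
            f"{self.experiment.config.problem}",
            f"subjects:            {len(self.experiment.cohort)}",
            "",
            "mean accuracy over subjects (max over trial lengths)",
            "train size      TL       NTL",
        ]
        for m in tl.index:
            lines.append(f"{m:>10d}   {tl[m]:.3f}    {ntl[m]:.3f}")
        lines += [
            "",
            f"calibration reduction: {red.reduction_pct:.2f}% "
            f"(m = {red.m}, N = {red.N})",
        ]
        return "\n".join(lines)

    def plot(self, value: str = "accuracy", ax=None):
        """Mean TL vs NTL curve against training-set size."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for curve, style in ((self.tl_curve, "o-"), (self.ntl_curve, "s--")):
            mean = curve.mean_curve(value)
            ax.plot(mean.index, mean.values, style, label=curve.mode)
        ax.set_xlabel("training trials (current subject)")
        ax.set_ylabel(value)
        ax.legend()
        ax.figure.tight_layout()
        return ax
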