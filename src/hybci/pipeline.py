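"""End-to-end decoding pipeline for one binary selection problem.

Glues the stages together: modality feature extraction -> rank-sum feature
selection -> SVM score projection -> class-conditional KDEs -> Bayesian
fusion. The pipeline operates on :class:`ProblemData`, a per-trial cache of
sufficient statistics (EEG trial scatter matrices for CSP, raw EEG for
template matching, fTCD wavelet features), so that repeated refits during
cross-validation and transfer-learning sweeps do not re-read raw signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import features as F
from .evidence import ScoreProjector, SelectionMask, ranksum_select
from .fusion import FusionConfig, alpha_search, fuse_classify_arrays, kde_fit
from .synth import SubjectDataset, TrialMatrix

__all__ = ["PipelineConfig", "ProblemData", "FittedDecoder", "fit_decoder",
           "extract_problem_data", "PROBLEMS"]

#: the three binary selection problems per paradigm, as (positive, negative)
PROBLEMS = {
    "task1-vs-baseline": ("task1", "baseline"),
    "task2-vs-baseline": ("task2", "baseline"),
    "task1-vs-task2": ("task1", "task2"),
}


@dataclass
class PipelineConfig:
    """Every tunable of the decoding pipeline, with study defaults."""

    paradigm: str = "MI"
    problem: str = "task1-vs-baseline"
    csp_f: int = 1                   # eigenvector pairs from each end of W
    xcorr_mode: str = "normalized"
    select_p: float = 0.05
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    kde_rule: str = "silverman_simple"
    assumption: str | None = None    # None -> paradigm default (MI: A3, MRWG: A2)
    alpha: float | None = None       # None under A3 -> grid search
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in ("MI", "MRWG"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.problem not in PROBLEMS:
            raise ValueError(f"unknown problem {self.problem!r}")

    @property
    def labels(self) -> tuple[str, str]:
        return PROBLEMS[self.problem]

    @property
    def effective_assumption(self) -> str:
        if self.assumption is not None:
            return self.assumption
        return "A3" if self.paradigm == "MI" else "A2"


@dataclass
class ProblemData:
    """Cached per-trial statistics for one problem at one trial length."""

    labels: np.ndarray               # (n,) condition strings
    eeg_scatter: np.ndarray          # (n, 16, 16) raw R R^T
    eeg_mean: np.ndarray             # (n, 16) channel means
    n_samples: int                   # EEG samples per trial at this length
    ftcd_features: np.ndarray        # (n, 48) wavelet statistics
    eeg_raw: list | None = None      # raw EEG (MRWG template path only)
    subject_ids: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.labels.size

    def subset(self, idx) -> "ProblemData":
        idx = np.asarray(idx)
        return ProblemData(
            labels=self.labels[idx],
            eeg_scatter=self.eeg_scatter[idx],
            eeg_mean=self.eeg_mean[idx],
            n_samples=self.n_samples,
            ftcd_features=self.ftcd_features[idx],
            eeg_raw=None if self.eeg_raw is None else [self.eeg_raw[i] for i in idx],
            subject_ids=None if self.subject_ids is None else self.subject_ids[idx],
        )

    @staticmethod
    def concatenate(parts: list["ProblemData"]) -> "ProblemData":
        if len({p.n_samples for p in parts}) != 1:
            raise ValueError("cannot combine trials of different lengths")
        raw = None
        if all(p.eeg_raw is not None for p in parts):
            raw = [m for p in parts for m in p.eeg_raw]
        sids = None
        if all(p.subject_ids is not None for p in parts):
            sids = np.concatenate([p.subject_ids for p in parts])
        return ProblemData(
            labels=np.concatenate([p.labels for p in parts]),
            eeg_scatter=np.concatenate([p.eeg_scatter for p in parts]),
            eeg_mean=np.concatenate([p.eeg_mean for p in parts]),
            n_samples=parts[0].n_samples,
            ftcd_features=np.concatenate([p.ftcd_features for p in parts]),
            eeg_raw=raw,
            subject_ids=sids,
        )


def extract_problem_data(trials: list[TrialMatrix], labels: list[str] | None,
                         config: PipelineConfig,
                         t_seconds: float | None = None,
                         subject_id: str | None = None) -> ProblemData:
    """Truncate, filter to the problem's two conditions and cache statistics."""
    if labels is None:
        labels = [t.label for t in trials]
    pos, neg = config.labels
    keep = [(t, l) for t, l in zip(trials, labels) if l in (pos, neg)]
    if not keep:
        raise ValueError("no trials belong to the requested problem")
    scatters, means, ftcd_rows, labs, raws = [], [], [], [], []
    n_samples = None
    for trial, lab in keep:
        if t_seconds is not None:
            trial = F.truncate_trial(trial, t_seconds)
        eeg = trial.eeg
        n_samples = eeg.shape[1]
        scatters.append(eeg @ eeg.T)
        means.append(eeg.mean(axis=1))
        ftcd_rows.append(F.ftcd_wavelet_features(trial))
        labs.append(lab)
        if config.paradigm == "MRWG":
            raws.append(eeg)
    n = len(labs)
    return ProblemData(
        labels=np.asarray(labs),
        eeg_scatter=np.asarray(scatters),
        eeg_mean=np.asarray(means),
        n_samples=n_samples,
        ftcd_features=np.asarray(ftcd_rows),
        eeg_raw=raws if config.paradigm == "MRWG" else None,
        subject_ids=None if subject_id is None else np.asarray([subject_id] * n),
    )


def problem_data_for_subject(dataset: SubjectDataset, config: PipelineConfig,
                             t_seconds: float | None = None) -> ProblemData:
    return extract_problem_data(dataset.trials, None, config, t_seconds,
                                subject_id=dataset.subject_id)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class _FeatureStage:
    """Feature extraction + selection + projection, fitted on one trial set."""

    csp_model: F.CSPModel | None
    template_bank: F.TemplateBank | None
    eeg_mask: SelectionMask | None
    ftcd_mask: SelectionMask
    eeg_projector: ScoreProjector
    ftcd_projector: ScoreProjector

    def eeg_features(self, data: ProblemData, config: "PipelineConfig") -> np.ndarray:
        if config.paradigm == "MI":
            return _csp_log_variances(data, self.csp_model, config.csp_f)
        X = np.asarray([F.template_transform(eeg, self.template_bank,
                                             mode=config.xcorr_mode)
                        for eeg in data.eeg_raw])
        return self.eeg_mask.apply(X)

    def raw_pairs(self, data: ProblemData, config: "PipelineConfig") -> np.ndarray:
        e = self.eeg_projector.decision_values(self.eeg_features(data, config))
        f = self.ftcd_projector.decision_values(
            self.ftcd_mask.apply(data.ftcd_features))
        return np.column_stack([e, f])


def _fit_stage(train: ProblemData, config: "PipelineConfig") -> _FeatureStage:
    pos, neg = config.labels
    y = train.labels
    csp_model = None
    template_bank = None
    eeg_mask = None
    if config.paradigm == "MI":
        csp_model = F.csp_fit_from_covariances(
            _avg_normalized_cov(train, y == pos),
            _avg_normalized_cov(train, y == neg),
            class_order=(pos, neg))
        X_eeg = _csp_log_variances(train, csp_model, config.csp_f)
    else:
        template_bank = F.template_fit({
            pos: [train.eeg_raw[i] for i in np.flatnonzero(y == pos)],
            neg: [train.eeg_raw[i] for i in np.flatnonzero(y == neg)],
        })
        X_full = np.asarray([
            F.template_transform(eeg, template_bank, mode=config.xcorr_mode)
            for eeg in train.eeg_raw])
        eeg_mask = ranksum_select(X_full, y, config.select_p)
        X_eeg = eeg_mask.apply(X_full)

    ftcd_mask = ranksum_select(train.ftcd_features, y, config.select_p)
    X_ftcd = ftcd_mask.apply(train.ftcd_features)

    eeg_proj = ScoreProjector(config.svm_kernel, config.svm_C).fit(
        X_eeg, y, positive_label=pos)
    ftcd_proj = ScoreProjector(config.svm_kernel, config.svm_C).fit(
        X_ftcd, y, positive_label=pos)
    return _FeatureStage(csp_model=csp_model, template_bank=template_bank,
                         eeg_mask=eeg_mask, ftcd_mask=ftcd_mask,
                         eeg_projector=eeg_proj, ftcd_projector=ftcd_proj)


def _stage_norm(stage: _FeatureStage, train_part: ProblemData,
                config: "PipelineConfig") -> tuple[np.ndarray, np.ndarray]:
    """Negative-class center and spread of one stage's training scores.

    Mapping scores through (x - center) / spread expresses them as
    separations from the reference class in its noise units; the affine map
    is common to both classes, hence decision-neutral, and it makes scores
    comparable across folds and across subjects.
    """
    neg = config.labels[1]
    raw = stage.raw_pairs(train_part, config)
    rows = train_part.labels == neg
    center = raw[rows].mean(axis=0)
    scale = np.array([max(float(np.std(raw[rows, j], ddof=1)), 1e-12)
                      for j in range(2)])
    return center, scale


def _oof_pairs(train: ProblemData, config: "PipelineConfig",
               n_folds: int = 10) -> tuple[np.ndarray, list]:
    """Out-of-fold, fold-normalized evidence pairs for every training row.

    The whole feature stage (CSP or templates, selection masks, projection
    SVMs) is refit on each fold's training part, so the scores carry no
    training optimism from any data-driven stage; each fold's scores are
    normalized by that fold's reference-class spread so fold outputs are
    commensurable. Returns the pairs and the fitted (stage, scales) folds.
    """
    y = train.labels
    min_class = min(int(np.sum(y == c)) for c in np.unique(y))
    if min_class < 4:
        # too few trials to guarantee 2 per class in every fold-train part;
        # fall back to (biased) self-scored training evidences
        stage = _fit_stage(train, config)
        center, scale = _stage_norm(stage, train, config)
        out = (stage.raw_pairs(train, config) - center) / scale
        return out, [(stage, center, scale)]
    n_folds = max(2, min(n_folds, min_class))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    out = np.zeros((y.size, 2))
    folds = []
    for tr, va in skf.split(np.zeros(y.size), y):
        part = train.subset(tr)
        stage = _fit_stage(part, config)
        center, scale = _stage_norm(stage, part, config)
        out[va] = (stage.raw_pairs(train.subset(va), config) - center) / scale
        folds.append((stage, center, scale))
    return out, folds

def _csp_log_variances(data: ProblemData, model: F.CSPModel, f: int) -> np.ndarray:
    """2f log-variance features from cached scatter matrices.

    The sample variance of the filtered signal w^T R equals
    w^T C w / (T - 1) with C the channel-mean-centered scatter, recovered
    from the cached raw scatter as R R^T - T mu mu^T.
    """
    idx = F.csp_filter_indices(model.n_channels, f)
    Wf = model.W[:, idx]                       # (16, 2f)
    T = data.n_samples
    centered = data.eeg_scatter - T * np.einsum(
        "ni,nj->nij", data.eeg_mean, data.eeg_mean)
    var = np.einsum("ia,nik,ka->na", Wf, centered, Wf) / (T - 1)
    return np.log(np.maximum(var, F.LOG_VAR_FLOOR))


def _avg_normalized_cov(data: ProblemData, mask: np.ndarray) -> np.ndarray:
    s = data.eeg_scatter[mask]
    tr = np.trace(s, axis1=1, axis2=2)
    return np.mean(s / tr[:, None, None], axis=0)


@dataclass
class FittedDecoder:
    """A fully trained decoding pipeline for one binary problem."""

    config: PipelineConfig
    classes: tuple[str, str]
    csp_model: F.CSPModel | None
    template_bank: F.TemplateBank | None
    eeg_mask: SelectionMask | None
    ftcd_mask: SelectionMask
    eeg_projector: ScoreProjector
    ftcd_projector: ScoreProjector
    #: fitted (stage, center, scale) per cross-validation fold; test
    #: evidences are the fold-ensemble average of normalized decision
    #: values, matching the units of the out-of-fold training scores the
    #: KDEs were fit on
    folds: list
    #: honest re-anchoring affine (from pooled out-of-fold reference scores)
    global_center: np.ndarray
    global_scale: np.ndarray
    densities: dict
    fusion: FusionConfig
    train_pairs: np.ndarray = field(repr=False, default=None)
    train_labels: np.ndarray = field(repr=False, default=None)

    def evidence_pairs(self, data: ProblemData) -> np.ndarray:
        """(n, 2) array of normalized (EEG, fTCD) evidence scores."""
        acc = np.zeros((data.n_trials, 2))
        for stage, center, scale in self.folds:
            acc += (stage.raw_pairs(data, self.config) - center) / scale
        return _soft_bound(
            (acc / len(self.folds) - self.global_center) / self.global_scale)

    def predict(self, data: ProblemData) -> np.ndarray:
        pairs = self.evidence_pairs(data)
        return fuse_classify_arrays(pairs[:, 0], pairs[:, 1], self.densities,
                                    self.fusion, self.classes)

    def accuracy(self, data: ProblemData) -> float:
        return float(np.mean(self.predict(data) == data.labels))


#: evidences beyond this many reference-noise units are soft-compressed;
#: separations that large are already conclusive, and bounding them keeps
#: near-separable subjects' score summaries stable
EVIDENCE_BOUND = 4.0


def _soft_bound(x: np.ndarray, cap: float = EVIDENCE_BOUND) -> np.ndarray:
    """Monotone soft clip cap*tanh(x/cap); identical for both classes,
    hence decision-neutral."""
    return cap * np.tanh(np.asarray(x, dtype=float) / cap)


def fit_decoder(train: ProblemData, config: PipelineConfig) -> FittedDecoder:
    """Fit every stage of the pipeline on one training set."""
    pos, neg = config.labels
    y = train.labels
    if np.sum(y == pos) < 2 or np.sum(y == neg) < 2:
        raise ValueError("need at least 2 training trials per class")

    stage = _fit_stage(train, config)

    # evidence scores of the training trials are computed out-of-fold (the
    # whole feature stage refit per fold) so the class-conditional densities
    # reflect out-of-sample separability rather than training optimism,
    # which saturates for any subject
    pairs, folds = _oof_pairs(train, config)
    # the per-fold affine map uses fold-train statistics, which are slightly
    # optimistic; re-anchor on the honest pooled out-of-fold reference-class
    # scores so the reference class sits at (0, 1) out of sample
    neg_rows = y == neg
    global_center = pairs[neg_rows].mean(axis=0)
    global_scale = np.array([
        max(float(np.std(pairs[neg_rows, j], ddof=1)), 1e-12) for j in range(2)])
    pairs = _soft_bound((pairs - global_center) / global_scale)

    densities = {}
    for c in (pos, neg):
        m = y == c
        densities[("EEG", c)] = kde_fit(pairs[m, 0], config.kde_rule)
        densities[("fTCD", c)] = kde_fit(pairs[m, 1], config.kde_rule)

    assumption = config.effective_assumption
    if assumption == "A3":
        alpha = config.alpha
        if alpha is None:
            min_class = min(int(np.sum(y == c)) for c in (pos, neg))
            if pairs.shape[0] >= 10 and min_class >= 3:
                alpha = alpha_search(pairs, y, seed=config.seed,
                                     rule=config.kde_rule)
            else:
                alpha = 0.5    # too few pairs to tune: equal weighting
        fusion = FusionConfig(assumption="A3", alpha=alpha)
    else:
        fusion = FusionConfig(assumption="A2")

    return FittedDecoder(
        config=config, classes=(pos, neg), csp_model=stage.csp_model,
        template_bank=stage.template_bank, eeg_mask=stage.eeg_mask,
        ftcd_mask=stage.ftcd_mask, eeg_projector=stage.eeg_projector,
        ftcd_projector=stage.ftcd_projector,
        folds=folds, global_center=global_center, global_scale=global_scale,
        densities=densities, fusion=fusion,
        train_pairs=pairs, train_labels=y.copy(),
    )
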