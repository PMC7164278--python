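"""Synthetic multi-subject EEG + fTCD cohort generator.

Emulates the two presentation paradigms of a hybrid motor-imagery /
flickering mental-rotation–word-generation BCI study:

* ``MI`` — task trials carry an 8–12 Hz band-limited source mixed into
  lateralized, class-specific channel subsets on top of 1/f + white noise,
  so the class-conditional spatial covariances differ (CSP-separable);
  baseline trials carry noise only.
* ``MRWG`` — task trials carry steady-state oscillations at 7 Hz (task 1,
  mental rotation) or 17 Hz (task 2, word generation) over parieto-occipital
  channels (template-separable); baseline trials carry noise only.

fTCD velocity envelopes on two segments (left/right transducer) combine a
pulsatile cardiac component (~1 Hz), slow class-dependent flow modulation
(lateralized between the two segments) and white noise, so class-dependent
sub-band energy is recoverable by wavelet statistics.

Each subject draws its own latent parameters (spatial patterns, amplitudes,
noise levels, flow contrasts) from cohort-level hyperparameters; ``clone``
pairs share parameters up to a small jitter, providing planted
highly-similar subjects for transfer-learning recovery experiments.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CHANNEL_NAMES",
    "TrialMatrix",
    "SubjectDataset",
    "CohortHyperparams",
    "CohortConfig",
    "generate_subject",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "cohort_manifest",
]

CONDITIONS = ("task1", "task2", "baseline")

#: 16-channel montage (frontal to parietal).
CHANNEL_NAMES = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "Fc1", "Fc2", "Cz",
    "C1", "C2", "Cp3", "Cp4", "P1", "P2", "P5", "P6",
)

# Channel groups used to build spatial patterns.
_LEFT_MOTOR = np.array([5, 8, 10])    # Fc1, C1, Cp3
_RIGHT_MOTOR = np.array([6, 9, 11])   # Fc2, C2, Cp4
_PARIETAL = np.array([12, 13, 14, 15])  # P1, P2, P5, P6


@dataclass
class TrialMatrix:
    """One labelled trial: 16-channel EEG plus left/right fTCD envelopes."""

    eeg: np.ndarray          # (16, n_samples)
    ftcd: np.ndarray         # (2, n_ftcd_samples), rows = (left, right)
    label: str               # one of CONDITIONS
    eeg_rate: float = 256.0  # samples/s
    ftcd_rate: float = 100.0  # samples/s

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.ftcd = np.asarray(self.ftcd, dtype=float)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != 16:
            raise ValueError(f"EEG must be 16 x samples, got {self.eeg.shape}")
        if self.ftcd.ndim != 2 or self.ftcd.shape[0] != 2:
            raise ValueError(f"fTCD must be 2 x samples, got {self.ftcd.shape}")
        if self.label not in CONDITIONS:
            raise ValueError(f"label must be one of {CONDITIONS}, got {self.label!r}")
        if self.eeg_rate <= 0 or self.ftcd_rate <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate


@dataclass
class SubjectDataset:
    """One subject's randomized trial sequence with its latent parameters."""

    subject_id: str
    paradigm: str                     # "MI" or "MRWG"
    trials: list[TrialMatrix]
    generative_params: dict

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def trials_for_problem(self, problem: tuple[str, str]) -> tuple[list[TrialMatrix], list[str]]:
        """Trials (in presentation order) belonging to a binary problem."""
        pos, neg = problem
        keep = [t for t in self.trials if t.label in (pos, neg)]
        return keep, [t.label for t in keep]


@dataclass
class CohortHyperparams:
    """Cohort-level means/spreads of the per-subject latent parameters.

    Amplitudes are in the same arbitrary units as the unit-RMS noise floor;
    every downstream stage is scale-covariant, so only ratios matter.
    """

    # EEG noise floor
    pink_noise: float = 1.0          # RMS of 1/f background per channel
    white_noise: float = 0.5         # RMS of white sensor noise per channel

    # MI paradigm: 8-12 Hz source pushed through a lateralized pattern;
    # per-subject amplitudes draw uniformly from this range (floored away
    # from zero so every subject has some learnable response)
    mi_amplitude_range: tuple[float, float] = (0.15, 1.5)
    # MRWG paradigm: SSVEP sinusoid amplitude over parietal channels
    ssvep_amplitude_range: tuple[float, float] = (0.15, 1.5)

    # How far each subject's spatial pattern deviates from the canonical one
    pattern_heterogeneity: float = 0.7

    # fTCD
    ftcd_base_flow: float = 10.0     # mean envelope level
    ftcd_pulsatility: float = 3.0    # cardiac component amplitude
    ftcd_noise: float = 1.0
    # class-dependent slow-flow modulation (uniform per-subject draw)
    ftcd_contrast_range: tuple[float, float] = (0.2, 1.5)
    # trial-to-trial drift of the overall flow level (all conditions)
    flow_drift_range: tuple[float, float] = (0.25, 0.9)

    # attention dynamics: subject-level ranges of the lapse probability and
    # of the trial-to-trial engagement variability; engagement is skewed
    # (right- or left-skewed lognormal), with the direction a stable
    # subject trait
    lapse_rate_range: tuple[float, float] = (0.0, 0.3)
    engagement_cv_range: tuple[float, float] = (0.1, 0.3)

    # relative jitter applied within clone pairs
    clone_jitter: float = 0.02

    def scaled_contrast(self, factor: float) -> "CohortHyperparams":
        """Copy with every class-contrast range scaled by ``factor``."""
        out = CohortHyperparams(**asdict(self))
        out.mi_amplitude_range = tuple(factor * v for v in self.mi_amplitude_range)
        out.ssvep_amplitude_range = tuple(
            factor * v for v in self.ssvep_amplitude_range)
        out.ftcd_contrast_range = tuple(
            factor * v for v in self.ftcd_contrast_range)
        return out


@dataclass
class CohortConfig:
    n_subjects: int = 10
    paradigm: str = "MI"
    hyperparams: CohortHyperparams = field(default_factory=CohortHyperparams)
    clone_pairs: Sequence[tuple[int, int]] = ()
    seed: int = 0
    trials_per_condition: int = 50
    trial_seconds: float = 10.0
    eeg_rate: float = 256.0
    ftcd_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.paradigm not in ("MI", "MRWG"):
            raise ValueError(f"paradigm must be 'MI' or 'MRWG', got {self.paradigm!r}")
        if self.trials_per_condition < 1 or self.trial_seconds <= 0:
            raise ValueError("trial counts and duration must be positive")
        if self.eeg_rate <= 0 or self.ftcd_rate <= 0:
            raise ValueError("sampling rates must be positive")
        for a, b in self.clone_pairs:
            if not (0 <= a < self.n_subjects and 0 <= b < self.n_subjects) or a == b:
                raise ValueError(f"invalid clone pair ({a}, {b})")


# ---------------------------------------------------------------------------
# latent subject parameters
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _base_pattern(idx: np.ndarray) -> np.ndarray:
    p = np.zeros(16)
    p[idx] = 1.0
    return _unit(p)


def _interp(lo: float, hi: float, q: float) -> float:
    return lo + q * (hi - lo)


def draw_subject_params(config: CohortConfig, rng: np.random.Generator,
                        quantiles: dict | None = None) -> dict:
    """Draw one subject's latent generative parameters from the cohort priors.

    ``quantiles`` optionally pins the four response dimensions (source
    amplitude, flow contrast, lapse rate, flow laterality) to given
    quantiles of their ranges; :func:`generate_cohort` uses this to place
    subjects on a space-filling design. Without it all draws are
    independent uniforms.
    """
    h = config.hyperparams
    het = h.pattern_heterogeneity
    q = quantiles or {k: rng.uniform() for k in
                      ("amplitude", "contrast", "lapse", "drift")}
    amp_range = (h.mi_amplitude_range if config.paradigm == "MI"
                 else h.ssvep_amplitude_range)
    params: dict = {
        "pink_noise": h.pink_noise * rng.uniform(0.9, 1.1),
        "white_noise": h.white_noise * rng.uniform(0.9, 1.1),
        "heart_rate": rng.uniform(0.9, 1.25),      # Hz
        "ftcd_contrast": _interp(*h.ftcd_contrast_range, q["contrast"]),
        # per-side asymmetry of the task flow response: task1 favours left MCA
        "ftcd_laterality": rng.uniform(0.2, 0.6),
        # attention model: on a lapse trial the task response is absent in
        # both modalities; otherwise the response scales with a per-trial
        # engagement factor of coefficient of variation `engagement_cv`
        "lapse_rate": _interp(*h.lapse_rate_range, q["lapse"]),
        "engagement_cv": rng.uniform(*h.engagement_cv_range),
        # stable direction of the engagement-strength skew (+1: occasional
        # unusually strong responses; -1: occasional unusually weak ones)
        "engagement_skew": float(rng.choice([-1.0, 1.0])),
        # slow physiological drift of the overall flow level, per trial;
        # anchors the baseline-condition score spread in real variability
        # and sets the fTCD noise floor. Drift excursions are asymmetric,
        # with a stable subject-specific skew.
        "flow_drift": _interp(*h.flow_drift_range, q["drift"]),
        "flow_drift_skew": rng.uniform(-4.0, 4.0),
        "source_amplitude": _interp(*amp_range, q["amplitude"]),
    }
    if config.paradigm == "MI":
        params["pattern_task1"] = _unit(
            _base_pattern(_LEFT_MOTOR) + het * rng.standard_normal(16) / 4.0)
        params["pattern_task2"] = _unit(
            _base_pattern(_RIGHT_MOTOR) + het * rng.standard_normal(16) / 4.0)
    else:
        base = _base_pattern(_PARIETAL)
        params["pattern_task1"] = _unit(base + het * rng.standard_normal(16) / 4.0)
        params["pattern_task2"] = _unit(base + het * rng.standard_normal(16) / 4.0)
    return params


#: strides of the rank-1 lattice used to spread subjects over the response
#: space; pairwise, any two subjects then differ substantially in at least
#: one dimension (wrapped separation >= 3/n for n = 10). The four dimensions
#: are the ones that dominate the evidence-score geometry: EEG source
#: amplitude, flow contrast, lapse rate and flow drift (the latter sets the
#: fTCD noise floor, so contrast/drift jointly fix fTCD separability).
_LATTICE_STRIDES = {"amplitude": 1, "contrast": 3, "lapse": 7, "drift": 9}


def _cohort_quantiles(n_subjects: int, rng: np.random.Generator) -> list[dict]:
    """Randomized rank-1 lattice: space-filling subject placement.

    Each dimension gets a random rotation, so cohorts differ across seeds
    while keeping marginals uniform and pairwise separation guaranteed.
    """
    offsets = {k: rng.uniform() for k in _LATTICE_STRIDES}
    order = rng.permutation(n_subjects)
    return [
        {k: float((offsets[k] + order[i] * s / n_subjects) % 1.0)
         for k, s in _LATTICE_STRIDES.items()}
        for i in range(n_subjects)
    ]


def _jitter_params(params: dict, jitter: float, rng: np.random.Generator) -> dict:
    """Perturb a parameter record multiplicatively by ~``jitter`` (clones)."""
    out: dict = {}
    for key, value in params.items():
        if isinstance(value, np.ndarray):
            out[key] = _unit(value + jitter * rng.standard_normal(value.shape))
        else:
            out[key] = float(value) * (1.0 + jitter * rng.standard_normal())
    return out


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], rate: float) -> np.ndarray:
    """Unit-RMS 1/f (power) noise, synthesized in the frequency domain."""
    n_ch, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * amp
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _bandlimited_source(rng: np.random.Generator, n: int, rate: float,
                        lo: float = 8.0, hi: float = 12.0) -> np.ndarray:
    """Unit-RMS noise band-passed to [lo, hi] Hz (mu-band MI source)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.where(mask, rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size), 0.0)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / max(rms, 1e-30)


def _skewed_unit(alpha: float, rng: np.random.Generator) -> float:
    """Zero-mean, unit-variance skew-normal draw with shape ``alpha``."""
    delta = alpha / np.sqrt(1.0 + alpha ** 2)
    z = delta * abs(rng.standard_normal()) + np.sqrt(
        1.0 - delta ** 2) * rng.standard_normal()
    mean = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - 2.0 * delta ** 2 / np.pi)
    return float((z - mean) / sd)


def _trial_engagement(label: str, params: dict, rng: np.random.Generator) -> float:
    """Shared task-response gain of one trial (0 on an attention lapse).

    Engaged trials draw a skewed lognormal gain of unit mean whose skew
    direction is a stable subject trait.
    """
    if label == "baseline":
        return 1.0
    if rng.random() < params.get("lapse_rate", 0.0):
        return 0.0
    cv = params.get("engagement_cv", 0.0)
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    g = np.exp(sigma * rng.standard_normal() - 0.5 * sigma ** 2)
    if params.get("engagement_skew", 1.0) >= 0:
        return float(g)
    return float(max(0.0, 2.0 - g))


def _eeg_trial(label: str, params: dict, config: CohortConfig,
               rng: np.random.Generator, engagement: float = 1.0) -> np.ndarray:
    n = int(round(config.trial_seconds * config.eeg_rate))
    eeg = (params["pink_noise"] * _pink_noise(rng, (16, n), config.eeg_rate)
           + params["white_noise"] * rng.standard_normal((16, n)))
    if label == "baseline":
        return eeg
    pattern = params["pattern_task1"] if label == "task1" else params["pattern_task2"]
    amp = params["source_amplitude"] * engagement
    if config.paradigm == "MI":
        src = _bandlimited_source(rng, n, config.eeg_rate)
    else:
        freq = 7.0 if label == "task1" else 17.0
        t = np.arange(n) / config.eeg_rate
        src = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return eeg + amp * np.outer(pattern, src)


def _ftcd_trial(label: str, params: dict, config: CohortConfig,
                rng: np.random.Generator, engagement: float = 1.0) -> np.ndarray:
    h = config.hyperparams
    n = int(round(config.trial_seconds * config.ftcd_rate))
    t = np.arange(n) / config.ftcd_rate
    cardiac_phase = rng.uniform(0, 2 * np.pi)
    # rectified sinusoid gives the peaked systolic shape of a velocity envelope
    pulse = np.abs(np.sin(np.pi * params["heart_rate"] * t + cardiac_phase))
    env = h.ftcd_base_flow + h.ftcd_pulsatility * pulse
    env = np.vstack([env, env]).copy()
    # slow per-trial drift of the flow level: one common (skewed) and one
    # per-side (symmetric) term
    drift = params.get("flow_drift", 0.0)
    env += drift * (_skewed_unit(params.get("flow_drift_skew", 0.0), rng)
                    + rng.standard_normal(2)[:, None] / np.sqrt(2.0))
    if label != "baseline":
        lat = params["ftcd_laterality"]
        # task1 drives the left MCA harder, task2 the right
        side_gain = np.array([1.0 + lat, 1.0 - lat])
        if label == "task2":
            side_gain = side_gain[::-1]
        # hemodynamics integrate over the trial: a sustained, largely
        # autonomic flow-level rise only weakly coupled to moment-to-moment
        # engagement
        c = params["ftcd_contrast"] * (0.7 + 0.3 * engagement)
        env += c * side_gain[:, None]
    env += h.ftcd_noise * rng.standard_normal((2, n))
    return env


def generate_subject(config: CohortConfig, subject_params: dict, seed: int,
                     subject_id: str = "S0") -> SubjectDataset:
    """Generate one subject's full randomized session.

    ``trials_per_condition`` trials of each of the three conditions are
    produced in a shuffled presentation order driven by ``seed``; identical
    (config, params, seed) yield bitwise-identical datasets.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.array(CONDITIONS), config.trials_per_condition)
    rng.shuffle(labels)
    trials = []
    for lab in labels:
        engagement = _trial_engagement(str(lab), subject_params, rng)
        trials.append(TrialMatrix(
            eeg=_eeg_trial(str(lab), subject_params, config, rng, engagement),
            ftcd=_ftcd_trial(str(lab), subject_params, config, rng, engagement),
            label=str(lab),
            eeg_rate=config.eeg_rate,
            ftcd_rate=config.ftcd_rate,
        ))
    return SubjectDataset(
        subject_id=subject_id,
        paradigm=config.paradigm,
        trials=trials,
        generative_params=copy.deepcopy(subject_params),
    )


def generate_cohort(config: CohortConfig) -> list[SubjectDataset]:
    """Generate the whole cohort; clone pairs share latent parameters.

    Per-subject seeds derive deterministically from ``config.seed`` via
    ``numpy`` seed sequences, so cohorts are reproducible bit for bit.
    """
    root = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    quantiles = _cohort_quantiles(config.n_subjects, param_rng)
    params = [draw_subject_params(config, param_rng, quantiles[i])
              for i in range(config.n_subjects)]
    for a, b in config.clone_pairs:
        params[b] = _jitter_params(
            params[a], config.hyperparams.clone_jitter, param_rng)
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(config.n_subjects + 1)[1:]]
    return [
        generate_subject(config, params[i], subject_seeds[i], subject_id=f"S{i:02d}")
        for i in range(config.n_subjects)
    ]


# ---------------------------------------------------------------------------
# persistence (HDF5 container + CSV manifest)
# ---------------------------------------------------------------------------

def save_cohort(path: str, cohort: Sequence[SubjectDataset]) -> None:
    """Persist a cohort as an HDF5 container, one group per subject."""
    with h5py.File(path, "w") as f:
        for ds in cohort:
            g = f.create_group(ds.subject_id)
            g.attrs["paradigm"] = ds.paradigm
            g.attrs["eeg_rate"] = ds.trials[0].eeg_rate
            g.attrs["ftcd_rate"] = ds.trials[0].ftcd_rate
            g.attrs["params_json"] = json.dumps(
                {k: v.tolist() if isinstance(v, np.ndarray) else v
                 for k, v in ds.generative_params.items()})
            g.create_dataset("eeg", data=np.stack([t.eeg for t in ds.trials]),
                             compression="gzip", compression_opts=4)
            g.create_dataset("ftcd", data=np.stack([t.ftcd for t in ds.trials]),
                             compression="gzip", compression_opts=4)
            g.create_dataset("labels", data=np.array(ds.labels, dtype="S16"))


def load_cohort(path: str) -> list[SubjectDataset]:
    cohort = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            eeg = g["eeg"][...]
            ftcd = g["ftcd"][...]
            labels = [s.decode() for s in g["labels"][...]]
            params = json.loads(g.attrs["params_json"])
            params = {k: np.asarray(v) if isinstance(v, list) else v
                      for k, v in params.items()}
            trials = [
                TrialMatrix(eeg=eeg[i], ftcd=ftcd[i], label=labels[i],
                            eeg_rate=float(g.attrs["eeg_rate"]),
                            ftcd_rate=float(g.attrs["ftcd_rate"]))
                for i in range(eeg.shape[0])
            ]
            cohort.append(SubjectDataset(subject_id=sid,
                                         paradigm=str(g.attrs["paradigm"]),
                                         trials=trials,
                                         generative_params=params))
    return cohort


def cohort_manifest(cohort: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Tabular overview of a cohort (one row per subject)."""
    rows = []
    for ds in cohort:
        counts = pd.Series(ds.labels).value_counts()
        rows.append({
            "subject_id": ds.subject_id,
            "paradigm": ds.paradigm,
            "n_trials": len(ds.trials),
            **{f"n_{c}": int(counts.get(c, 0)) for c in CONDITIONS},
            "eeg_rate": ds.trials[0].eeg_rate,
            "ftcd_rate": ds.trials[0].ftcd_rate,
        })
    return pd.DataFrame(rows)
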