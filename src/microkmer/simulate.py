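"""Synthetic ground-truth generator for the full pipeline.

Emulates the generative picture behind microstate analysis: a small set of
quasi-stable scalp topographies, a first-order Markov switching process with
geometric dwell times, a GFP-like amplitude envelope, and additive white
sensor noise.  Two stimulus conditions differ only in their transition
dynamics, and each trial carries a 1-9 affect rating so the downstream
binarization and classification stages have targets.

Everything is deterministic given the seed(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import EEGRecording, MarkovModel, MicrostateSequence, TemplateSet

__all__ = [
    "SimulationConfig",
    "LabeledTrialSet",
    "make_templates",
    "sample_microstate_sequence",
    "synthesize_recording",
    "make_labeled_dataset",
]

#: rectified-sinusoid envelope period, seconds (mimics ~10 GFP peaks/s)
ENVELOPE_PERIOD = 0.1


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-condition experiment.

    Defaults follow a 32-channel, 128 Hz recording setup with four planted
    microstates of ~100 ms mean dwell, trials of 30 s, sensor SNR 4, and a
    strong cyclic transition-bias between conditions (``condition_delta``).
    """

    n_channels: int = 32
    m_states: int = 4
    fs: float = 128.0
    n_samples: int = 3840
    mean_dwell: float = 0.1
    snr: float = 4.0
    seed: int = 0
    condition_delta: float = 0.5

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.m_states < 2:
            raise ValueError("need at least 2 microstates")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.mean_dwell * self.fs < 1:
            raise ValueError("mean dwell must cover at least one sample")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.condition_delta < 0:
            raise ValueError("condition_delta must be nonnegative")


@dataclass
class LabeledTrialSet:
    """Balanced two-condition trial collection with ratings and ground truth."""

    trials: list[EEGRecording]
    ratings: np.ndarray
    conditions: list[str]
    templates: TemplateSet | None = None
    sequences: list[MicrostateSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if not (len(self.trials) == self.ratings.size == len(self.conditions)):
            raise ValueError("trials, ratings and conditions must align")
        if self.ratings.size and (self.ratings.min() < 1 or self.ratings.max() > 9):
            raise ValueError("ratings must lie in [1, 9]")
        fss = {t.fs for t in self.trials}
        chs = {t.n_channels for t in self.trials}
        if len(fss) > 1 or len(chs) > 1:
            raise ValueError("all trials must share fs and channel count")

    def __len__(self) -> int:
        return len(self.trials)


def make_templates(m_states: int, n_channels: int, seed: int) -> TemplateSet:
    """Draw ``m_states`` mutually distinguishable synthetic topographies.

    Random Gaussian channel vectors are demeaned and orthonormalized (zero-mean
    maps live in an (n_channels-1)-dimensional subspace, hence the strict
    ``m_states < n_channels`` requirement), then lightly mixed so maps are
    correlated like real microstate classes while every pairwise absolute
    spatial correlation stays at or below 0.5.
    """
    if m_states >= n_channels:
        raise ValueError(
            "cannot build zero-mean mutually distinguishable maps with "
            f"m_states={m_states} >= n_channels={n_channels}; zero-mean maps "
            f"span only {n_channels - 1} dimensions"
        )
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, m_states))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)  # columns: orthonormal, still zero-mean
    q = q[:, :m_states]

    # mix the orthonormal basis so maps overlap mildly; shrink the mixing
    # until the 0.5 correlation cap holds (always terminates: gamma -> 0
    # recovers the orthonormal, zero-correlation basis)
    mix = rng.standard_normal((m_states, m_states))
    gamma = 0.3
    for _ in range(40):
        maps = (q @ (np.eye(m_states) + gamma * mix)).T
        maps -= maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        corr = np.abs(maps @ maps.T)
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= 0.5:
            break
        gamma *= 0.5
    else:  # pragma: no cover - gamma ~ 1e-13 is effectively orthonormal
        maps = q.T
    return TemplateSet.from_maps(maps)


def sample_microstate_sequence(
    model: MarkovModel, n_samples: int, fs: float, seed: int
) -> MicrostateSequence:
    """Sample a label series from a first-order Markov chain."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if model.zero_rows.size:
        raise ValueError("transition matrix has rows with no outgoing mass")
    m = model.n_states
    rng = np.random.default_rng(seed)
    cum_T = np.cumsum(model.transition, axis=1)
    cum_T[:, -1] = 1.0  # guard roundoff
    u = rng.random(n_samples)
    labels = np.empty(n_samples, dtype=np.int64)
    labels[0] = np.searchsorted(np.cumsum(model.initial), u[0], side="right")
    labels[0] = min(labels[0], m - 1)
    for t in range(1, n_samples):
        labels[t] = np.searchsorted(cum_T[labels[t - 1]], u[t], side="right")
    return MicrostateSequence(labels, fs=fs, n_states=m)


def _envelope(n_samples: int, fs: float) -> np.ndarray:
    """Strictly positive rectified-sinusoid amplitude envelope, unit mean."""
    t = np.arange(n_samples) / fs
    env = np.abs(np.sin(np.pi * t / ENVELOPE_PERIOD)) + 0.05
    return env / env.mean()


def synthesize_recording(
    templates: TemplateSet,
    sequence: MicrostateSequence,
    snr: float,
    seed: int,
) -> EEGRecording:
    """Invert the back-fitting model: each sample is its state's topography.

    ``data[:, t] = a(t) * maps[labels[t]] + noise`` where ``a`` is a strictly
    positive rectified-sinusoid envelope (unit mean, period 100 ms — gives the
    GFP its peak structure) and the white Gaussian noise is scaled so the
    realized signal-RMS / noise-RMS ratio equals ``snr`` exactly.
    """
    if sequence.n_states != templates.n_states:
        raise ValueError("sequence alphabet size does not match template count")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    env = _envelope(len(sequence), sequence.fs)
    signal = templates.maps[sequence.labels].T * env  # (channels, samples)
    noise = rng.standard_normal(signal.shape)
    sig_rms = np.sqrt(np.mean(signal**2))
    noise_rms = np.sqrt(np.mean(noise**2))
    noise *= sig_rms / (snr * noise_rms)
    return EEGRecording(signal + noise, fs=sequence.fs)


def condition_models(config: SimulationConfig) -> tuple[MarkovModel, MarkovModel]:
    """Base chain (condition A) and its cyclically biased variant (condition B).

    Condition B adds ``condition_delta`` of transition mass from each state to
    its cyclic successor before row re-normalization, changing switching
    preferences while keeping dwell times comparable.  ``condition_delta = 0``
    makes the conditions identical.
    """
    base = MarkovModel.with_dwell(config.m_states, config.mean_dwell, config.fs)
    T = base.transition.copy()
    m = config.m_states
    for i in range(m):
        T[i, (i + 1) % m] += config.condition_delta
    T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    return base, MarkovModel(base.initial.copy(), T)


def make_labeled_dataset(
    config: SimulationConfig, n_trials_per_condition: int
) -> LabeledTrialSet:
    """Generate a balanced two-condition trial set with 1-9 ratings.

    Condition A trials get ratings above 4.5 (high affect), condition B below,
    so rating binarization at the conventional 4.5 cut recovers the condition
    labels exactly.  Ground-truth templates and label sequences are kept on
    the returned set for oracle checks.
    """
    if n_trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    templates = make_templates(config.m_states, config.n_channels, config.seed)
    model_a, model_b = condition_models(config)

    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(4 * n_trials_per_condition + 1)]
    rng = np.random.default_rng(child_seeds[-1])

    trials: list[EEGRecording] = []
    sequences: list[MicrostateSequence] = []
    conditions: list[str] = []
    ratings: list[float] = []
    i = 0
    for cond, model in (("A", model_a), ("B", model_b)):
        for _ in range(n_trials_per_condition):
            seq = sample_microstate_sequence(
                model, config.n_samples, config.fs, seed=child_seeds[i]
            )
            rec = synthesize_recording(
                templates, seq, snr=config.snr, seed=child_seeds[i + 1]
            )
            i += 2
            trials.append(rec)
            sequences.append(seq)
            conditions.append(cond)
            lo, hi = (5.5, 8.5) if cond == "A" else (1.5, 4.0)
            ratings.append(float(rng.uniform(lo, hi)))
    return LabeledTrialSet(
        trials=trials,
        ratings=np.asarray(ratings),
        conditions=conditions,
        templates=templates,
        sequences=sequences,
    )
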