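"""Core in-memory containers shared across the pipeline.

All containers are plain dataclasses around numpy arrays, validated at
construction.  Topographic maps ("templates") are stored channel-demeaned and
unit-norm, which makes spatial correlation a plain dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EEGRecording",
    "MicrostateSequence",
    "TemplateSet",
    "MarkovModel",
    "normalize_map",
    "spatial_correlation",
]

#: symbol alphabet used for plain-text sequence export (one char per state)
TEXT_ALPHABET = "0123456789"


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Channel-demean and L2-normalize a topography vector."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot normalize an all-constant topography (zero GFP)")
    return v / norm


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a zero-GFP map")
    return float(a @ b / (na * nb))


@dataclass
class EEGRecording:
    """Multichannel EEG trial: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] < 2:
            raise ValueError("an EEG recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        elif len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


@dataclass
class MicrostateSequence:
    """Symbolic label series over the alphabet {0..n_states-1}."""

    labels: np.ndarray
    fs: float
    n_states: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.n_states is None:
            self.n_states = int(self.labels.max()) + 1
        elif self.labels.max() >= self.n_states:
            raise ValueError("label exceeds declared alphabet size")

    def __len__(self) -> int:
        return self.labels.size

    def to_text(self) -> str:
        """Render the sequence as one line over the alphabet '0'..'9'."""
        if self.n_states > len(TEXT_ALPHABET):
            raise ValueError("text export supports at most 10 states")
        lut = np.frombuffer(TEXT_ALPHABET.encode(), dtype=np.uint8)
        return lut[self.labels].tobytes().decode()

    @classmethod
    def from_text(cls, line: str, fs: float, n_states: int | None = None) -> "MicrostateSequence":
        codes = np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0")
        if codes.size and (codes.min() < 0 or codes.max() > 9):
            raise ValueError("text sequences must use characters '0'..'9'")
        return cls(codes.astype(np.int64), fs=fs, n_states=n_states)


@dataclass
class TemplateSet:
    """Set of m microstate topographies (rows), zero-mean and unit-norm.

    ``gev_total`` is the global explained variance the templates attained on
    the data they were fit to; ``meta`` carries clustering diagnostics
    (warning flag, GEV trace, thresholds).
    """

    maps: np.ndarray
    gev_total: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[1] < 2:
            raise ValueError("templates need at least 2 channels")
        means = self.maps.mean(axis=1)
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(means) > 1e-9) or np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError(
                "template rows must be zero-mean and unit-norm; "
                "use TemplateSet.from_maps to normalize"
            )
        if self.gev_total is not None and not -1e-9 <= self.gev_total <= 1 + 1e-9:
            raise ValueError("gev_total must lie in [0, 1]")

    @classmethod
    def from_maps(cls, maps: np.ndarray, gev_total: float | None = None,
                  meta: dict | None = None) -> "TemplateSet":
        maps = np.atleast_2d(np.asarray(maps, dtype=float))
        maps = np.stack([normalize_map(row) for row in maps])
        return cls(maps, gev_total=gev_total, meta=meta or {})

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def pairwise_gmd(self, polarity_invariant: bool = True) -> np.ndarray:
        """Symmetric matrix of global map dissimilarities between templates."""
        from .segmentation import gmd  # local import to avoid a cycle

        m = self.n_states
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = gmd(
                    self.maps[i], self.maps[j], polarity_invariant=polarity_invariant
                )
        return out


@dataclass
class MarkovModel:
    """First-order Markov chain over m symbols.

    Rows of ``transition`` are probability vectors; a row may be all-zero when
    the symbol was never followed by anything in the estimation data (listed
    in ``zero_rows``).
    """

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        m = self.initial.size
        if self.transition.shape != (m, m):
            raise ValueError("transition must be m x m for an m-symbol initial vector")
        if np.any(self.initial < -1e-12) or abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must be a probability vector")
        row_sums = self.transition.sum(axis=1)
        ok = np.isclose(row_sums, 1.0, atol=1e-9) | np.isclose(row_sums, 0.0, atol=1e-12)
        if np.any(self.transition < -1e-12) or not np.all(ok):
            raise ValueError("transition rows must sum to 1 (or be all-zero)")

    @property
    def n_states(self) -> int:
        return self.initial.size

    @property
    def zero_rows(self) -> np.ndarray:
        """Indices of symbols with no outgoing transition mass."""
        return np.flatnonzero(self.transition.sum(axis=1) < 1e-12)

    @classmethod
    def uniform(cls, m: int) -> "MarkovModel":
        return cls(np.full(m, 1 / m), np.full((m, m), 1 / m))

    @classmethod
    def with_dwell(cls, m: int, mean_dwell: float, fs: float) -> "MarkovModel":
        """Symmetric chain whose geometric dwell time has the given mean.

        Self-transition probability is ``1 - 1/(mean_dwell * fs)``; leaving
        mass is spread uniformly over the other states.
        """
        if m < 2:
            raise ValueError("need at least 2 states")
        if mean_dwell * fs < 1:
            raise ValueError("mean dwell must be at least one sample")
        p_stay = 1.0 - 1.0 / (mean_dwell * fs)
        T = np.full((m, m), (1 - p_stay) / (m - 1))
        np.fill_diagonal(T, p_stay)
        return cls(np.full(m, 1 / m), T)
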