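"""Coarse-level microstate statistics: duration, occurrence, coverage, GEV.

These four conventional temporal parameters per class summarize the label
series at the run level; with m classes they form a flat 4*m feature vector
(block order: durations, occurrences, coverages, GEVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .segmentation import gev_of_assignment
from .types import EEGRecording, MicrostateSequence, TemplateSet

__all__ = ["TemporalParameters", "temporal_parameters", "TemporalFeaturizer"]


@dataclass
class TemporalParameters:
    """Per-class temporal statistics of a microstate sequence.

    duration : mean uninterrupted presence per class, seconds.
    occurrence : mean number of runs per class per second.
    coverage : fraction of samples per class (sums to 1).
    gev : fraction of GFP-weighted variance explained per class (zeros when
        no recording/templates were supplied).
    """

    duration: np.ndarray
    occurrence: np.ndarray
    coverage: np.ndarray
    gev: np.ndarray

    @property
    def n_states(self) -> int:
        return self.duration.size

    @property
    def vector(self) -> np.ndarray:
        """Flat 4*m feature vector: [dur_0..dur_m-1, occ_*, cov_*, gev_*]."""
        return np.concatenate([self.duration, self.occurrence, self.coverage, self.gev])

    @property
    def feature_names(self) -> list[str]:
        m = self.n_states
        return (
            [f"dur_{k}" for k in range(m)]
            + [f"occ_{k}" for k in range(m)]
            + [f"cov_{k}" for k in range(m)]
            + [f"gev_{k}" for k in range(m)]
        )


def _run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run_labels, run_lengths) of the label series, boundary runs included."""
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return labels[starts], ends - starts


def temporal_parameters(
    sequence: MicrostateSequence,
    recording: EEGRecording | None = None,
    templates: TemplateSet | None = None,
) -> TemporalParameters:
    """Compute duration, occurrence, time coverage and GEV per class.

    duration_k = mean run length of class k / fs (seconds);
    occurrence_k = number of runs of k / total time (per second);
    coverage_k = fraction of samples labeled k.  Runs touching the sequence
    boundaries count like any other, which preserves the exact identity
    coverage_k = duration_k * occurrence_k.  Classes absent from the sequence
    get zeros throughout.  GEV per class needs the source recording and the
    templates; omit them to get a GEV block of zeros.
    """
    m = sequence.n_states
    n = len(sequence)
    fs = sequence.fs
    total_time = n / fs

    run_labels, run_lens = _run_lengths(sequence.labels)
    duration = np.zeros(m)
    occurrence = np.zeros(m)
    coverage = np.zeros(m)
    for k in range(m):
        lens = run_lens[run_labels == k]
        if lens.size:
            duration[k] = lens.mean() / fs
            occurrence[k] = lens.size / total_time
            coverage[k] = lens.sum() / n

    if recording is not None and templates is not None:
        if recording.n_samples != n:
            raise ValueError("recording length must equal the sequence length")
        _, gev = gev_of_assignment(recording, templates, sequence)
    else:
        gev = np.zeros(m)
    return TemporalParameters(duration, occurrence, coverage, gev)


class TemporalFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer yielding the 4*m coarse feature vector per trial.

    ``transform`` accepts a list of :class:`MicrostateSequence` (GEV block
    zero) or a list of ``(sequence, recording)`` pairs; templates for the GEV
    block are passed at construction.
    """

    def __init__(self, templates: TemplateSet | None = None):
        self.templates = templates

    def fit(self, X, y=None):
        first = X[0][0] if isinstance(X[0], tuple) else X[0]
        self.n_states_ = first.n_states
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            if isinstance(item, tuple):
                seq, rec = item
                tp = temporal_parameters(seq, rec, self.templates)
            else:
                tp = temporal_parameters(item)
            rows.append(tp.vector)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        m = getattr(self, "n_states_", None)
        if m is None:
            raise AttributeError("featurizer is not fitted")
        dummy = TemporalParameters(*(np.zeros(m),) * 4)
        return np.asarray(dummy.feature_names, dtype=object)
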