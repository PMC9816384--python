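"""Microstate segmentation: GFP, peak picking, and DTAAHC clustering.

The segmentation stage reduces a multichannel EEG trial to a small set of
template topographies.  Global field power (GFP) — the spatial standard
deviation across channels at each sample — marks moments of high
signal-to-noise topography at its peaks; the topographies at smoothed-GFP
peaks are clustered with a dual-threshold Atomize-and-Agglomerate
Hierarchical Clustering (DTAAHC) that picks the number of classes
automatically from a global-explained-variance (GEV) floor and a global
map dissimilarity (GMD) redundancy cut.

Everything topographic is polarity-invariant: a map and its negation are the
same microstate, so correlations enter as absolute values and cluster
templates are principal eigenvectors (defined up to sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal.windows import gaussian as gaussian_window
from sklearn.base import BaseEstimator

from .types import EEGRecording, MicrostateSequence, TemplateSet, normalize_map

__all__ = [
    "ClusteringConfig",
    "GfpSeries",
    "global_field_power",
    "smooth_gfp",
    "find_gfp_peaks",
    "extract_peak_maps",
    "gmd",
    "gev_of_assignment",
    "dtaahc",
    "group_templates",
    "MicrostateSegmenter",
]


@dataclass
class ClusteringConfig:
    """Thresholds of the dual-threshold clustering.

    gev_threshold : minimum fraction of GFP-weighted variance the templates
        must explain (default 0.85).
    gmd_threshold : templates closer than this GMD are redundant and merged
        (default 0.1; GMD 0.1 corresponds to |spatial correlation| 0.995).
    smoothing_window : length in samples of the Gaussian GFP smoother
        (default 50).
    peak_radius : samples around each GFP peak whose topographies are also
        collected (default 0: the peak sample only).
    """

    gev_threshold: float = 0.85
    gmd_threshold: float = 0.1
    smoothing_window: int = 50
    peak_radius: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gev_threshold <= 1:
            raise ValueError("gev_threshold must lie in (0, 1]")
        if self.gmd_threshold < 0:
            raise ValueError("gmd_threshold must be nonnegative")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be at least 1")
        if self.peak_radius < 0:
            raise ValueError("peak_radius must be nonnegative")


@dataclass
class GfpSeries:
    """Per-sample global field power (nonnegative, microvolts)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("GFP series must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


def global_field_power(recording: EEGRecording) -> GfpSeries:
    """Spatial standard deviation of the channel voltages at each sample.

    GFP(t) = sqrt( (1/N) * sum_i (u_i(t) - mean_i u_i(t))^2 ).
    Invariant to adding a common offset to all channels.
    """
    return GfpSeries(recording.data.std(axis=0, ddof=0), fs=recording.fs)


def smooth_gfp(series: GfpSeries, window: int) -> GfpSeries:
    """Gaussian-weighted moving average of the GFP (unit-sum kernel).

    The kernel has the stated length and sigma (window-1)/5; edges are
    handled by reflection so the output length equals the input length.
    """
    n = len(series)
    if window < 1:
        raise ValueError("window must be at least 1")
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")
    if window == 1:
        return GfpSeries(series.values.copy(), fs=series.fs)
    kernel = gaussian_window(window, std=(window - 1) / 5)
    kernel /= kernel.sum()
    return GfpSeries(convolve1d(series.values, kernel, mode="reflect"), fs=series.fs)


def find_gfp_peaks(series: GfpSeries) -> np.ndarray:
    """Indices of strictly interior local maxima, ascending."""
    v = series.values
    if v.size < 3:
        return np.empty(0, dtype=np.int64)
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(interior).astype(np.int64) + 1


def extract_peak_maps(
    recording: EEGRecording, config: ClusteringConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-demeaned topographies at smoothed-GFP peaks.

    Returns ``(maps, peak_indices)`` where maps has one row per collected
    sample (peaks, plus ``peak_radius`` neighbors on each side when set).
    """
    config = config or ClusteringConfig()
    gfp = global_field_power(recording)
    peaks = find_gfp_peaks(smooth_gfp(gfp, config.smoothing_window))
    if config.peak_radius:
        offs = np.arange(-config.peak_radius, config.peak_radius + 1)
        idx = np.unique(np.clip(peaks[:, None] + offs, 0, recording.n_samples - 1))
    else:
        idx = peaks
    maps = recording.data[:, idx].T
    maps = maps - maps.mean(axis=1, keepdims=True)
    return maps, idx


def gmd(map_a: np.ndarray, map_b: np.ndarray, polarity_invariant: bool = True) -> float:
    """Global map dissimilarity between two topographies.

    Each map is channel-demeaned and scaled by its GFP; the GMD is the root
    mean squared difference of the normalized maps, optionally minimized over
    a sign flip of the second map.  Equals sqrt(2 * (1 - r)) with r the
    spatial correlation, hence 0 for identical shapes and 2 (or sqrt(2) when
    polarity-invariant) at the far end.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have the same channel count")
    a = a - a.mean()
    b = b - b.mean()
    ga = np.sqrt(np.mean(a**2))
    gb = np.sqrt(np.mean(b**2))
    if ga == 0 or gb == 0:
        raise ValueError("GMD undefined for a zero-GFP map")
    a /= ga
    b /= gb
    d = float(np.sqrt(np.mean((a - b) ** 2)))
    if polarity_invariant:
        d = min(d, float(np.sqrt(np.mean((a + b) ** 2))))
    return d


def _abs_corr_to_templates(demeaned: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of demeaned sample maps (rows) with unit-norm templates."""
    norms = np.linalg.norm(demeaned, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    corr = np.abs(demeaned @ templates.T) / safe[:, None]
    corr[norms == 0] = 0.0
    return corr


def gev_of_assignment(
    recording: EEGRecording,
    templates: TemplateSet,
    labels: MicrostateSequence | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Total and per-class global explained variance of a label assignment.

    GEV_k = sum_{t: L(t)=k} (GFP(t) * corr(u(t), map_k))^2 / sum_t GFP(t)^2,
    with corr the spatial correlation; the total is the sum over classes and
    lies in [0, 1].
    """
    lab = labels.labels if isinstance(labels, MicrostateSequence) else np.asarray(labels)
    if lab.size != recording.n_samples:
        raise ValueError("labels length must equal the sample count")
    gfp = recording.data.std(axis=0, ddof=0)
    demeaned = (recording.data - recording.data.mean(axis=0)).T
    corr = _abs_corr_to_templates(demeaned, templates.maps)
    chosen = corr[np.arange(lab.size), lab]
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("GEV undefined for an all-zero recording")
    contrib = (gfp * chosen) ** 2
    per_class = np.array(
        [contrib[lab == k].sum() for k in range(templates.n_states)]
    ) / denom
    return float(per_class.sum()), per_class


# --------------------------------------------------------------------------
# DTAAHC


def _principal_template(members: np.ndarray) -> np.ndarray:
    """Polarity-invariant mean of member maps: leading eigenvector of their
    channel scatter, demeaned and unit-normalized."""
    if members.shape[0] == 1:
        return normalize_map(members[0])
    scatter = members.T @ members
    _, vecs = np.linalg.eigh(scatter)
    return normalize_map(vecs[:, -1])


class _AAHCState:
    """Mutable clustering state over a fixed set of demeaned peak maps."""

    def __init__(self, maps: np.ndarray, gfp: np.ndarray):
        self.maps = maps          # (N, C) demeaned
        self.gfp = gfp            # (N,)
        self.members: list[np.ndarray] = [np.array([i]) for i in range(len(maps))]
        norms = np.linalg.norm(maps, axis=1, keepdims=True)
        self.templates = maps / norms
        self.assign = np.arange(len(maps))
        self.corr = np.ones(len(maps))
        self._gfp2_total = float(np.sum(gfp**2))

    def copy(self) -> "_AAHCState":
        new = object.__new__(_AAHCState)
        new.maps = self.maps
        new.gfp = self.gfp
        new.members = [m.copy() for m in self.members]
        new.templates = self.templates.copy()
        new.assign = self.assign.copy()
        new.corr = self.corr.copy()
        new._gfp2_total = self._gfp2_total
        return new

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def gev(self) -> float:
        return float(np.sum((self.gfp * self.corr) ** 2) / self._gfp2_total)

    def cluster_contributions(self) -> np.ndarray:
        w = (self.gfp * self.corr) ** 2 / self._gfp2_total
        return np.array([w[m].sum() for m in self.members])

    def _refresh_cluster(self, c: int) -> None:
        m = self.members[c]
        self.templates[c] = _principal_template(self.maps[m])
        self.corr[m] = _abs_corr_to_templates(self.maps[m], self.templates[c][None, :])[:, 0]
        self.assign[m] = c

    def pairwise_gmd(self) -> np.ndarray:
        r = np.abs(self.templates @ self.templates.T)
        np.fill_diagonal(r, 1.0)
        d = np.sqrt(np.maximum(2.0 - 2.0 * np.clip(r, -1, 1), 0.0))
        np.fill_diagonal(d, np.inf)
        return d

    def merge_redundant(self, gmd_threshold: float) -> None:
        """Merge cluster pairs closer than the GMD threshold, closest first."""
        while self.n_clusters > 1:
            d = self.pairwise_gmd()
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] >= gmd_threshold:
                return
            i, j = sorted((int(i), int(j)))
            self.members[i] = np.concatenate([self.members[i], self.members[j]])
            del self.members[j]
            self.templates = np.delete(self.templates, j, axis=0)
            self.assign[self.assign > j] -= 1
            self._refresh_cluster(i)

    def dissolve_worst(self) -> None:
        """Remove the cluster contributing least GEV and reassign its members."""
        worst = int(np.argmin(self.cluster_contributions()))
        orphans = self.members[worst]
        del self.members[worst]
        self.templates = np.delete(self.templates, worst, axis=0)
        self.assign[self.assign > worst] -= 1
        corr = _abs_corr_to_templates(self.maps[orphans], self.templates)
        target = np.argmax(corr, axis=1)  # argmax ties to the lowest index
        touched = set()
        for c in np.unique(target):
            add = orphans[target == c]
            self.members[c] = np.concatenate([self.members[c], add])
            touched.add(int(c))
        for c in touched:
            self._refresh_cluster(c)

    def to_template_set(self, meta: dict) -> TemplateSet:
        d = self.pairwise_gmd()
        finite = d[np.isfinite(d)]
        meta = dict(meta)
        meta["min_gmd"] = float(finite.min()) if finite.size else float("nan")
        meta["n_maps"] = len(self.maps)
        return TemplateSet(self.templates.copy(), gev_total=self.gev(), meta=meta)


def dtaahc(peak_maps: np.ndarray, config: ClusteringConfig | None = None) -> TemplateSet:
    """Dual-threshold Atomize-and-Agglomerate Hierarchical Clustering.

    Starting from singleton clusters, (1) clusters whose templates are closer
    than ``gmd_threshold`` (polarity-invariant GMD) are merged, closest pair
    first; (2) the cluster contributing least GEV is repeatedly dissolved and
    its members reassigned to their best-correlated remaining template,
    stopping before a step that would drop the fitted GEV below
    ``gev_threshold``.  Cluster templates are principal eigenvectors of the
    member scatter, recomputed after every step.

    Returns the smallest template set meeting both thresholds, with the
    attained GEV and a per-step GEV trace in ``meta``.  If the thresholds are
    jointly unattainable, the full singleton solution is returned with
    ``meta['warning'] = True``.
    """
    config = config or ClusteringConfig()
    maps = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 peak maps to cluster")
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = maps.std(axis=1, ddof=0)
    keep = gfp > 0
    if not np.all(keep):
        maps, gfp = maps[keep], gfp[keep]
        if maps.shape[0] < 2:
            raise ValueError("fewer than 2 nonzero-GFP peak maps")

    state = _AAHCState(maps, gfp)
    state.merge_redundant(config.gmd_threshold)
    trace = [state.gev()]
    if trace[0] < config.gev_threshold:
        # dual thresholds conflict: distinctness alone already drops GEV
        # below the floor — fall back to the full singleton solution
        full = _AAHCState(maps, gfp)
        return full.to_template_set(
            {"warning": True, "gev_trace": [full.gev()], "config": config}
        )

    while state.n_clusters > 1:
        trial = state.copy()
        trial.dissolve_worst()
        trial.merge_redundant(config.gmd_threshold)
        g = trial.gev()
        if g < config.gev_threshold:
            break
        state = trial
        trace.append(g)
    return state.to_template_set(
        {"warning": False, "gev_trace": trace, "config": config}
    )


def group_templates(
    per_subject: list[TemplateSet], config: ClusteringConfig | None = None
) -> TemplateSet:
    """Second-level clustering: pool all subject templates and rerun DTAAHC."""
    if not per_subject:
        raise ValueError("need at least one subject template set")
    chs = {ts.n_channels for ts in per_subject}
    if len(chs) > 1:
        raise ValueError("subject template sets must share the channel count")
    pooled = np.vstack([ts.maps for ts in per_subject])
    if pooled.shape[0] == 1:
        return TemplateSet.from_maps(pooled, gev_total=1.0, meta={"warning": False})
    return dtaahc(pooled, config)


class MicrostateSegmenter(BaseEstimator):
    """Two-level microstate segmentation with back-fitting prediction.

    ``fit`` collects smoothed-GFP peak topographies from the given recordings
    (optionally grouped by subject), clusters them with DTAAHC per subject,
    and pools subject templates through a second DTAAHC pass.  ``predict``
    back-fits a recording against the learned templates and applies temporal
    smoothing.

    Parameters
    ----------
    gev_threshold, gmd_threshold, smoothing_window, peak_radius :
        clustering configuration (see :class:`ClusteringConfig`).
    strength, half_size :
        temporal-smoothing parameters used by ``predict`` (defaults 10 / 3).
    max_maps_per_subject :
        optional cap on pooled peak maps per subject (uniform deterministic
        subsample) to bound the clustering cost.
    random_state :
        seed for the subsample.

    Attributes
    ----------
    templates_ : TemplateSet
    subject_templates_ : list of TemplateSet
    gev_ : float, GEV attained on the pooled peak maps
    n_states_ : int
    """

    def __init__(
        self,
        gev_threshold: float = 0.85,
        gmd_threshold: float = 0.1,
        smoothing_window: int = 50,
        peak_radius: int = 0,
        strength: float = 10.0,
        half_size: int = 3,
        max_maps_per_subject: int | None = None,
        random_state: int = 0,
    ):
        self.gev_threshold = gev_threshold
        self.gmd_threshold = gmd_threshold
        self.smoothing_window = smoothing_window
        self.peak_radius = peak_radius
        self.strength = strength
        self.half_size = half_size
        self.max_maps_per_subject = max_maps_per_subject
        self.random_state = random_state

    def _config(self) -> ClusteringConfig:
        return ClusteringConfig(
            gev_threshold=self.gev_threshold,
            gmd_threshold=self.gmd_threshold,
            smoothing_window=self.smoothing_window,
            peak_radius=self.peak_radius,
        )

    def fit(self, X, y=None, subjects=None):
        recordings = [X] if isinstance(X, EEGRecording) else list(X)
        if not recordings:
            raise ValueError("need at least one recording")
        if subjects is None:
            subjects = [0] * len(recordings)
        if len(subjects) != len(recordings):
            raise ValueError("subjects must align with recordings")
        config = self._config()
        rng = np.random.default_rng(self.random_state)

        by_subject: dict = {}
        for rec, subj in zip(recordings, subjects):
            by_subject.setdefault(subj, []).append(rec)

        self.subject_templates_ = []
        for subj in sorted(by_subject, key=str):
            maps = np.vstack(
                [extract_peak_maps(rec, config)[0] for rec in by_subject[subj]]
            )
            if (
                self.max_maps_per_subject is not None
                and maps.shape[0] > self.max_maps_per_subject
            ):
                idx = np.sort(
                    rng.choice(maps.shape[0], self.max_maps_per_subject, replace=False)
                )
                maps = maps[idx]
            self.subject_templates_.append(dtaahc(maps, config))

        if len(self.subject_templates_) == 1:
            self.templates_ = self.subject_templates_[0]
        else:
            self.templates_ = group_templates(self.subject_templates_, config)
        self.gev_ = self.templates_.gev_total
        self.n_states_ = self.templates_.n_states
        return self

    def predict(self, X):
        from .backfit import SmoothingConfig, assign_labels, smooth_labels

        if not hasattr(self, "templates_"):
            raise AttributeError("segmenter is not fitted")
        single = isinstance(X, EEGRecording)
        recs = [X] if single else list(X)
        cfg = SmoothingConfig(strength=self.strength, half_size=self.half_size)
        out = []
        for rec in recs:
            raw = assign_labels(rec, self.templates_)
            out.append(smooth_labels(rec, self.templates_, raw, cfg))
        return out[0] if single else out

    def fit_predict(self, X, y=None, subjects=None):
        return self.fit(X, subjects=subjects).predict(X)
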