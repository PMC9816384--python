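"""End-to-end affective-state classification experiment.

Binds the stages together: binarize 1-9 ratings at 4.5 into high/low classes,
fuse coarse (temporal-parameter) and fine (k-mer F_w) feature blocks,
standardize + PCA (smallest component count explaining the variance target,
default 85%) fit on training folds only, classify with an SVM, and report
accuracy = (TP+TN)/(TP+TN+FP+FN) under stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .coarse import TemporalFeaturizer
from .kmer import KmerFeaturizer
from .segmentation import MicrostateSegmenter
from .simulate import LabeledTrialSet, SimulationConfig, make_labeled_dataset

__all__ = [
    "ExperimentConfig",
    "ClassificationReport",
    "TrialFeatureMatrix",
    "binarize_ratings",
    "fuse_features",
    "make_classifier",
    "crossval_classify",
    "run_pipeline",
]


@dataclass
class ExperimentConfig:
    """Settings of the classification experiment."""

    dimension: str = "valence"
    threshold: float = 4.5
    k: int = 5
    pca_variance: float = 0.85
    folds: int = 5
    seed: int = 0
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    svm_gamma: str | float = "scale"
    pca_per_fold: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class ClassificationReport:
    """Cross-validated accuracy with confusion counts.

    ``fold_accuracies`` has one entry per test fold; the confusion counts are
    summed over folds (each trial is tested exactly once), so
    mean-over-trials accuracy is (tp+tn)/(tp+tn+fp+fn).
    """

    fold_accuracies: list[float]
    mean_accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int
    n_components: list[int]
    fold_test_sizes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class TrialFeatureMatrix:
    """Trials-by-features table with a per-column provenance level tag."""

    values: pd.DataFrame
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if set(self.provenance) != set(self.values.columns):
            raise ValueError("provenance must tag every column")

    @property
    def n_trials(self) -> int:
        return len(self.values)


def binarize_ratings(ratings, threshold: float = 4.5) -> np.ndarray:
    """High/low labels from 1-9 ratings: strictly above the cut is high (1)."""
    r = np.asarray(ratings, dtype=float)
    if r.size and (r.min() < 1 or r.max() > 9):
        raise ValueError("ratings must lie in [1, 9]")
    return (r > threshold).astype(int)


def fuse_features(
    coarse: np.ndarray | None = None,
    fine: np.ndarray | None = None,
    coarse_names: list[str] | None = None,
    fine_names: list[str] | None = None,
) -> TrialFeatureMatrix:
    """Column-wise concatenation of the coarse and fine feature blocks.

    Either block may be used alone; with both, trial ordering must match.
    """
    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for arr, names, level in (
        (coarse, coarse_names, "coarse"),
        (fine, fine_names, "fine"),
    ):
        if arr is None:
            continue
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if names is None:
            names = [f"{level}_{i}" for i in range(arr.shape[1])]
        blocks.append(pd.DataFrame(arr, columns=list(names)))
        provenance.update({c: level for c in names})
    if not blocks:
        raise ValueError("at least one feature block is required")
    if len({len(b) for b in blocks}) > 1:
        raise ValueError("feature blocks disagree on trial count")
    values = pd.concat([b.reset_index(drop=True) for b in blocks], axis=1)
    return TrialFeatureMatrix(values=values, provenance=provenance)


def make_classifier(config: ExperimentConfig) -> Pipeline:
    """Standardize -> PCA(variance target) -> SVM, as one sklearn pipeline."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=config.pca_variance, svd_solver="full")),
            (
                "svm",
                SVC(
                    C=config.svm_c,
                    kernel=config.svm_kernel,
                    gamma=config.svm_gamma,
                ),
            ),
        ]
    )


def crossval_classify(
    features: TrialFeatureMatrix | pd.DataFrame | np.ndarray,
    labels,
    config: ExperimentConfig | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of the PCA+SVM classifier.

    Standardization and PCA statistics are fit on each training split only
    (no leakage into the held-out fold); the retained component count is the
    smallest explaining at least ``pca_variance`` of the training variance.
    With ``pca_per_fold=False`` the scaler and PCA are fit once on all trials
    (replication mode; leaks test-fold statistics by construction).
    """
    config = config or ExperimentConfig()
    if isinstance(features, TrialFeatureMatrix):
        X = features.values.to_numpy(dtype=float)
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree on trial count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present")
    if counts.min() < config.folds:
        raise ValueError("need at least `folds` trials per class for stratification")

    base = make_classifier(config)
    if not config.pca_per_fold:
        prep = Pipeline(base.steps[:2]).fit(X)
        X = prep.transform(X)
        base = Pipeline(base.steps[2:])

    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    n_components: list[int] = []
    cm_total = np.zeros((2, 2), dtype=int)
    for train, test in skf.split(X, y):
        model = clone(base).fit(X[train], y[train])
        pred = model.predict(X[test])
        cm = confusion_matrix(y[test], pred, labels=[0, 1])
        cm_total += cm
        fold_acc.append(float(np.trace(cm) / cm.sum()))
        fold_sizes.append(int(test.size))
        if config.pca_per_fold:
            n_components.append(int(model.named_steps["pca"].n_components_))
    if not config.pca_per_fold:
        n_components = [int(prep.named_steps["pca"].n_components_)] * config.folds
    (tn, fp), (fn, tp) = cm_total
    return ClassificationReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        n_components=n_components,
        fold_test_sizes=fold_sizes,
    )


# --------------------------------------------------------------------------
# Orchestration


def _features_from_trialset(
    data: LabeledTrialSet,
    config: ExperimentConfig,
    level: str = "fused",
    segmenter: MicrostateSegmenter | None = None,
    trials_per_subject: int | None = None,
):
    """Segment -> back-fit -> featurize a trial set; returns (features, artifacts)."""
    segmenter = segmenter or MicrostateSegmenter()
    n = len(data.trials)
    if trials_per_subject:
        subjects = [i // trials_per_subject for i in range(n)]
    else:
        subjects = [0] * n
    segmenter.fit(data.trials, subjects=subjects)
    sequences = segmenter.predict(data.trials)

    coarse = fine = None
    coarse_names = fine_names = None
    if level in ("coarse", "fused"):
        tf = TemporalFeaturizer(templates=segmenter.templates_)
        pairs = list(zip(sequences, data.trials))
        coarse = tf.fit(pairs).transform(pairs)
        coarse_names = list(tf.get_feature_names_out())
    if level in ("fine", "fused"):
        kf = KmerFeaturizer(k=config.k, n_states=segmenter.n_states_)
        fine = kf.fit(sequences).transform(sequences)
        fine_names = list(kf.get_feature_names_out())
    features = fuse_features(coarse, fine, coarse_names, fine_names)
    artifacts = {"segmenter": segmenter, "sequences": sequences}
    return features, artifacts


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None):
    """Run the full experiment from a configuration mapping or YAML file.

    The configuration holds a ``simulate`` block (study conditions and trial
    counts for the synthetic generator) or a ``data`` block naming a trial
    directory written by the io module, plus optional ``experiment``,
    ``segmentation`` and ``output`` blocks.  Intermediates (templates,
    sequences, features, report) are written under ``out_dir`` when given.
    Re-running the same configuration reproduces the outputs exactly.
    """
    from . import io as mkio

    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to a YAML file")

    exp = ExperimentConfig(**config.get("experiment", {}))
    level = config.get("feature_level", "fused")
    if level not in ("coarse", "fine", "fused"):
        raise ValueError("feature_level must be coarse, fine or fused")

    if "simulate" in config:
        sim_block = dict(config["simulate"])
        n_per = sim_block.pop("n_trials_per_condition", 20)
        sim = SimulationConfig(**sim_block)
        data = make_labeled_dataset(sim, n_per)
    elif "data" in config:
        data = mkio.read_trial_set(config["data"]["directory"])
    else:
        raise ValueError("config needs a 'simulate' or 'data' block")

    seg_kwargs = config.get("segmentation", {})
    trials_per_subject = seg_kwargs.pop("trials_per_subject", None)
    segmenter = MicrostateSegmenter(**seg_kwargs)
    features, artifacts = _features_from_trialset(
        data, exp, level=level, segmenter=segmenter,
        trials_per_subject=trials_per_subject,
    )
    labels = binarize_ratings(data.ratings, exp.threshold)
    report = crossval_classify(features, labels, exp)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mkio.write_templates(out / "templates.csv", artifacts["segmenter"].templates_)
        mkio.write_sequences(out / "sequences.txt", artifacts["sequences"])
        features.values.to_csv(out / "features.csv", index=False)
        report.to_json(out / "report.json")
        (out / "config.json").write_text(json.dumps(config, indent=2, default=str))
    return report, features, artifacts
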