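"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: sequences as one line of '0'..'9' characters
per trial (or FASTA records), templates as CSV with a JSON sidecar, trial
sets as one ``.npz`` array container per trial plus a CSV manifest.  EDF/BDF
reading is delegated to mne when available; DEAP's preprocessed per-subject
containers (pickled dicts with ``data`` and ``labels`` arrays) and its
ratings CSV get thin dedicated readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import LabeledTrialSet
from .types import EEGRecording, MicrostateSequence, TemplateSet

__all__ = [
    "write_sequences",
    "read_sequences",
    "write_sequences_fasta",
    "read_sequences_fasta",
    "write_templates",
    "read_templates",
    "write_trial_set",
    "read_trial_set",
    "read_edf",
    "read_deap_trials",
    "read_deap_ratings",
]


# ---- symbolic sequences ---------------------------------------------------

def write_sequences(path: str | Path, sequences: list[MicrostateSequence]) -> None:
    """One line per trial over the characters '0'..'9'."""
    Path(path).write_text("\n".join(s.to_text() for s in sequences) + "\n")


def read_sequences(path: str | Path, fs: float,
                   n_states: int | None = None) -> list[MicrostateSequence]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    return [MicrostateSequence.from_text(ln, fs=fs, n_states=n_states) for ln in lines]


def write_sequences_fasta(path: str | Path, sequences: list[MicrostateSequence],
                          ids: list[str] | None = None) -> None:
    """FASTA-like export: one record per trial, digits as residues."""
    ids = ids or [f"trial_{i}" for i in range(len(sequences))]
    with open(path, "w") as fh:
        for name, seq in zip(ids, sequences):
            fh.write(f">{name}\n{seq.to_text()}\n")


def read_sequences_fasta(path: str | Path, fs: float = 1.0,
                         n_states: int | None = None) -> list[MicrostateSequence]:
    """Read FASTA records as symbolic sequences (alphabet auto-detected).

    Digit residues map to their value; other residues (e.g. nucleotides) are
    mapped to 0..m-1 in order of first appearance, so the k-mer machinery
    doubles as a generic alignment-free comparison tool.
    """
    records: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current:
                records.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    if current:
        records.append("".join(current))
    alphabet = "".join(dict.fromkeys("".join(records)))
    if all(c.isdigit() for c in alphabet):
        return [MicrostateSequence.from_text(r, fs=fs, n_states=n_states)
                for r in records]
    lut = {c: i for i, c in enumerate(sorted(alphabet))}
    m = n_states or len(lut)
    return [
        MicrostateSequence(np.array([lut[c] for c in r]), fs=fs, n_states=m)
        for r in records
    ]


# ---- templates ------------------------------------------------------------

def write_templates(path: str | Path, templates: TemplateSet) -> None:
    """CSV (rows = classes, columns = channels) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        templates.maps,
        index=[f"class_{k}" for k in range(templates.n_states)],
        columns=[f"ch{i}" for i in range(templates.n_channels)],
    )
    df.to_csv(path)
    meta = {
        "n_states": templates.n_states,
        "gev_total": templates.gev_total,
        "warning": bool(templates.meta.get("warning", False)),
        "min_gmd": templates.meta.get("min_gmd"),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    maps = pd.read_csv(path, index_col=0).to_numpy(dtype=float)
    gev = None
    sidecar = path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gev = meta.get("gev_total")
    return TemplateSet.from_maps(maps, gev_total=gev, meta=meta)


# ---- labeled trial sets ---------------------------------------------------

def write_trial_set(directory: str | Path, data: LabeledTrialSet) -> None:
    """One array container per trial plus a manifest CSV.

    Manifest columns: trial id, condition, rating, file path (relative).
    Ground-truth sequences, when present, go to ``sequences.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(data.trials):
        fname = f"trial_{i:04d}.npz"
        np.savez(directory / fname, data=rec.data, fs=rec.fs,
                 channel_names=np.asarray(rec.channel_names))
        rows.append(
            {"trial": i, "condition": data.conditions[i],
             "rating": data.ratings[i], "path": fname}
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    if data.sequences:
        write_sequences(directory / "sequences.txt", data.sequences)
    if data.templates is not None:
        write_templates(directory / "templates.csv", data.templates)


def read_trial_set(directory: str | Path) -> LabeledTrialSet:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials, conditions = [], []
    for _, row in manifest.iterrows():
        with np.load(directory / row["path"], allow_pickle=False) as npz:
            trials.append(
                EEGRecording(npz["data"], fs=float(npz["fs"]),
                             channel_names=[str(c) for c in npz["channel_names"]])
            )
        conditions.append(str(row["condition"]))
    sequences = []
    seq_path = directory / "sequences.txt"
    if seq_path.exists() and trials:
        sequences = read_sequences(seq_path, fs=trials[0].fs)
    templates = None
    tpl_path = directory / "templates.csv"
    if tpl_path.exists():
        templates = read_templates(tpl_path)
    return LabeledTrialSet(
        trials=trials,
        ratings=manifest["rating"].to_numpy(dtype=float),
        conditions=conditions,
        templates=templates,
        sequences=sequences,
    )


# ---- external formats -----------------------------------------------------

def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/BDF file through mne (optional dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF reading requires mne (install extra 'edf')") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names))


def read_deap_trials(path: str | Path, fs: float = 128.0,
                     n_eeg_channels: int = 32) -> list[EEGRecording]:
    """Read one DEAP preprocessed per-subject container (pickled dict).

    The distribution stores ``data`` as (40 trials, 40 channels, 8064
    samples); the first 32 channels are EEG.
    """
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh, encoding="latin1")
    data = np.asarray(payload["data"])
    return [EEGRecording(trial[:n_eeg_channels], fs=fs) for trial in data]


def read_deap_ratings(path: str | Path, dimension: str = "valence") -> pd.DataFrame:
    """Read a DEAP-style ratings CSV; returns the table with a lowercase
    column for the requested affect dimension."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if dimension.lower() not in df.columns:
        raise ValueError(f"ratings table has no '{dimension}' column")
    return df
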