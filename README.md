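# microkmer

EEG microstate sequence analysis with alignment-free k-mer features, for
affective-state (emotion) classification from multichannel EEG.

Spontaneous scalp EEG passes through a succession of brief (~100 ms)
quasi-stable potential topographies — *microstates*. Labeling every sample
with its best-matching microstate class turns a multichannel recording into
a symbolic sequence, much like a DNA string over a small alphabet. This
package analyzes those sequences at two levels:

- **coarse** — the four conventional temporal parameters per class
  (mean duration, occurrence rate, time coverage, global explained
  variance), a 4·m feature vector;
- **fine** — k-mer statistics borrowed from alignment-free genomics: for
  every word w of length k over the m-state alphabet, the standardized
  deviation of its observed count from the expectation under the sequence's
  own first-order Markov background,

  F_w = (X_w − (n−k+1)·p(w)) / √((n−k+1)·p(w)),
  p(w) = p(w₁)·∏ⱼ T(w_{j−1}, w_j),

  together with the D2 / D2\* similarity statistics and the normalized D2\*
  dissimilarity D2\*_norm = 1 − D2\*(X,Y)/√(D2\*(X,X)·D2\*(Y,Y)) for
  comparing whole sequences.

The pipeline: **segment** (global field power → smoothed-GFP peak
topographies → dual-threshold Atomize-and-Agglomerate Hierarchical
Clustering, which picks the class count automatically from a GEV floor and
a GMD redundancy cut, at individual then group level) → **back-fit**
(absolute spatial correlation labeling + windowed temporal smoothing,
strength 10 / half-size 3) → **featurize** (coarse, fine, or fused) →
**classify** (per-fold standardization, PCA retaining 85% training
variance, SVM, stratified 5-fold cross-validation of ratings binarized at
4.5 into high/low affect).

A first-class synthetic-data module generates the whole experiment from
ground truth — planted topographies, Markov label processes with
controllable dwell and transition structure, GFP-like amplitude modulation,
sensor noise, and two stimulus conditions with 1–9 ratings — so every stage
is testable without any recording.

## Worked example

```python
import numpy as np
import microkmer as mk

config = mk.SimulationConfig(seed=0)            # 32 ch, 4 states, 128 Hz, 30 s, snr 4
data = mk.make_labeled_dataset(config, n_trials_per_condition=40)

seg = mk.MicrostateSegmenter(smoothing_window=5, max_maps_per_subject=1000)
seg.fit(data.trials)
print(f"templates: {seg.n_states_}  GEV: {seg.gev_:.3f}")

sequences = seg.predict(data.trials)
tp = mk.temporal_parameters(sequences[0], data.trials[0], seg.templates_)
print("duration (s):", np.round(tp.duration, 3))
print("coverage:    ", np.round(tp.coverage, 3))

pairs = list(zip(sequences, data.trials))
coarse = mk.TemporalFeaturizer(templates=seg.templates_).fit(pairs).transform(pairs)
fine = mk.KmerFeaturizer(k=5, n_states=seg.n_states_).fit(sequences).transform(sequences)
features = mk.fuse_features(coarse=coarse, fine=fine)
labels = mk.binarize_ratings(data.ratings)
report = mk.crossval_classify(features, labels, mk.ExperimentConfig(k=5, seed=0))
print(f"5-fold accuracy: {report.mean_accuracy:.3f}")
```

prints

```
templates: 4  GEV: 0.971
duration (s): [0.133 0.103 0.136 0.155]
coverage:     [0.226 0.197 0.277 0.3  ]
5-fold accuracy: 1.000
```

The clustering recovered the four planted topographies (explaining 97% of
the GFP-peak variance), the back-fitted sequences show the planted ~100 ms
dwell in their per-class durations, and the fused 16 + 1024 feature vector
separates the two planted transition regimes perfectly under
cross-validation. The same chain runs from the shell:

```
microkmer simulate --n-trials 40 --seed 0 --out trials/
microkmer segment trials/ --window 5 --out templates.csv
microkmer backfit trials/ templates.csv --out sequences.txt
microkmer features sequences.txt --level fine --k 5 --out features.csv
microkmer classify features.csv trials/ --out report.json
```

or from a single YAML config via `microkmer run config.yaml --out out/`.
`microkmer features` also accepts FASTA input, so the D2\*/k-mer machinery
doubles as a generic alignment-free sequence-comparison tool.

Real recordings enter through `microkmer.io`: EDF/BDF files (via mne),
per-subject preprocessed array containers, and a ratings CSV binarized at
the 4.5 cut.

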