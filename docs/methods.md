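# Methods

## The model

Multichannel EEG is treated as a concatenation of microstates: intervals of
~100 ms during which the spatial distribution of scalp potential stays
quasi-stable while its overall strength fluctuates. Writing u(t) for the
channel vector at sample t, the generative picture is

    u(t) = a(t) · map[L(t)] + ε(t)

with L(t) a symbolic label process over m classes, map_k a fixed
topography per class (defined up to sign — a polarity flip of a map is the
same microstate), a(t) > 0 a slowly varying amplitude, and ε sensor noise.
All topographies are average-referenced (channel-demeaned); input
recordings are assumed average-referenced as well.

Global field power, GFP(t) = √((1/N)·Σᵢ(uᵢ(t) − ū(t))²), is the spatial
standard deviation across the N channels; it is invariant to common
offsets, and its peaks mark the samples where the topography has the best
signal-to-noise ratio.

## Segmentation

1. GFP is smoothed with a unit-sum Gaussian window (σ = (len−1)/5,
   reflection padding). The window length must stay below the typical GFP
   peak spacing or the peaks it is meant to stabilize are averaged away;
   the real-data default is 50 samples, and the synthetic experiments use
   5 samples, matched to the generator's 100 ms envelope period.
2. Channel-demeaned topographies at the strictly interior local maxima of
   the smoothed GFP are pooled (optionally with a ±radius neighborhood,
   default the peak sample only).
3. Dual-threshold Atomize-and-Agglomerate Hierarchical Clustering
   (DTAAHC) fixes the class count automatically. Starting from singleton
   clusters: (a) *agglomerate* — any two cluster templates with
   polarity-invariant global map dissimilarity (GMD) below the redundancy
   threshold (default 0.1, i.e. |spatial correlation| > 0.995) are merged,
   closest pair first; (b) *atomize* — the cluster contributing least
   global explained variance (GEV) is dissolved and its members reassigned
   to their best-correlated remaining template, repeatedly, stopping
   before a step that would drop the fitted GEV below the floor (default
   0.85). Cluster templates are the leading eigenvector of the member
   scatter (the polarity-invariant mean), demeaned and unit-normalized,
   recomputed after every step. Ties break deterministically: merges by
   (GMD, lower index pair), assignment and dissolution to the lowest
   index. If the two thresholds are jointly unattainable the full
   singleton solution is returned with a warning flag.
4. Group level: subject template sets are pooled and reclustered with the
   same procedure.

GMD between maps a, b is √(mean((a/GFP_a − b/GFP_b)²)) after channel
demeaning, equal to √(2(1−r)) with r the spatial correlation, minimized
over a sign flip of b when polarity-invariant. GEV of an assignment is
Σₜ (GFP(t)·corr(u(t), map_{L(t)}))² / Σₜ GFP(t)².

## Back-fitting and smoothing

Each sample takes the label of the template with the greatest absolute
spatial correlation (ties to the lowest index; zero-GFP samples fall to
class 0 and are counted). A signed-correlation variant is available for
evoked data. Temporal smoothing then sweeps left to right, relabeling each
sample to maximize

    corr(u(t), map_k)² + (strength / w_t) · N_k(t)

where N_k(t) counts current k-labels within ±half_size samples of t
(excluding t) and w_t is the actual window size (2·half_size in the
interior, truncated at the edges). Defaults strength = 10, half_size = 3;
sweeps repeat to a fixed point (cap 100). At strength 10 the neighborhood
prior dominates the fit term, so genuine runs shorter than roughly the
window half-width are absorbed along with noise flips — the intended
trade-off. strength = 0 returns the input labels unchanged.

## Coarse features

Per class: mean run duration (s), occurrence (runs/s), time coverage
(fraction), and per-class GEV — a flat 4·m vector. Runs touching the
sequence boundaries are counted like any other, which makes
coverage = duration · occurrence an exact identity; a config flag can
exclude them, at the cost of that identity.

## Fine (k-mer) features and D2 statistics

A length-n sequence has n−k+1 overlapping k-mers from the m^k-word space,
ordered lexicographically. The background model is the sequence's own
maximum-likelihood first-order Markov fit: initial distribution = symbol
frequencies over all n samples, transitions = row-normalized bigram
counts, no pseudocounts by default (Laplace smoothing is an option).
Word probability p(w) = p(w₁)·∏ T(w_{j−1}, w_j); expected count
E_w = (n−k+1)·p(w); centralized count X̃_w = X_w − E_w.

- D2 = Σ X_w·Y_w (raw inner product);
- D2\* = Σ X̃_w·Ỹ_w / √(E_w^X · E_w^Y);
- D2\*_norm = 1 − D2\* / √(D2\*(X,X)·D2\*(Y,Y)), symmetric, zero on
  identical inputs, in [0, 2] by Cauchy–Schwarz;
- fine feature F_w = X̃_w / √(E_w), length m^k.

Terms with E_w = 0 and X_w = 0 contribute 0 (the 0/0 := 0 convention);
E_w = 0 with X_w > 0 is impossible under a self-estimated model and raises.
The denominators are square roots of expected-count products, the form
used throughout the D2\* literature; the un-halved normalization of
D2\*_norm is the default.

A consequence worth stating plainly: because the background is each
sequence's own first-order fit, D2\* is asymptotically blind to purely
first-order differences between sequences — that is its design, it filters
background. Discrimination between conditions therefore shows up on
back-fitted sequences, whose noise- and smoothing-induced departures from
first-order structure are condition-specific, and grows with k (3 → 5) as
longer words capture more of that residual structure. Raw planted Markov
chains with different transition matrices do *not* separate in D2\*_norm,
and the tests compare back-fitted sequences accordingly.

## Classification

Ratings (1–9) binarize at 4.5, strictly-greater = high. Features
(coarse 4·m, fine m^k, or their fusion) pass through per-training-fold
standardization and PCA retaining the smallest component count explaining
≥ 85% of the training variance, then an SVM (RBF, C = 1, inverse-scale
kernel width — the classifier itself is unspecified upstream, so standard
defaults, all exposed). Stratified 5-fold cross-validation with a fixed
seed; accuracy = (TP+TN)/(TP+TN+FP+FN) per fold and pooled. Fitting the
scaler/PCA once on all trials (global-fit flag) is available for strict
replication attempts but leaks test statistics by construction and is off
by default.

## Synthetic data

The generator inverts the back-fitting model. Defaults, chosen once as the
study conditions: 32 channels, 128 Hz, m = 4 planted states, 30 s trials,
mean dwell 0.1 s, SNR 4, condition perturbation 0.5.

- *Templates*: random Gaussian channel vectors, demeaned, orthonormalized
  (zero-mean maps span an (n_channels−1)-dim subspace, so strictly
  m < n_channels), then lightly mixed with the mixing shrunk until every
  pairwise |correlation| ≤ 0.5 — separable like real microstate classes
  but not artificially orthogonal.
- *Label process*: first-order Markov; mean dwell enters as the
  self-transition probability p_stay = 1 − 1/(mean_dwell·fs) (geometric
  dwell). Condition B adds `condition_delta` of mass from each state to
  its cyclic successor before row renormalization — note renormalization
  also shortens dwell, so a large delta changes both switching preference
  and run lengths.
- *Amplitude*: rectified sinusoid of 100 ms period plus a 0.05 floor,
  scaled to unit mean — strictly positive and periodic, giving the GFP the
  peak structure the segmentation stage expects (~10 peaks/s).
- *Noise*: white Gaussian per channel, scaled so the realized
  signal-RMS/noise-RMS equals the requested SNR exactly.
- *Ratings*: condition A uniform in [5.5, 8.5], condition B in [1.5, 4.0],
  so the 4.5 binarization recovers the condition labels exactly.

What this emulates: quasi-stable topographies, Markov switching, GFP
amplitude modulation, sensor noise, and two conditions differing in
transition dynamics. What it does not: volume-conducted (spatially
correlated) noise, 1/f spectra, artifacts, non-geometric dwell
distributions, inter-subject topography variability. Passing tests
therefore demonstrate the machinery's correctness and sensitivity under
the planted model, not field performance on recorded EEG.

## Problem sizes and numerics

The test suite and the acceptance script run the experiment at 40+40
trials of 30 s (3840 samples) with the defaults above; segmentation pools
smoothed-GFP peak maps capped at 1000 per subject group (uniform
deterministic subsample). Markov recovery uses a 100,000-sample chain;
template recovery ≥ 500 peak maps at SNR 4. The permutation-null accuracy
is averaged over several independent label permutations because a single
draw at 80 trials has ~0.06 standard error. All randomness flows from
explicit integer seeds (numpy `SeedSequence` spawning for independent
streams); identical seeds reproduce outputs bit for bit.

Degenerate inputs: zero-GFP samples are assigned by the tie rule and
counted; zero-GFP maps are rejected in GMD and dropped before clustering;
all-constant topographies cannot be normalized and raise; a sequence whose
counts match its Markov expectation exactly has zero self-norm and makes
D2\*_norm undefined (raised, not patched).

## Known limitations

- DTAAHC's atomize loop is O(N²)–O(N³) in the pooled peak-map count; the
  per-subject cap (and the two-level subject→group design) is the intended
  mitigation for large datasets.
- The exact reference formulations of the clustering and of the temporal
  smoothing are toolbox conventions that vary across the literature; the
  procedures above are standard forms with every constant exposed in
  config, and results at different constants are not interchangeable.
- With 10 classes the fine vector at k = 5 has 10⁵ entries; memory and PCA
  cost grow accordingly (the upstream advice holds: prefer longer k only
  with few classes).
- Readers for external recordings (EDF via mne, pickled per-subject
  containers, ratings CSV) are thin and assume preprocessed,
  average-referenced input; no artifact handling is provided.
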