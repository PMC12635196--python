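# Methods

`crossrun-dia` implements a cross-run, peptide-centric analysis of
data-independent-acquisition (DIA) chromatograms in which match-between-runs
(MBR) alignment happens *before* statistical scoring. This note documents the
model, its assumptions, the tunable parameters, the synthetic data the tests
run on, and the numerical choices made where the design was open.

## Workflow model

For each precursor in a spectral library, per-run extracted-ion chromatograms
(XICs) of the top-6 fragment ions are scored by a sliding window (stride one
grid point), producing a continuous *scoring profile* per run: the main
peak-quality score plus spectral cosine, MS1-area and MS2-area traces. Runs
are then related through anchor peptides: a stratified iRT sample of the
library (default 4000, equal-width iRT bins, 20% extra draws in the two edge
bins) is located in every run at the profile argmax (*best RT*), validated by
spectral cosine > 0.95, and fitted against library iRT with a linear or
lowess model. Anchors whose fit residual, converted to seconds through the
local slope, is below 60 s are *inliers*.

Inlier sets define the global run-similarity matrix. The default metric is
the Dice overlap of inlier IDs,

    w_ij = 2 * N_common / (N_i + N_j),

with total-intensity cosine, mean XIC cosine and aligned-XIC cosine as
alternatives. A minimum spanning tree over distances `1 - w_ij` restricts
pairwise alignment to adjacent, highly similar runs, so each peptide needs
exactly `n_runs - 1` alignments (linear, not quadratic, in runs). Alignment
is either the fitted global model alone (assumes preserved elution order) or
a banded Needleman–Wunsch dynamic program per peptide on top of the global
constraint. Mappings are composed along tree paths to a root run (the run
with maximal total similarity) and profiles are interpolated onto its grid.

Candidate peaks are picked *once* on the run-averaged main-score profile
(top 10 local maxima, greedy minimum separation) and applied to every run.
Each candidate then receives, per run and per score type, a *multi-run score*

    s_multi = sum_j phi(w_tj) * s_j / sum_j phi(w_tj),
    phi(w) = (k^w - 1) / (k - 1),

a convex combination of the aligned single-run scores weighted by decayed
global similarity to the target run (the target itself enters with weight 1).
The decay coefficient `k` (default 50; 0 disables decay, k = 1 is the
identity limit) leaves weights near 1 nearly untouched and crushes small
weights, so dissimilar runs cannot inflate a peak's evidence. `k` can be
selected automatically from the first elbow (maximum chord distance on the
Gaussian-smoothed curve, restricted to the initial descending segment) of the
identification-count-versus-k curve on a ~10% downsampled library.

A semi-supervised random-forest (or gradient-boosted) discriminant separates
targets from decoys using 4 single-run scores, 4 multi-run scores, delta-RT,
peptide length and charge; q-values follow from the decoy score distribution;
quantities are MS2 window areas of accepted rank-1 candidates.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | 17 points | sliding-window width (odd, centred); edge replication |
| `n_anchors` / `oversample_edge` | 4000 / 0.20 | anchor sample size; extra quota for edge iRT bins |
| `cosine_threshold` | 0.95 (strict >) | anchor validation |
| `residual_threshold_s` | 60 s | inlier cutoff, seconds-equivalent via local slope |
| `band_width_s` | 180 s (3× residual threshold) | DP band around the global model |
| `gap_penalty` | 0.05 | per-step gap cost against the intensity-weighted similarity |
| `k` | 50 | weight-decay coefficient (0 = off) |
| `top_n_candidates` / `min_separation_s` | 10 / 24 s | consensus picking |
| `q_cutoff` | 0.01 | experiment-wide precursor q-value threshold |

## Numerical and design choices

* **Default scorer.** The pluggable scorer's default is a deterministic
  composite: mean of (i) mean pairwise Pearson correlation between fragment
  traces, (ii) correlation of the summed trace with a Gaussian template, and
  (iii) spectral cosine at the window centre — each mapped to [0, 1] by
  clamping negatives, since anti-correlation carries no co-elution evidence.
  The affine map `(r+1)/2` was rejected: it gives pure-noise windows a 0.5
  floor on two components, which caps profile SNR and buries the averaging
  gain the cross-run profile is designed to deliver. Any model with the same
  signature (e.g. a trained neural scorer) can be injected.
* **DP similarity.** The point-pair similarity is the cosine between the two
  runs' fragment-intensity vectors *scaled by the geometric mean of relative
  column intensities*. Plain cosine is unusable on baseline-subtracted,
  non-negative traces: noise columns have cosine ≈ 0.85 against anything, so
  the DP loses all contrast and collapses onto the global model. The
  intensity weighting (the masked-dot-product flavour familiar from XIC
  alignment) makes baseline matches nearly free and peak correspondence
  decisive; the gap penalty (0.05/step) is calibrated to that scale.
  Tie-breaks prefer diagonal, then gap-in-j, then gap-in-i; many-to-one
  aligned points collapse by averaging; non-monotone composed mappings are
  repaired by a running-maximum projection.
* **Lowess RT models** (span 0.3) are made monotone by isotonic
  post-correction so mappings stay invertible for synchronization; linear
  extrapolation beyond the fitted range.
* **q-values.** FDR(t) = π₀ · #decoys≥t / #targets≥t with the decoy count
  rescaled by the target/decoy size ratio (exact at a 1:1 decoy library);
  π₀ is twice the fraction of targets at or below the decoy median, capped
  at 1; q-values are the running minimum. q-values are *global*
  (experiment-wide over run–precursor rows), reported for rank-1 candidates
  only; lower ranks participate in learning only.
* **Cross-validation is grouped by precursor.** Rows of one peptide share
  sequence-level features (length, charge); row-wise folds would let the
  forest memorize peptide identity and overstate separation.
* **Multi-run weights are normalized** to sum 1 and include the target run:
  the combination is then convex, so multi-run scores live on the same scale
  as single-run scores for the classifier.

## Synthetic data

The generator emulates multi-run DIA XIC sets with known ground truth:
Gaussian co-eluting fragment peaks (σ = 8 s on a 2 s grid) with intensities
proportional to the library spectrum; per-run RT shifts (none, linear in run
index, smooth sinusoidal "lowess-like" warps, or peptide-specific offsets
that swap elution order and motivate per-peptide DP alignment); additive
truncated-Gaussian detector noise; whole-group peptide dropout for run
heterogeneity; decoys as library entries with permuted fragment intensities
and noise-only traces; and two-group entrapment designs where a tagged
peptide subset is truly absent from one group while remaining in the library.

Interference is modelled as a *cofragmenting analyte with its own
reproducible elution time*: one interferer RT per precursor, present per run
with the configured probability, shifted with the run, hitting a fixed
fragment subset, and bleeding into the MS1 channel at reduced amplitude.
Reproducible interferers matter: run-random interference gives decoys no
cross-run-consistent signal at all, making the null unrealistically easy and
the 1% FDR threshold vacuous.

What the generator does **not** model: m/z-domain signals, isotope
envelopes, peak tailing/fronting, gradient-dependent peak-width changes,
correlated (pink) noise, or library iRT errors. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not performance on vendor raw data.

Problem sizes in the test-suite experiments (8–24 runs, 50–60 peptides,
300-point grids, 1:1 decoys) are chosen so the full workflow remains
desk-scale while keeping every mechanism active; the entrapment experiment
uses 24 runs (12 + 12), 20% entrapment peptides, 15% group dropout and
interference on 80% of run-peptides so the between-group similarity sits
near 0.75 and cross-run score transfer is strong enough to measure.

## Degenerate inputs and edge rules

All-zero scoring windows score 0; zero-vector cosines are defined 0; ties at
the profile argmax resolve to the smallest RT; equal-score peak candidates
rank lower-RT first; an empty DP band falls back to the global mapping with
a warning; an all-NaN profile stack skips the peptide; zero decayed weight
mass falls back to the target run's own score; SNR with a zero outside
maximum reports +inf.

## Known limitations

* The default composite scorer is a transparent stand-in for a trained
  peak-group model; absolute identification numbers on real data would
  depend on that model's quality.
* Global q-value scope (not per-run) is a fixed choice, flagged in the
  result manifest.
* The DP aligner implements a single linear gap model, not overlap-penalty
  or hybrid variants of published XIC aligners.
* Protein-level FDR is out of scope; protein rollup is top-3 precursor
  summation only.
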