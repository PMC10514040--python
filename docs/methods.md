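# Methods

## Problem and pipeline

`plvnet` implements a phase-synchrony brain-network analysis for multichannel
EEG recorded under Ganzfeld stimulation (homogeneous visual field, flickering
at eight target frequencies, with three soundscape-induced moods), aimed at
contrasting two groups defined by positive schizotypy: a small
high-schizotypy-like group (HS, n = 14) and a larger low-schizotypy-like
group (LS, n = 29). The chain is:

1. **Preprocessing** — downsample to 256 Hz (polyphase, anti-aliased),
   common average reference, 0.5–40 Hz zero-phase FIR, decomposition into
   six sub-bands (delta 2–4, theta 4–8, alpha-low 8–10, alpha-high 10–13,
   beta 13–30, gamma 30–40 Hz), and 20 non-overlapping 4-s epochs per
   condition cell.
2. **Connectivity** — per channel pair and band, the phase-locking value
   PLV = |N⁻¹ Σₖ exp(i·Δφ(tₖ))| of Hilbert instantaneous phases, computed
   per epoch and averaged over the 20 epochs; edges pruned against a
   phase-permutation surrogate null (M = 100, α = 0.05).
3. **Graphs** — proportional density thresholding (0.01–0.50, step 0.01;
   features at 0.08), node strength, Onnela weighted clustering, global
   efficiency.
4. **Statistics** — Welch's t (HS − LS) at edge level with
   Benjamini–Hochberg FDR, at node level at uncorrected p < 0.05 (p < 0.001
   flagged separately), and on GE per density; one-sample KS normality
   screening is reported but does not gate the t-tests.
5. **Classification** — per mood, features {CC, strength} × channel × band ×
   target frequency at density 0.08 plus GE × band × frequency; Welch-|t|
   filter selection re-fit inside every leave-one-out fold; DT, KNN (K = 5),
   LDA, linear SVM, and RUSBoost; HS is the positive class.

Because the underlying EEG cohort is not public, all end-to-end behavior is
exercised on a synthetic generator with known ground truth.

## Synthetic coupling model

Exact joint control of an arbitrary 64×64 pairwise von Mises concentration
matrix is infeasible, so coupling is parameterized by channel **blocks**.
Per band and epoch each channel's phase is

    φ_c(t) = θ(t) + Δ_b(t) + δ_c(t),

with θ a band-center oscillation, Δ_b the block offset from the global
reference (von Mises, concentration = the block's attachment κ) and δ_c the
channel's jitter around the block phase. For a within-block pair the phase
difference is a difference of independent von Mises variates, so the pair
PLV equals the product of the channels' mean resultants r(κ) = I₁(κ)/I₀(κ);
channel concentrations are set by inverting r so a block with target κ
yields pair PLV r(κ). A block may declare an anchor channel (zero jitter),
making anchor–partner differences *exactly* von Mises(κ); the
parameter-recovery experiments use anchored two-channel blocks.

Two numerical choices matter:

* **Stratified jitter.** Jitter values are stratified von Mises quantiles
  in random order, which pins each epoch's empirical resultant at r(κ) and
  removes the small-sample positive bias of |mean-phasor| estimates. Without
  it, 16–32 effective draws per epoch would inflate PLV by up to +0.1 at
  low κ.
* **Jitter timescale.** Values are piecewise constant over 0.25-s segments
  with cosine cross-fades. Per-sample i.i.d. jitter would whiten the band
  component and the FIR + Hilbert stage could not recover the planted
  coupling (uncoupled pairs then measure PLV ≈ 0.17 through the filter);
  the slow segments keep the phase modulation inside the band. The price is
  a small residual floor through the signal route (≈ 0.04–0.05 at κ = 0,
  from the finite number of independent phase states per epoch — analogous
  to the PLV sample-size floor in real data). Exact Bessel-ratio recovery
  is therefore asserted on the generator's ground-truth phases (errors
  < 0.03 for κ in 0.5–5 with 20 epochs), and the signal route is asserted
  for monotonicity, sign and looser tolerances.

Channels sum the six band cosines plus 1/f-shaped Gaussian noise at a
configurable SNR (default 0 dB). Noise attenuates measured PLV equally in
both groups; group ordering is preserved.

**Planted group structure** (defaults of `default_coupling_plan`): baseline
within-block κ = 2.0 for the bilateral temporal/frontotemporal blocks, 1.5
occipital/parieto-occipital, 1.0 prefrontal, background attachment 0.5; the
HS-like group's temporal/frontotemporal κ is multiplied by 0.5 and its
occipital/parieto-occipital κ by 1.6, reproducing the direction of the
reported group differences (LS higher temporally, lower occipitally, higher
global efficiency). Per-subject block κ carries lognormal variability
(σ = 0.15) so groups overlap realistically. These effect sizes were chosen
once so that the full pipeline separates the groups clearly (best
classifiers reach ~100 % LOO accuracy on 29+14 subjects, RUSBoost ≥ 90 %);
they are config values, not hard-coded.

What the generator does **not** emulate: volume conduction and field spread
(a dominant source of spurious synchrony in real EEG), ocular/muscle
artifacts, non-stationary amplitude dynamics, SSVEP entrainment at the
flicker frequency, and condition-dependent coupling (all moods and target
frequencies share one coupling plan by default). Passing tests therefore
demonstrate the estimators and the inference chain, not robustness to those
real-data confounds.

## Connectivity and surrogate null

Instantaneous phase is the argument of the analytic signal
(`scipy.signal.hilbert`) of the band-filtered epoch; a frequency-domain
analytic-signal construction serves as an independent cross-check. The PLV
complex-mean and sin/cos quadrature forms are both implemented and agree to
1e-12 (identity check in the tests).

Surrogates randomly permute the time samples of the **second** channel's
phase sequence — a full permutation, not a circular shift — with a fresh
permutation per surrogate per epoch, shared across pairs within a
surrogate for efficiency; surrogate PLV is epoch-averaged exactly like the
observed statistic. The empirical one-sided p-value is
(1 + #{PLV_surr ≥ PLV_obs})/(M + 1); entries with p ≥ α are zeroed, the
rest keep their observed values. With M = 100 and α = 0.05 the nominal
null retention rate is 5/101 ≈ 0.0495; calibration is verified Monte-Carlo
on independent white-phase pairs, where observed and surrogate statistics
are exchangeable. On strongly autocorrelated (narrowband) phase series the
permutation null destroys autocorrelation and the test is anti-conservative
relative to a null of independent *narrowband* processes — the standard
behavior of this surrogate family, worth remembering when interpreting
near-threshold edges.

## Graph metrics

Thresholding keeps the strongest round(density · N(N−1)/2) upper-triangle
weights (round half away from zero; ties broken by ascending (i, j) index),
preserving weights. At density 0.08 on 64 nodes this is 161 edges.
Strength is the weighted degree. Clustering follows Onnela's geometric-mean
triangle intensity on weights normalized by the matrix maximum (CC ∈ [0, 1],
scale-invariant); nodes with degree < 2 get CC = 0. Global efficiency uses
edge lengths 1/w with Dijkstra shortest paths; disconnected pairs
contribute zero. By default GE is computed on max-normalized weights so
GE ∈ [0, 1]; `normalize=False` gives raw-weight GE.

A consequence worth stating: at a *fixed* proportional density both groups
retain the same edge count, and max-normalization divides out the overall
coupling level, so normalized GE carries no planted group sign in the
synthetic model — it measures relative weight topology. The planted global
effect (LS-like subjects more strongly coupled overall) appears in
raw-weight GE on the pruned matrices, which is what the group-effect tests
assert; both variants are exposed.

## Statistics

Group contrasts are Welch's unequal-variance t with Welch–Satterthwaite
degrees of freedom, signed HS − LS (negative t ⇒ LS higher). The FDR family
is the edge set of one (band × target frequency × mood) panel. The
demographics worked examples compute the two-group one-way ANOVA F from
(mean, SD, n) summaries — algebraically the squared pooled t, df
(1, n₁+n₂−2) — and the 2×2 Pearson chi-square without continuity
correction. KS normality standardizes by the sample's own moments
(Lilliefors-style), which makes the tabulated p conservative; it warns but
never gates.

## Classification

Feature ranking uses |Welch t| with stable index tie-breaking, re-fit
inside each LOO training fold (the leakage-free reading; a deliberately
leaky global mode exists behind a flag for comparison). k = 10 features by
default. KNN/LDA/SVM see features z-scored by training-fold statistics;
trees are scale-invariant and see raw features.

RUSBoost is AdaBoost.M1 with per-round random undersampling: each round
draws all minority rows plus an equally sized majority subsample (without
replacement, probability proportional to current boosting weights), fits a
depth-3 CART tree, and computes the weighted error, learner weight
(learning rate 0.1) and multiplicative weight update on the full training
set. Rounds with error ≥ 0.5 are discarded and redrawn; perfect rounds get
an error floored at 1/(2n) so boosting continues to average over many
balanced resamples rather than collapsing onto a single subsample tree
(without the floor, LOO accuracy drops by ~5 points and becomes
seed-sensitive). With undersampling disabled and learning rate 1 the
algorithm reduces to plain AdaBoost.M1 and is checked against
scikit-learn's AdaBoostClassifier round for round.

Report metrics truncate (not round) percentages to two decimals
(41/43 = 95.348 → 95.34), matching the arithmetic of the reported
confusion tables; F1 is reported as a truncated proportion (13/14 → 0.92).

## Problem sizes

The full study design — 43 subjects × 3 moods × 8 target frequencies × 6
bands, each with 100-surrogate pruning over 2016 channel pairs and 20
epochs — is a cluster-scale computation by construction. The package's own
validation runs use deliberately scaled extents: the acceptance/test cohort
is the full 29+14 subjects but one condition cell and the beta band
(~2 minutes end-to-end); group-effect recovery uses an 8+8 cohort on a
19-channel montage restricted to the planted regions; surrogate calibration
uses 500 Monte-Carlo pairs. Extents are config fields
(`moods`, `target_frequencies`, `bands`, `density_grid`), so the full
design is a configuration change, not a code change.

## Known limitations

* Coupling targets are exact for within-block and anchored pairs; cross-
  block pair PLV follows the product-of-resultants path through the global
  reference and is controlled only at block level.
* The surrogate test's exchangeability argument holds per epoch; epochs are
  treated as independent.
* LDA uses lsqr with automatic shrinkage (p ≫ n after selection is still
  possible with large k).
* EDF export quantizes to 16 bits over the recording's symmetric amplitude
  range; round-trips are exact only to that quantization.
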