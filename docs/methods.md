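# Methods

This note documents the models, estimators, defaults and design
decisions behind `rcnet`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Functional connectivity networks (`rcnet.fc_network`)

ROI time series (rows = time points, columns = ROIs labelled
`hemisphere:name`) are band-pass filtered to the slow-fluctuation band
0.01–0.1 Hz with a zero-phase order-4 Butterworth filter
(`sosfiltfilt`; band edges are −3 dB points). Series too short for the
filter's edge padding are rejected with an explicit error rather than
silently truncated. FC is the Pearson correlation between every ROI
pair, computed on an analysis window of 500 time points per condition —
the first 500 of a pre-condition run and the last 500 of a
post-condition run (configurable via `RunConfig.window_len`). The full
window is used for each correlation; no sub-windowing.

Cross-animal aggregation defaults to the plain arithmetic mean of *r*;
a Fisher-z mode (atanh → mean → tanh) is available through
`average_fc(..., mode="fisher")` for robustness comparisons. Between-
animal variation is summarized as the element-wise sample SD (n−1
denominator).

Networks are built **after** averaging: each ROI pair with averaged
r > 0 becomes an undirected edge of weight r. Negative *and exactly
zero* correlations are excluded, so all weights are strictly positive
and a weight reshuffle can never produce a zero-weight edge.
Hemispheric sub-networks are the induced subgraphs on `ipsi:`/`contra:`
nodes with their edge-weight ranking recomputed. Ties in the descending
weight ranking are broken by (i, j) lexicographic order — the rich-club
ratio is tie-invariant (it only ever sums the top-E values), so this
choice affects nothing but determinism.

## 2. Weighted rich-club estimation (`rcnet.richclub`)

* **Club rule.** Strict inequality: the club at threshold *s* is
  {i : s_i > s}.
* **Denominator.** The E_>s largest edge weights of the *entire*
  network, not of the club.
* **Null model.** Edge weights are permuted uniformly over the fixed
  edge set (topology, node set, weight multiset and total weight are
  conserved). Strengths and club membership are recomputed on every
  null network — the statistic is a function of the network, so the
  null value must be the statistic of the null network, not the
  observed clubs with substituted weights.
* **Normalization.** rho_w divides by the *mean* of the null phi values
  (1000 nulls by default, reducible for tests); the full null sample is
  retained in `RichClubCurve.phi_random_samples` so users can form
  empirical bands.
* **Threshold grid.** Evenly spaced from 0 toward the disintegration
  point: the smallest strength value at which the club drops below 3
  nodes or 2 internal edges (both configurable). The grid is half-open
  — it approaches but never reaches disintegration. Thresholds at which
  the observed phi or any null phi is undefined (edgeless club) are
  reported as NaN, never imputed as 0.
* **Undefined values.** `phi_w` returns `None` (not 0) for an empty or
  edgeless club; curve code propagates NaN.

The hot path is vectorized: for B weight assignments on a fixed
topology, club membership over all thresholds is evaluated as a
(B, nodes, thresholds) boolean tensor and edge-internal sums as batched
reductions, which keeps 1000-null curves and 999-permutation
comparisons within seconds to minutes on one CPU core.

### Pre/post comparison

Curves are compared with a paired condition-label sign-flip permutation
test at the animal level: each permutation swaps pre/post for a random
subset of animals, then repeats the entire average → network → rho_w
derivation in the requested scope (whole brain, ipsi, contra). When
2^n_animals ≤ the permutation budget, all label assignments are
enumerated exactly and the observed assignment is one of them, giving
exact p-values with floor 1/2^n; otherwise Monte-Carlo sampling with
the (b+1)/(m+1) correction is used. Two-sided p-values per threshold
compare |Δrho|; thresholds undefined in the observed curves or any
permutation get NaN p-values (flagged missing, not imputed). Both
condition curves inside one permutation share the same null-model
random draws (common random numbers), so Δrho carries no between-curve
Monte-Carlo noise and is exactly zero for identical groups.

A consequence worth stating: with 3 animals the smallest attainable
exact p is 1/8, so no threshold can reach α = 0.01 in a 3-animal
cohort under this scheme. Published asterisks at that sample size must
rest on a different (unstated) permutation unit; this package keeps the
animal-level paired scheme because it respects the experimental design,
and demonstrates detection power at n = 12 instead.

## 3. Synthetic cohorts (`rcnet.synthetic`)

The analysis consumes only second-order structure, so the generator is
a multivariate Gaussian with a structured target correlation matrix —
hemodynamic forward modelling would add untestable complexity without
exercising any additional code path.

### Target correlation matrices

Each animal/condition target is a sum of factor contributions, hence
positive semi-definite by construction:

* **Global integration factor.** Per-node loadings λ_i with a bimodal
  cohort-level distribution: a `peripheral_fraction` (default 0.25) of
  ROIs is weakly integrated (λ uniform on 0.05–0.25), the rest form a
  graded core (normal, SD `hub_sd` = 0.18, clipped to 0.30–0.75).
  Loadings are renormalized so the mean pair product equals
  `base_inter_r` (0.35). The post-condition scales background loadings
  by √(inter_post/inter_pre), realizing the interhemispheric drop
  (`inter_delta` = −0.20).
* **Hemisphere factors.** One factor per hemisphere carries the
  intra-hemispheric surplus (`base_intra_r` − `base_inter_r` = 0.10
  pre; raised post by +0.10 ipsi, +0.05 contra).
* **Club.** The 8 club members (4 per hemisphere, drawn once per
  cohort) carry global loading √`club_r`, so club×club entries equal
  `club_r` = 0.8. Post-condition, half the club slots
  (`hub_reshuffle_fraction` = 0.5) are reassigned to non-club nodes,
  modelling the observed post-injection reordering of hub identity.
* **Signed community factors.** Three communities with signed loadings
  whose magnitude grows as λ falls: weakly integrated nodes scatter
  most, pushing their weakest pairs below zero. This mirrors two
  robust features of real FC matrices — anticorrelated network blocks,
  and the coupling between a region's integration level and its count
  of near-zero/negative correlations — and it is what gives the
  derived networks degree heterogeneity aligned with strength. That
  alignment matters: the reshuffle null preserves topology, so only
  genuine weight–topology structure (not additive noise) can produce
  rho_w > 1 over a range of thresholds.

Per-animal symmetric Gaussian jitter (`animal_sd` = 0.03 per entry)
is added afterwards; the tiny PSD violations it introduces are repaired
by eigenvalue clipping at 10⁻⁶ with renormalization to unit diagonal,
and the repair magnitude is logged (it is orders of magnitude smaller
than the structural terms, unlike repairs of additively perturbed
block matrices, which was the reason for the factor construction).

### Signal generation

White-in-time Gaussian draws are mixed through the Cholesky factor of
the target, AR(1)-smoothed (coefficient 0.4), band-limited and
re-standardized per channel, then white sensor noise (`noise_sd` = 0.1)
is added. Identical temporal filtering of all channels leaves the
cross-channel correlation invariant, so windowed empirical FC converges
to the target as T grows. The band limit is asymmetric by design: a
steep order-4 high-pass at 0.01 Hz (slow drift would otherwise dominate
500-point windows and inflate between-window FC variability far beyond
what the emulated study reports) and a gentle order-1 low-pass at
0.1 Hz (soft spectral skirts, as real hemodynamic signals have; a steep
low-pass would leave ≈45 effective samples per window and push the
across-animal FC SD above the reported 0–0.4 range). `noise_sd` and
`animal_sd` were calibrated once so that the across-animal SD of
windowed FC lands inside that range; they were not revisited
afterwards.

What the generator does *not* emulate: hemodynamic response shapes,
physiological noise spectra (cardiac/respiratory), motion, scanner
drift, spatial autocorrelation between neighbouring ROIs, and
non-Gaussian tails. Tests passing on this generator therefore establish
the correctness and power of the *estimators* under the assumed
covariance structure, not robustness to real-world artefacts.

### EEG

Two channels share per-band band-limited sources: each band contributes
`amplitude · (√r · shared + noise_gain · √(1−r) · private)` per channel,
so the within-band epoch correlation approximates the configured r.
After the injection time (7.5 min of a 15 min recording), theta and
alpha shared fractions drop 0.8 → 0.3, gamma rises transiently
(0.5 → 0.85 for 2 min), delta and beta stay unchanged; the broad-band
correlation falls as an arithmetic consequence of the theta/alpha drop
(from ≈0.75 to ≈0.51 at the default amplitudes — values the ground-truth
dictionary reports and the tests verify). With `noise_gain=0` the
channels are identical and every epoch correlation is exactly 1.

## 4. EEG synchronization analysis (`rcnet.eeg_sync`)

Bands: delta 1–5, theta 5–8, alpha 8–15, beta 15–30, gamma 30–250,
broad 1–255 Hz. Shared edges belong to both neighbouring bands; no
half-open convention is imposed. Band edges are −3 dB points of a
zero-phase order-4 Butterworth filter. The broad band's printed 255 Hz
upper edge exceeds what a 250 Hz-limited acquisition passes — likely a
reporting quirk in the emulated protocol — and any edge at or above
Nyquist is clipped to 0.99 × Nyquist with a logged warning rather than
re-interpreted.

The recording is filtered once per band and then cut into consecutive,
non-overlapping 30 s epochs (partial trailing epoch discarded;
15 min → 30 epochs); synchronization is the Pearson r between the two
band-filtered channels within each epoch. Filtering before epoching
avoids per-epoch filter transients; a property test bounds the
difference against the epoch-then-filter order on interior epochs.
Zero-variance epochs yield NaN, not 0.

## 5. Numerical and statistical choices

* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` substreams (generator, null model,
  permutations are independently reproducible). Generator outputs are a
  pure function of (config, seed).
* The null-calibration test evaluates the 3-SE band only at thresholds
  where rho varies across draws; at degenerate thresholds (club =
  whole network in essentially every draw) rho is a point mass at 1
  and the normal-theory band is meaningless — equality within 10⁻³ is
  checked there instead.
* Monte-Carlo rho has a small positive Jensen bias of order
  Var(phī_null)/phi², negligible at the default 1000 nulls.
* Simulation sizes in the test suite (null counts of 50–200,
  permutation budgets of 100–999, 8–40 seeds per property) keep the
  default run at a few minutes while leaving comfortable statistical
  margins; `rho_w` defaults to 1000 nulls for analysis use.

## 6. Known limitations

* The rich-club comparison assumes paired pre/post designs; unpaired
  groups are rejected rather than approximated.
* rho_w is undefined wherever any null club loses its last internal
  edge; very sparse networks may disintegrate before interesting
  thresholds are reached.
* The generator's disruption effect sizes are calibrated to reproduce
  qualitative directions (interhemispheric drop, intrahemispheric rise,
  hub reshuffling) and the reported variation range — not quantitative
  effect magnitudes, which the emulated study does not publish.
* Fisher-z averaging diverges for |r| = 1; inputs are clipped at
  1 − 10⁻¹⁵ before the transform.
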