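# Methods

## Signal model and assumptions

The package addresses instantaneous, noiseless linear mixing:
X(t) = A·S(t), with M observed channels, N sources, M < N, and
A ∈ R^{M×N} constant over the recording. There are no delays, filters or
reverberation — each microphone sees a memoryless weighted sum. All
guarantees below further assume the sources are *sparse in the STFT
domain*: at most one source dominates most time-frequency points. Under
that premise the cross-channel STFT coefficient vector at a
single-source point is parallel to one column of A, which is what both
the matrix estimator and the recovery step exploit.

## Single-source-point extraction

STFT: Hann window of 512 samples, hop 256 (COLA-exact inversion),
one-sided spectrum, unnormalised coefficients. Three screens run in
sequence on the masked grid:

- **Energy mask** `e = 0.05`: a time-frequency point is zeroed (jointly
  across channels, so the channels stay synchronised) when the squared
  norm of its stacked cross-channel coefficient vector falls below `e`.
  Inputs are normalised to [−1, 1] on read so the threshold is
  scale-meaningful.
- **Ratio screen** `ε₁ = 0.01`: keep a point iff every channel pair
  agrees on Im/Re within ε₁. For M > 2 all pairs must pass (pairwise
  consistency is the natural generalisation of the two-channel
  criterion). Points with any |Re| < 10⁻⁶ are dropped outright rather
  than risking ratio blow-up.
- **Variance screen** `G = 6`, `ε₂ = 0.05`: candidates ordered by
  (bin, frame) are cut into runs of G consecutive points within one
  frequency bin ("constant frequency, adjacent time"; a partial tail run
  is dropped), and a run survives iff the per-channel sample variance
  (1/(G−1)) is below ε₂. The variance is evaluated on unit-normalised,
  sign-canonicalised feature vectors, not raw real parts: the raw real
  part of a stationary tone rotates in phase from frame to frame (it
  alternates sign in odd bins at half-window hop), so a raw-value
  variance would be phase- and scale-dependent and discard genuine
  single-source neighbourhoods. Direction variance is scale-free, zero
  for a perfect single-source run, and keeps ε₂ interpretable as an O(1)
  angular-stability tolerance.

Retained features are the real parts of the coefficients (the imaginary
parts carry the same direction; the real parts are the conventional
scatter-plot axis). A `σ = 0.5` placeholder appears in the configuration
for compatibility with published settings lists; nothing reads it.

## Mixing-matrix estimation

Features are scaled to unit norm with the sign flipped so the first
non-negligible component is ≥ 0: single-source points live on lines
through the origin, and without normalisation amplitude spread dominates
the Euclidean similarity.

**Affinity propagation.** Similarity s(i,k) = −‖p_i − p_k‖², preference
(diagonal) = median of the off-diagonal similarities. Standard
responsibility/availability message passing with damping
m ← λ·m_old + (1−λ)·m_new; exemplars are the indices with positive
decision value R(k,k)+W(k,k); the run stops when the exemplar set is
unchanged for 50 consecutive iterations, or at 500 iterations.

**Adaptive damping.** λ starts at 0.5. Each iteration records a flag:
1 when the cluster count decreased or stayed equal *with the same
exemplars*, 0 when it grew, collapsed to zero, or kept its count while
the exemplar identities churned. When strictly more than 2/3 of a
6-record window shows 0, λ increases by 0.01 and the window clears; a
second trigger fires when the count window is non-constant with no net
decrease (a purely count-based rule is blind to period-2 limit cycles,
where counts alternate a↔b and exactly half the records are 0 — observed
routinely on clean synthetic data at λ = 0.5). λ never decreases and is
capped at 0.99: at λ = 1 the damped update is a no-op and the messages
freeze, so the usable ceiling sits just below it. On the worked scenario
λ typically plateaus between 0.78 and 0.89 with the cluster count locked
at the true source number.

**Subsampling.** AP is O(L²) in memory and time, and — measured on this
generator — similarity matrices built from ≥ 800 near-duplicate
directions push the message passing into a degenerate slow regime that
exhausts the 500-iteration budget. The estimator therefore runs AP on a
seeded uniform subsample of at most `l_max = 300` points (24/24
convergence across a duration × seed calibration grid; the count
estimate saturates far below 300 points), while the K-means refinement
runs over *all* retained points, so the final accuracy does not depend
on the subsample. Lloyd iteration starts from the AP exemplars, tracks
the (provably non-increasing) sum-of-squares objective each iteration,
re-seeds an emptied cluster to the farthest point, and stops at centre
movement < 10⁻⁸ or 100 iterations. Â's columns are the final centroids,
unit-normalised under the same sign convention. The silhouette
coefficient of the final labelling is reported as a clustering
diagnostic (NaN for a single cluster).

An optional SSA-style preprocessing stage (off by default) Hankel-embeds
each channel, truncates the SVD to an energy fraction (default 0.95) and
de-Hankelises by anti-diagonal averaging; long recordings are processed
in 1024-sample blocks because a full-length embedding of a 12 s
recording at 44.1 kHz would be a ~265 000² matrix. Per-channel
truncation slightly perturbs the exact cross-channel proportionality the
ratio screen tests for, so the stage is useful for noisy inputs and
neutral-to-harmful on clean synthetic data — another reason it defaults
off.

## Source recovery

Per-sample minimal-l1 subset selection in the time domain: all C(N, M)
square column subsets of Â are enumerated in lexicographic order,
submatrix inverses are precomputed once (subsets with condition number
≥ 10⁸ are skipped; if all are skipped the sample is zeroed with a
counted warning), and for each sample the candidate B_k⁻¹x with minimal
l1 norm wins, ties to the lowest subset index. Batched evaluation uses a
broadcast multiply-sum rather than BLAS matmul so the batch is
bit-identical to a sample-at-a-time loop. An experimental STFT-domain
variant (solve per time-frequency coefficient on real and imaginary
parts, then overlap-add) sits behind `recovery_domain="tf"`; the
time-domain solver is the reference formulation.

A property worth knowing: the l1-minimal solution coincides with the
generating sparse solution only when no column is l1-expressible more
cheaply through others. Columns of unequal norm break this — for the
packaged reference matrix, the third (norm 0.83) column costs 0.90 via
the other two, so recovery against the *raw* matrix misattributes that
source. The estimator always emits unit columns, which restores the
property for well-separated directions; supplying an external matrix for
separation is best done with unit columns and the norms folded into the
sources.

## Evaluation

Recovered sources are aligned to the truth by the permutation maximising
total similarity (exhaustive, N ≤ 8), then optionally gain-matched per
source by least squares before the energy metrics — blind separation
determines sources only up to order and scale, so the defaults report
waveform fidelity, not the unrecoverable gains. ξ uses the absolute
inner product (polarity-blind) and is clamped to [0, 1]. NMSE is
primarily the raw pooled energy ratio Σ(s−ŝ)²/Σs² — the scale on which
such results are conventionally tabulated — with the 10·log₁₀ form
reported alongside. ARSNR averages per-source dB terms; perfect pairs
(zero error) are excluded with a warning, +∞ if all are perfect.

## Synthetic source generator

Each source is a train of Hann-enveloped harmonic bursts: per burst a
fundamental drawn from 300–2000 Hz, 4 harmonics at 1/k amplitude (capped
below 0.45·fs), random phase and amplitude, burst lengths 0.05–0.3 s.
Per-source duty cycles are drawn from (0.2, 0.4); under the default
`disjoint` overlap policy all bursts are laid on one timeline with
random exponential gaps, so at most one source is active at any sample
(total duty is rescaled to 0.9 if the draw exceeds it); under `free`
each source is placed independently and co-occurrence is occasional.
Sources are peak-normalised to 0.9 and carry a −60 dB white noise floor.
Everything is determined by one integer seed.

This emulates what matters to the method — harmonic structure,
time-sparsity, mostly disjoint TF supports (a ground-truth audit shows
well over 60% of above-threshold TF points single-source-dominated) —
and deliberately not what doesn't: no reverberation, no inter-burst
amplitude dynamics, no ambient noise, no species-specific call
morphology. Passing tests on this generator demonstrate the algorithm's
correctness under its stated sparsity premise, not field performance on
barn recordings.

## Problem sizes used by the test and acceptance runs

The acceptance script and the acceptance tests run the full worked
configuration: 3 sources / 2 mixtures, 12 s at 44.1 kHz, ten seeded
replicates (~4 s per replicate on one CPU). Unit tests reuse a 6 s,
16 kHz scenario with identical STFT settings — the screen geometry is
rate-independent — plus purpose-built micro-fixtures. The duration-trend
experiment uses {5, 9, 12} s at the full rate.

On this clean synthetic emulation the separation quality saturates
(ξ ≈ 0.99995 at every duration): the mixing-matrix error does fall with
duration (0.0071° → 0.0046° from 5 s to 12 s, roughly as 1/√T), but its
contribution to 1−ξ (~10⁻⁹) is three orders of magnitude below a
duration-independent floor set by the −60 dB source noise (only M of
the N per-source noise streams are representable at any sample, leaving
~10⁻⁵ relative energy unexplained). A monotone duration trend in ξ is
therefore not resolvable here; it belongs to noisy real recordings,
where single-source points are scarce and duration genuinely buys
information.

## Kalman preprocessing

Field recordings can be smoothed by a scalar random-walk Kalman filter
before the pipeline (CLI flag `--denoise`; never applied to synthetic
data). The observation-noise variance r is estimated from the first
100 ms (assumed noise-only); the state innovation q defaults to 0.1·r,
placing the filter's effective passband above typical vocalization
fundamentals at audio rates while attenuating broadband noise — a fixed
tiny q would act as a sub-200 Hz low-pass at 44.1 kHz and destroy the
calls themselves. Both variances are exposed.

## Known limitations

- The median AP preference needs a few hundred reasonably balanced
  single-source points; with < ~150 points or one direction holding the
  majority, the median lands on the within-cluster scale and AP
  over-segments. Short or degenerate inputs should be checked via the
  reported SSP count and silhouette.
- Estimated source count N̂ is trusted downstream; recovery refuses
  implausible column counts (C(N, M) > 1000) instead of guessing.
- Recovery ordering follows Â's (arbitrary) column order; no
  permutation correction is attempted outside evaluation.
- Instantaneous mixing only: reverberant/convolutive scenes and moving
  sources are out of scope, as is resampling (mixed-rate inputs are an
  error by design).
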