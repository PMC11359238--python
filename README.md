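# ubss — underdetermined blind source separation of sparse acoustic mixtures

Recordings made in group housing — a pig barn, an aviary, any pen with
more animals than microphones — superimpose several vocalizations onto
each channel. With M microphones and N > M callers the mixing system
X(t) = A·S(t) cannot be inverted, yet the individual calls are what a
welfare-monitoring pipeline needs. `ubss` implements the two-step sparse
component analysis (SCA) solution for the instantaneous, noiseless mixing
model:

1. **Mixing-matrix estimation.** After an STFT, time-frequency points fed
   by a single source satisfy x(t, f) = a_i · s_i(t, f): the cross-channel
   coefficient vector is parallel to column a_i of the mixing matrix, and
   Im(x_m)/Re(x_m) is the same in every channel m. The package screens for
   these *single-source points* with an energy mask (‖X(t,f)‖² ≥ e), a
   cross-channel ratio test (|Im x_i/Re x_i − Im x_j/Re x_j| < ε₁), and a
   neighbourhood-variance test over G adjacent points in one frequency bin
   (var < ε₂). The surviving directions are clustered with
   **affinity propagation under an adaptive damping factor** — λ starts at
   0.5 and is raised by 0.01 whenever a sliding window of cluster-count
   records shows oscillation, capped below 1 — which yields the number of
   sources N̂ (the exemplar count) without it being supplied. K-means
   (Lloyd) refinement over all retained points polishes the cluster
   centres; the unit-normalised centres are the columns of Â.
2. **Source recovery.** For each sample t, the l1-minimal exact-fit
   solution of Â·s = x has at most M nonzeros and is attained on one of
   the C(N, M) square column subsets B_k of Â: every candidate
   ŝ⁽ᵏ⁾ = B_k⁻¹x (zeros elsewhere) is scored by J_k = Σ|ŝ_i| and the
   minimiser wins.

Separation quality is reported with the similarity coefficient
ξ = |⟨ŝ, s⟩| / (‖ŝ‖‖s‖), the average recovery SNR
(mean of 10·log₁₀(E s² / E(s−ŝ)²), dB) and the normalised MSE
(Σ(s−ŝ)² / Σs²), after aligning the permutation and per-source gain that
blind separation inherently leaves free.

Because no public recordings accompany the problem, the package ships a
synthetic generator of vocalization-like sources — trains of Hann-
enveloped harmonic bursts with controllable duty cycle, fundamental range
and overlap policy — which reproduces the time-frequency sparsity the
method assumes and makes every stage testable end to end.

## Worked example

Three synthetic sources, 12 s at 44.1 kHz, mixed down to two channels by
the fixed reference attenuation matrix; the pipeline then estimates the
matrix from the mixtures alone and separates:

```python
import numpy as np
from ubss import (BurstSourceSpec, RunConfig, estimate_mixing_matrix,
                  evaluate_separation, generate_sources, matrix_error, mix,
                  recover_sources, reference_matrix_3x2)

cfg = RunConfig(seed=1)
a_true = reference_matrix_3x2()                     # 2 x 3, the scenario is underdetermined
spec = BurstSourceSpec(n_sources=3, duration_s=12.0, sample_rate=44100, seed=1)
sources = generate_sources(spec)
mixtures = mix(sources, a_true)                     # X = A S

a_est, clusters, diag = estimate_mixing_matrix(mixtures, cfg)
recovered = recover_sources(mixtures, a_est)
report = evaluate_separation(sources, recovered)
```

which prints (via the obvious `print` statements):

```
single-source points: 11364
estimated sources:    3
final damping:        0.85
silhouette:           0.994
matrix error:         0.0035 deg
A_est =
[[0.9552 0.3448 0.7453]
 [0.2961 0.9387 0.6667]]
A_true (unit columns) =
[[0.9552 0.3447 0.7454]
 [0.296  0.9387 0.6667]]
mean similarity xi:   0.9999
ARSNR:                41.5 dB
NMSE ratio:           0.00009
```

Reading this: 11 364 time-frequency points survived the single-source
screens; adaptive-damping affinity propagation found exactly 3 clusters
(the true source count) with the damping factor settling at 0.85; the
estimated columns agree with the true directions to 0.0035°. The
recovered waveforms match the originals nearly perfectly — similarity
0.9999, reconstruction SNR 41.5 dB, error-to-signal energy ratio 9·10⁻⁵ —
because the sources are time-disjoint, so the sparsity premise holds at
every sample. Columns are compared after unit normalisation: blind
separation cannot recover per-source gains, and the third *printed*
column of the reference matrix is deliberately shorter than the others.

The same flow is available from a shell:

```bash
ubss simulate --out run/ --duration 12 --seed 1        # sources, mixtures, A.csv
ubss estimate-matrix run/mixture_1.wav run/mixture_2.wav --out run/est --seed 1
ubss separate run/mixture_1.wav run/mixture_2.wav --matrix run/est/A_est.csv --out run/sep
ubss evaluate --true run/source_1.wav --true run/source_2.wav --true run/source_3.wav \
              --recovered run/sep/recovered_1.wav --recovered run/sep/recovered_2.wav \
              --recovered run/sep/recovered_3.wav
ubss sweep --durations 5,9,12 --replicates 10 --out grid.csv
```

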