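"""Source reconstruction by per-sample minimal-l1-norm subset selection.

With the mixing matrix A (M x N, M < N) known or estimated, each sample of
the mixtures x(t) = A s(t) is an underdetermined linear system.  Under the
sparsity assumption, the l1-minimal exact-fit solution has at most M
nonzeros, and it is attained on one of the C(N, M) square column subsets
of A: invert each invertible submatrix B_k, score the candidate by its l1
norm J_k, and keep the minimiser (ties to the lowest subset index).
Recovery runs sample-by-sample in the time domain; the submatrix inverses
are factorised once and reused across all T samples.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .audio import MixtureSet, SourceSet

logger = logging.getLogger("ubss")

__all__ = ["enumerate_submatrices", "solve_l1_sample", "recover_sources",
           "recover_sources_tf"]

COND_LIMIT = 1e8  # submatrices worse-conditioned than this are skipped


def enumerate_submatrices(a):
    """All C(N, M) M x M column submatrices of A, in lexicographic order
    of their column index sets."""
    amat = np.asarray(a, dtype=np.float64)
    m, n = amat.shape
    if m > n:
        raise ValueError(f"M={m} > N={n}: no square column subsets exist")
    return [(idx, amat[:, idx]) for idx in combinations(range(n), m)]


def _prepare(a):
    """Precompute inverses of the well-conditioned submatrices."""
    amat = np.asarray(a, dtype=np.float64)
    subs = enumerate_submatrices(amat)
    prepared = []
    for idx, b in subs:
        if np.linalg.cond(b) < COND_LIMIT:
            prepared.append((idx, np.linalg.inv(b)))
        else:
            prepared.append((idx, None))
    return amat, prepared


def _solve_batch(amat: np.ndarray, prepared, x: np.ndarray):
    """Vectorised subset enumeration over a batch of samples.

    x has shape (M, T); returns (s_hat (N, T), k_min (T,), n_singular_hits).
    """
    m, n = amat.shape
    t = x.shape[1]
    n_sub = len(prepared)
    j = np.full((n_sub, t), np.inf)
    sols = []
    for k, (idx, binv) in enumerate(prepared):
        if binv is None:
            sols.append(None)
            continue
        # broadcast multiply-sum rather than BLAS matmul: the rounding
        # order is then independent of T, so batched recovery is
        # bit-identical to the sample-at-a-time loop
        s_sub = (binv[:, :, None] * x[None, :, :]).sum(axis=1)  # (M, T)
        sols.append(s_sub)
        j[k] = np.sum(np.abs(s_sub), axis=0)

    k_min = np.argmin(j, axis=0)  # first minimum = lowest subset index
    s_hat = np.zeros((n, t))
    all_singular = ~np.isfinite(j.min(axis=0))
    for k, (idx, _) in enumerate(prepared):
        if sols[k] is None:
            continue
        cols = (k_min == k) & ~all_singular
        if cols.any():
            s_hat[np.ix_(list(idx), np.flatnonzero(cols))] = sols[k][:, cols]
    return s_hat, k_min, int(all_singular.sum())


def solve_l1_sample(x_t, a):
    """Minimal-l1 exact-fit solution for one observation vector.

    Returns ``(s_hat, k_min)`` where ``k_min`` indexes the chosen column
    subset in lexicographic order.  If every submatrix is singular, the
    zero vector is returned with a warning.
    """
    amat, prepared = _prepare(a)
    x = np.asarray(x_t, dtype=np.float64).reshape(amat.shape[0], 1)
    s_hat, k_min, n_bad = _solve_batch(amat, prepared, x)
    if n_bad:
        logger.warning("all submatrices singular for this sample; emitted zeros")
    return s_hat[:, 0], int(k_min[0])


def recover_sources(x: MixtureSet, a, audit: bool = False):
    """Reconstruct N sources from M mixtures given the mixing matrix.

    Applies the minimal-l1 subset solver independently at every sample.
    Output ordering follows the column order of the supplied matrix; no
    permutation correction is attempted.  With ``audit`` the chosen subset
    index per sample is returned alongside the sources.
    """
    amat = np.asarray(a, dtype=np.float64)
    if amat.shape[0] != x.n_signals:
        raise ValueError(
            f"matrix has {amat.shape[0]} rows but mixtures have {x.n_signals} channels"
        )
    if np.linalg.matrix_rank(amat) < amat.shape[0]:
        raise ValueError("mixing matrix must have full row rank")
    from math import comb

    n_sub = comb(amat.shape[1], amat.shape[0])
    if n_sub > 1000:
        raise ValueError(
            f"C({amat.shape[1]}, {amat.shape[0]}) = {n_sub} column subsets: "
            "the matrix has implausibly many columns for subset enumeration "
            "(was it estimated from a failed clustering run?)"
        )

    amat, prepared = _prepare(amat)
    s_hat, k_min, n_bad = _solve_batch(amat, prepared, x.data)
    if n_bad:
        logger.warning("recover_sources: %d samples had no invertible "
                       "submatrix and were zeroed", n_bad)
    labels = [f"recovered_{i + 1}" for i in range(amat.shape[1])]
    sources = SourceSet.from_array(s_hat, x.sample_rate, labels)
    if audit:
        return sources, k_min
    return sources


def recover_sources_tf(x: MixtureSet, a, window_len: int = 512,
                       hop: int = 256, window: str = "hann") -> SourceSet:
    """Experimental STFT-domain variant of minimal-l1 recovery.

    The subset solver is applied independently to the real and imaginary
    parts of every time-frequency coefficient vector, and the recovered
    source spectra are inverted by overlap-add.  Because the mixing is
    instantaneous and real, linearity carries the exact-fit property over
    to each part separately.  This is an extension for experimentation;
    the time-domain solver is the reference formulation.
    """
    from .tf import istft_inverse, stft_forward, TFGrid

    amat = np.asarray(a, dtype=np.float64)
    grid = stft_forward(x, window_len, hop, window)
    m, n = amat.shape
    coeffs = grid.coefficients.reshape(m, -1)  # (M, bins*frames)
    amat, prepared = _prepare(amat)
    re_hat, _, _ = _solve_batch(amat, prepared, coeffs.real)
    im_hat, _, _ = _solve_batch(amat, prepared, coeffs.imag)
    s_spec = (re_hat + 1j * im_hat).reshape(n, grid.n_bins, grid.n_frames)
    out_grid = TFGrid(s_spec, grid.window, grid.window_len, grid.hop,
                      grid.sample_rate, grid.n_samples)
    rec = istft_inverse(out_grid, x.n_samples)
    return SourceSet.from_array(rec.data, x.sample_rate,
                                [f"recovered_{i + 1}" for i in range(n)])
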