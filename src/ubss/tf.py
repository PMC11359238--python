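"""Time-frequency analysis and single-source-point (SSP) extraction.

The mixtures are taken to the STFT domain, where the instantaneous model
becomes X(t, f) = A S(t, f).  At a point where only source i is active,
the cross-channel coefficient vector is parallel to column i of A and the
imaginary/real ratio is the same in every channel.  SSP extraction is a
three-stage sieve:

1. energy mask — zero every point whose cross-channel squared norm is
   below ``e`` (removes the cloud of low-energy points near the origin);
2. ratio screen — keep points where all channel pairs agree on the
   Im/Re ratio to within ``eps1``;
3. neighbourhood-variance screen — group surviving points into runs of
   ``G`` consecutive candidates within one frequency bin and keep a run
   only if the per-channel variance of its (direction-normalised)
   features is below ``eps2``.

The retained features — the real parts of the coefficients — populate an
:class:`SSPSet`, the input of mixing-matrix estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT, check_COLA
from scipy.signal.windows import get_window

from .audio import MixtureSet

__all__ = [
    "TFGrid",
    "SSPSet",
    "stft_forward",
    "istft_inverse",
    "mask_low_energy",
    "ssp_ratio_screen",
    "ssp_variance_screen",
    "extract_ssp",
]

REAL_PART_GUARD = 1e-6  # |Re| below this risks ratio blow-up; point dropped


def _make_stft(window_len: int, hop: int, fs: float,
               window: str = "hann") -> ShortTimeFFT:
    win = get_window(window, window_len, fftbins=True)
    if not check_COLA(win, window_len, window_len - hop):
        raise ValueError(
            f"window '{window}' length {window_len} with hop {hop} is not "
            "COLA-compliant; inversion would not be exact"
        )
    return ShortTimeFFT(win, hop=hop, fs=fs, fft_mode="onesided")


@dataclass
class TFGrid:
    """Per-channel complex STFT coefficients on a shared (bin, frame) grid.

    ``coefficients`` has shape (channels, bins, frames); the one-sided
    spectrum carries bins 0 .. window_len/2.
    """

    coefficients: np.ndarray
    window: str
    window_len: int
    hop: int
    sample_rate: float
    n_samples: int

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_bins(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[2]


@dataclass
class SSPSet:
    """Retained single-source time-frequency points.

    ``features`` is an (L, M) array of the real parts of the cross-channel
    coefficients; ``frames``/``bins`` give each point's grid position.
    ``thresholds`` echoes the screen settings that produced the set.
    """

    frames: np.ndarray
    bins: np.ndarray
    features: np.ndarray
    thresholds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.features.shape[0]

    def to_frame(self):
        """Flat pandas view (frame, bin, feature_1..feature_M) for CSV dumps."""
        import pandas as pd

        cols = {f"feature_{i + 1}": self.features[:, i]
                for i in range(self.features.shape[1])}
        return pd.DataFrame({"frame": self.frames, "bin": self.bins, **cols})


def stft_forward(x: MixtureSet, window_len: int = 512, hop: int = 256,
                 window: str = "hann") -> TFGrid:
    """Forward STFT of every mixture channel onto one shared grid."""
    if not (window_len > hop > 0):
        raise ValueError("require window_len > hop > 0")
    if x.n_samples < window_len:
        raise ValueError(
            f"signal of {x.n_samples} samples is shorter than the window ({window_len})"
        )
    sft = _make_stft(window_len, hop, x.sample_rate, window)
    coeffs = np.stack([sft.stft(s.samples) for s in x])
    return TFGrid(coeffs, window, window_len, hop, x.sample_rate, x.n_samples)


def istft_inverse(grid: TFGrid, length: int | None = None) -> MixtureSet:
    """Overlap-add inversion of a TFGrid back to waveforms.

    The result is truncated/padded to ``length`` (defaults to the number of
    samples the grid was built from).
    """
    length = grid.n_samples if length is None else int(length)
    sft = _make_stft(grid.window_len, grid.hop, grid.sample_rate, grid.window)
    rows = []
    for c in range(grid.n_channels):
        y = sft.istft(grid.coefficients[c], k1=length)
        if y.size < length:
            y = np.pad(y, (0, length - y.size))
        rows.append(y[:length])
    return MixtureSet.from_array(np.vstack(rows), int(grid.sample_rate))


def mask_low_energy(grid: TFGrid, e: float = 0.05) -> TFGrid:
    """Zero every TF point whose cross-channel squared norm is below ``e``.

    The norm is taken on the stacked observation vector X(t0, f0) — all
    channels are zeroed together, keeping the grid synchronised.  The
    boundary case ``norm**2 == e`` is kept.
    """
    if e < 0:
        raise ValueError("energy threshold e must be >= 0")
    power = np.sum(np.abs(grid.coefficients) ** 2, axis=0)
    keep = power >= e
    out = np.where(keep[None, :, :], grid.coefficients, 0.0)
    return TFGrid(out, grid.window, grid.window_len, grid.hop,
                  grid.sample_rate, grid.n_samples)


def ssp_ratio_screen(grid: TFGrid, eps1: float = 0.01):
    """Preliminary SSP screen by cross-channel Im/Re ratio agreement.

    A nonzero point survives when, for every channel pair (i, j),
    |Im(x_i)/Re(x_i) - Im(x_j)/Re(x_j)| < eps1.  Points where any channel
    has |Re| < 1e-6 are discarded outright (noise and rounding make the
    ratio meaningless there).  Returns (frames, bins, features) arrays of
    the candidates, features being the real parts.
    """
    if not (0 < eps1 < 1):
        raise ValueError("eps1 must lie in (0, 1)")
    if grid.n_channels < 2:
        raise ValueError("ratio screen needs at least 2 channels")
    c = grid.coefficients  # (M, B, F)
    re, im = c.real, c.imag
    nonzero = np.any(np.abs(c) > 0, axis=0)
    safe = np.all(np.abs(re) >= REAL_PART_GUARD, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(re) >= REAL_PART_GUARD, im / re, 0.0)
    spread = ratio.max(axis=0) - ratio.min(axis=0)  # max pairwise |diff|
    keep = nonzero & safe & (spread < eps1)
    b_idx, f_idx = np.nonzero(keep)
    features = re[:, b_idx, f_idx].T  # (L, M)
    return f_idx, b_idx, features


def _canonical(features: np.ndarray) -> np.ndarray:
    """Unit-normalise rows and flip sign so the first non-negligible
    component is >= 0 (SSPs live on lines through the origin, so a
    direction and its negation are the same point)."""
    norms = np.linalg.norm(features, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = features / norms
    nz = np.abs(u) > 1e-12
    first = np.argmax(nz, axis=1)
    lead = u[np.arange(u.shape[0]), first]
    flip = np.where(lead < 0, -1.0, 1.0)
    flip[~nz.any(axis=1)] = 1.0
    return u * flip[:, None]


def ssp_variance_screen(frames, bins, features, G: int = 6,
                        eps2: float = 0.05, *,
                        normalize: bool = True,
                        thresholds: dict | None = None) -> SSPSet:
    """Neighbourhood-variance confirmation of SSP candidates.

    Candidates are ordered by (bin, frame) and cut into runs of ``G``
    consecutive points within the same frequency bin ("constant frequency,
    adjacent time"); a trailing partial run is dropped.  A run is kept iff
    for every channel the sample variance (1/(G-1) normalisation) of its
    feature values is below ``eps2``.  With ``normalize`` (default) the
    variance is computed on unit-norm, sign-canonicalised directions, so
    the screen measures directional stability independently of amplitude.
    """
    if G < 2:
        raise ValueError("subgroup size G must be >= 2")
    if not (0.01 < eps2 < 0.5):
        warnings.warn(f"eps2={eps2} is outside the recommended (0.01, 0.5) range")
    frames = np.asarray(frames)
    bins = np.asarray(bins)
    features = np.asarray(features, dtype=np.float64)
    thr = dict(thresholds or {})
    thr.update({"G": G, "eps2": eps2})

    if len(frames) < G:
        warnings.warn("fewer candidates than one subgroup; empty SSP set")
        return SSPSet(np.empty(0, int), np.empty(0, int),
                      np.empty((0, features.shape[1] if features.ndim == 2 else 0)),
                      thr)

    order = np.lexsort((frames, bins))
    frames, bins, features = frames[order], bins[order], features[order]
    screened = _canonical(features) if normalize else features

    keep = np.zeros(len(frames), dtype=bool)
    start = 0
    while start < len(frames):
        stop = start
        while stop < len(frames) and bins[stop] == bins[start]:
            stop += 1
        # runs of G within this bin; drop the partial tail
        for g0 in range(start, stop - G + 1, G):
            block = screened[g0:g0 + G]
            if np.all(np.var(block, axis=0, ddof=1) < eps2):
                keep[g0:g0 + G] = True
        start = stop

    return SSPSet(frames[keep], bins[keep], features[keep], thr)


def extract_ssp(x: MixtureSet, window_len: int = 512, hop: int = 256,
                window: str = "hann", e: float = 0.05, eps1: float = 0.01,
                eps2: float = 0.05, G: int = 6) -> SSPSet:
    """Full SSP chain: STFT -> energy mask -> ratio screen -> variance screen."""
    grid = stft_forward(x, window_len, hop, window)
    masked = mask_low_energy(grid, e)
    frames, bins, features = ssp_ratio_screen(masked, eps1)
    return ssp_variance_screen(frames, bins, features, G, eps2,
                               thresholds={"e": e, "eps1": eps1})
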