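"""Synthetic sparse vocalization-like sources and mixing matrices.

Real group-housed animal recordings are short harmonic calls (grunts,
squeals, growls) separated by silence: time-sparse, harmonically
structured bursts whose time-frequency supports rarely coincide.  That
sparsity is exactly what sparse-component-analysis separation assumes, so
the generator emulates it directly: each source is a train of Hann-
enveloped harmonic bursts with a per-burst fundamental, 1/k harmonic
rolloff, and a controllable duty cycle, over a low broadband noise floor.

Mixing is the noiseless linear instantaneous model X(t) = A S(t); each
column of A is the attenuation direction of one source as seen by the M
receivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .audio import MixtureSet, SourceSet

__all__ = [
    "MixingMatrix",
    "BurstSourceSpec",
    "reference_matrix_3x2",
    "make_matrix_angular",
    "make_matrix_random",
    "generate_sources",
    "mix",
    "sparsity_audit",
]


@dataclass
class MixingMatrix:
    """An M x N real attenuation matrix; columns are source directions.

    Validity: at least 2 rows, no all-zero column, and no two columns
    closer than ``min_separation_deg`` as lines through the origin
    (collinear columns make the scatter-plot geometry unidentifiable).
    """

    entries: np.ndarray
    method: str = "fixed"
    params: dict = field(default_factory=dict)
    min_separation_deg: float = 5.0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        if self.entries.ndim != 2:
            raise ValueError("mixing matrix must be 2-D")
        m, n = self.entries.shape
        if m < 2:
            raise ValueError("need at least 2 observation channels (rows)")
        norms = np.linalg.norm(self.entries, axis=0)
        if np.any(norms == 0):
            raise ValueError("mixing matrix has an all-zero column")
        u = self.entries / norms
        for i, j in combinations(range(n), 2):
            cosang = abs(float(u[:, i] @ u[:, j]))
            ang = np.degrees(np.arccos(min(1.0, cosang)))
            if ang < self.min_separation_deg - 1e-9:
                raise ValueError(
                    f"columns {i} and {j} are only {ang:.3f} deg apart "
                    f"(< {self.min_separation_deg} deg): directions not separable"
                )

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    @property
    def shape(self):
        return self.entries.shape

    def normalized(self) -> np.ndarray:
        """Columns scaled to unit norm with the first nonzero component >= 0."""
        from .estimation import canonicalize_directions

        return canonicalize_directions(self.entries.T).T

    def __array__(self, dtype=None, copy=None):
        arr = np.asarray(self.entries, dtype=dtype)
        if copy:
            arr = arr.copy()
        return arr


def reference_matrix_3x2() -> MixingMatrix:
    """The fixed 2x3 amplitude-attenuation matrix of the worked
    three-source / two-microphone example.

    Its columns are deliberately not unit-norm; estimation and evaluation
    normalise columns before any comparison.
    """
    a = np.array([[0.9552, 0.3663, 0.6205],
                  [0.2960, 0.9974, 0.5550]])
    return MixingMatrix(a, method="fixed", params={"name": "reference_3x2"})


def make_matrix_angular(t_deg: float, n_sources: int,
                        min_separation_deg: float = 5.0) -> MixingMatrix:
    """2 x N matrix with unit columns at angles k*T degrees, k = 1..N.

    Column k is (cos kT, sin kT).  All column directions must be distinct
    modulo 180 degrees (as lines through the origin), otherwise two
    sources share a scatter direction and the construction is rejected.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    angles = np.deg2rad(t_deg) * np.arange(1, n_sources + 1)
    cols = np.vstack([np.cos(angles), np.sin(angles)])
    line_deg = (t_deg * np.arange(1, n_sources + 1)) % 180.0
    for i, j in combinations(range(n_sources), 2):
        d = abs(line_deg[i] - line_deg[j])
        d = min(d, 180.0 - d)
        if d < min_separation_deg - 1e-9:
            raise ValueError(
                f"angular matrix T={t_deg}: columns {i + 1} and {j + 1} "
                f"are collinear modulo 180 deg (separation {d:.3f} deg)"
            )
    return MixingMatrix(cols, method="angular",
                        params={"T_deg": t_deg, "n_sources": n_sources},
                        min_separation_deg=min_separation_deg)


def make_matrix_random(m: int, n: int, seed: int,
                       min_separation_deg: float = 5.0,
                       max_tries: int = 1000) -> MixingMatrix:
    """Random unit-column M x N matrix with pairwise angular separation
    at least ``min_separation_deg`` (rejection sampling, seeded)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        a = rng.standard_normal((m, n))
        a /= np.linalg.norm(a, axis=0)
        # canonical half-space so separations are measured between lines
        a *= np.where(a[0] < 0, -1.0, 1.0)
        try:
            return MixingMatrix(a.copy(), method="random",
                                params={"seed": seed},
                                min_separation_deg=min_separation_deg)
        except ValueError:
            continue
    raise RuntimeError("could not draw a well-separated random mixing matrix")


@dataclass
class BurstSourceSpec:
    """Parameters of the burst-train source model.

    duty_cycle is a (lo, hi) range; each source draws its own target
    active fraction from it.  With ``overlap_policy='disjoint'`` bursts of
    different sources never co-occur in time (at most one source above a
    -40 dB envelope at any sample); with ``'free'`` each source is placed
    independently and occasional co-occurrence is allowed.
    """

    n_sources: int = 3
    duration_s: float = 12.0
    sample_rate: int = 44100
    fundamental_range: tuple = (300.0, 2000.0)
    n_harmonics: int = 4
    burst_len_range: tuple = (0.05, 0.3)
    duty_cycle: tuple = (0.2, 0.4)
    overlap_policy: str = "disjoint"
    noise_floor_db: float = -60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.duration_s < 1:
            raise ValueError("duration_s must be >= 1 s")
        lo, hi = self.duty_cycle
        if not (0 < lo <= hi < 1):
            raise ValueError("duty_cycle range must lie in (0, 1)")
        blo, bhi = self.burst_len_range
        if not (0 < blo <= bhi):
            raise ValueError("invalid burst_len_range")
        if bhi > self.duration_s:
            raise ValueError("bursts longer than the signal are infeasible")
        if self.overlap_policy not in ("disjoint", "free"):
            raise ValueError("overlap_policy must be 'disjoint' or 'free'")
        if self.overlap_policy == "disjoint":
            mean_duty = 0.5 * (lo + hi)
            if mean_duty * self.n_sources > 0.95:
                raise ValueError(
                    "disjoint placement infeasible: expected total duty "
                    f"{mean_duty * self.n_sources:.2f} > 0.95"
                )


def _burst(n: int, f0: float, n_harm: int, fs: int, rng) -> np.ndarray:
    """One Hann-enveloped harmonic burst of n samples."""
    t = np.arange(n) / fs
    y = np.zeros(n)
    for k in range(1, n_harm + 1):
        fk = k * f0
        if fk >= 0.45 * fs:
            break
        y += (1.0 / k) * np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
    env = np.hanning(n) if n > 1 else np.ones(1)
    return y * env


def generate_sources(spec: BurstSourceSpec) -> SourceSet:
    """Generate N sparse harmonic-burst sources; fully seed-determined.

    Each source's active fraction (envelope above -40 dB of its peak)
    lands within +-0.05 of its drawn duty-cycle target.  Peak amplitude of
    every source is normalised to 0.9, and white noise at
    ``noise_floor_db`` relative to that peak is added throughout.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n_samp = int(round(spec.duration_s * fs))
    lo, hi = spec.duty_cycle

    duties = rng.uniform(lo, hi, size=spec.n_sources)
    if spec.overlap_policy == "disjoint" and duties.sum() > 0.9:
        duties *= 0.9 / duties.sum()

    # Draw each source's burst lengths until its active-sample budget is met.
    bursts = []  # (source, length in samples)
    for i in range(spec.n_sources):
        budget = int(duties[i] * n_samp)
        got = 0
        while got < budget:
            ln = int(rng.uniform(*spec.burst_len_range) * fs)
            ln = min(ln, budget - got) if budget - got < ln else ln
            ln = max(ln, 8)
            bursts.append((i, ln))
            got += ln

    out = np.zeros((spec.n_sources, n_samp))

    def place(seq, total_len):
        """Lay bursts of `seq` left to right with random gaps filling the slack."""
        used = sum(ln for _, ln in seq)
        slack = total_len - used
        if slack < 0:
            raise ValueError("infeasible duty/burst combination: bursts overflow signal")
        w = rng.exponential(size=len(seq) + 1)
        gaps = np.floor(slack * w / w.sum()).astype(int)
        pos = 0
        for (src, ln), g in zip(seq, gaps):
            pos += g
            f0 = rng.uniform(*spec.fundamental_range)
            amp = rng.uniform(0.5, 1.0)
            out[src, pos:pos + ln] += amp * _burst(ln, f0, spec.n_harmonics, fs, rng)
            pos += ln

    if spec.overlap_policy == "disjoint":
        order = rng.permutation(len(bursts))
        place([bursts[k] for k in order], n_samp)
    else:
        for i in range(spec.n_sources):
            place([b for b in bursts if b[0] == i], n_samp)

    # Per-source peak normalisation + broadband noise floor.
    for i in range(spec.n_sources):
        peak = np.max(np.abs(out[i]))
        if peak > 0:
            out[i] *= 0.9 / peak
        out[i] += (0.9 * 10 ** (spec.noise_floor_db / 20.0)
                   * rng.standard_normal(n_samp))

    labels = [f"source_{i + 1}" for i in range(spec.n_sources)]
    if spec.n_sources == 1:
        s = SourceSet.__new__(SourceSet)
        from .audio import AudioSignal

        s.signals = [AudioSignal(out[0], fs, labels[0])]
        return s
    return SourceSet.from_array(out, fs, labels)


def mix(sources: SourceSet, a) -> MixtureSet:
    """Noiseless instantaneous mixing X = A S.

    Each observation is x_m(t) = sum_n a_mn s_n(t); no additive noise term
    is applied (robustness noise, if wanted, is added to the mixtures by
    the caller).
    """
    amat = np.asarray(a, dtype=np.float64)
    if amat.shape[1] != sources.n_signals:
        raise ValueError(
            f"mixing matrix has {amat.shape[1]} columns but {sources.n_signals} sources"
        )
    x = amat @ sources.data
    labels = [f"mixture_{i + 1}" for i in range(amat.shape[0])]
    return MixtureSet.from_array(x, sources.sample_rate, labels,
                                 provenance=a if isinstance(a, MixingMatrix) else None)


def activity_fraction(x: np.ndarray, rel_db: float = -40.0,
                      win: int = 256) -> float:
    """Fraction of samples whose smoothed envelope exceeds ``rel_db``
    relative to the signal peak envelope."""
    env = np.sqrt(np.convolve(x ** 2, np.ones(win) / win, mode="same"))
    thr = env.max() * 10 ** (rel_db / 20.0)
    return float(np.mean(env > thr))


def sparsity_audit(sources: SourceSet, window_len: int = 512, hop: int = 256,
                   e: float = 0.05, dominance: float = 10.0) -> float:
    """Fraction of above-threshold STFT points dominated by one source.

    Uses the ground-truth per-source STFTs: a point is single-source-
    dominated when the strongest source carries at least ``dominance``
    times the energy of all the others combined.  The generator is meant
    to keep this fraction high (>= 0.6) — that is the sparsity premise of
    the whole separation method.
    """
    from .tf import _make_stft

    sft = _make_stft(window_len, hop, sources.sample_rate)
    specs = np.stack([np.abs(sft.stft(s.samples)) ** 2 for s in sources])
    total = specs.sum(axis=0)
    mask = total >= e
    if not mask.any():
        return 0.0
    top = specs.max(axis=0)
    rest = total - top
    dominated = top[mask] >= dominance * rest[mask]
    return float(np.mean(dominated))
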