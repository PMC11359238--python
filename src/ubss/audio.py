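"""Multi-channel audio I/O and preprocessing.

Waveforms are held as :class:`AudioSignal` records (float64 samples,
nominally in [-1, 1]) and grouped into :class:`SourceSet` /
:class:`MixtureSet` containers whose rows are the ``S(t)`` and ``X(t)``
matrices of the instantaneous mixing model ``X(t) = A S(t)``.

Only 16-bit-style PCM WAV is supported on disk; amplitudes are normalised
to [-1, 1] on read so that downstream energy thresholds are
scale-meaningful across inputs.  Mixed sample rates are an error, never a
silent resample: resampling changes the time-frequency structure that the
single-source-point screens rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger("ubss")

__all__ = [
    "AudioSignal",
    "SourceSet",
    "MixtureSet",
    "read_wav",
    "read_wav_multi",
    "write_wav",
    "write_wav_multi",
    "zero_pad_align",
    "kalman_denoise",
]


@dataclass
class AudioSignal:
    """A single waveform with its sample rate.

    Parameters
    ----------
    samples : ndarray
        1-D float array, amplitude dimensionless, nominally in [-1, 1].
    sample_rate : int
        Sampling frequency in Hz, > 0.
    label : str
        Free-text tag (e.g. "grunt", "mixture 1").
    """

    samples: np.ndarray
    sample_rate: int
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("AudioSignal requires a non-empty 1-D sample vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


class _SignalSet:
    """Common behaviour of SourceSet / MixtureSet: equal-length,
    equal-rate bundles of AudioSignal rows."""

    _min_signals = 2

    def __init__(self, signals):
        signals = list(signals)
        if len(signals) < self._min_signals:
            raise ValueError(
                f"{type(self).__name__} needs at least {self._min_signals} signals"
            )
        rates = {s.sample_rate for s in signals}
        if len(rates) != 1:
            raise ValueError(f"mixed sample rates {sorted(rates)}; resample explicitly")
        lengths = {len(s) for s in signals}
        if len(lengths) != 1:
            raise ValueError("signals must share one length; use zero_pad_align first")
        self.signals = signals

    @property
    def sample_rate(self) -> int:
        return self.signals[0].sample_rate

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    @property
    def n_samples(self) -> int:
        return len(self.signals[0])

    @property
    def data(self) -> np.ndarray:
        """Stacked (n_signals, n_samples) float matrix."""
        return np.vstack([s.samples for s in self.signals])

    @classmethod
    def from_array(cls, arr, sample_rate, labels=None, **kw):
        arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
        labels = labels or [f"{cls.__name__.lower()}_{i + 1}" for i in range(arr.shape[0])]
        sigs = [AudioSignal(row, sample_rate, lab) for row, lab in zip(arr, labels)]
        return cls(sigs, **kw)

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self):
        return iter(self.signals)

    def __getitem__(self, i):
        return self.signals[i]


class SourceSet(_SignalSet):
    """N source waveforms S(t) = [s1(t) ... sN(t)]^T of equal length/rate."""


class MixtureSet(_SignalSet):
    """M observed waveforms X(t); for underdetermined runs M < N.

    ``provenance`` optionally records the mixing matrix that produced the
    mixtures (for synthetic experiments).
    """

    def __init__(self, signals, provenance=None):
        super().__init__(signals)
        self.provenance = provenance


def read_wav(path) -> AudioSignal:
    """Read a mono PCM WAV file, scaling samples to [-1, 1].

    Raises a ``ValueError`` for multi-channel files (use
    :func:`read_wav_multi`) and an ``IOError`` naming the path for
    unreadable files.
    """
    try:
        rate, raw = wavfile.read(path)
    except FileNotFoundError:
        raise IOError(f"cannot read WAV file: {path}") from None
    except ValueError as exc:  # scipy raises ValueError for unsupported encodings
        raise ValueError(f"unsupported WAV encoding in {path}: {exc}") from exc
    if raw.ndim != 1:
        raise ValueError(
            f"{path} has {raw.shape[1]} channels; use read_wav_multi for multi-channel files"
        )
    return AudioSignal(_pcm_to_float(raw), int(rate), label=str(path))


def read_wav_multi(path):
    """Read a WAV file of any channel count as a list of AudioSignal."""
    try:
        rate, raw = wavfile.read(path)
    except FileNotFoundError:
        raise IOError(f"cannot read WAV file: {path}") from None
    data = _pcm_to_float(raw)
    if data.ndim == 1:
        data = data[:, None]
    return [
        AudioSignal(data[:, c], int(rate), label=f"{path}[ch{c}]")
        for c in range(data.shape[1])
    ]


def _pcm_to_float(raw: np.ndarray) -> np.ndarray:
    """Scale integer PCM to float64 in [-1, 1]; pass float data through."""
    if raw.dtype == np.int16:
        # symmetric with write_wav's round(x * 32767); the single code
        # -32768 is clamped so outputs stay inside [-1, 1]
        return np.maximum(raw.astype(np.float64) / 32767.0, -1.0)
    if raw.dtype == np.int32:
        return raw.astype(np.float64) / 2147483648.0
    if raw.dtype == np.uint8:
        return (raw.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(raw.dtype, np.floating):
        return raw.astype(np.float64)
    raise ValueError(f"unsupported WAV sample format {raw.dtype}")


def write_wav(signal: AudioSignal, path) -> None:
    """Write a mono 16-bit PCM WAV file.

    Samples outside [-1, 1] are clipped with a logged warning (clipping
    policy: hard clip, never rescale, so that round-trips of in-range
    material are exact to 16-bit quantisation).
    """
    x = signal.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot write non-finite samples")
    if np.any(np.abs(x) > 1.0):
        logger.warning("write_wav: clipping %d samples outside [-1, 1] in %s",
                       int(np.sum(np.abs(x) > 1.0)), path)
        x = np.clip(x, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, signal.sample_rate, pcm)


def write_wav_multi(signals, path) -> None:
    """Write equal-length signals as one multi-channel 16-bit PCM WAV."""
    sset = _SignalSet(signals)
    x = sset.data.T  # (samples, channels)
    if np.any(np.abs(x) > 1.0):
        logger.warning("write_wav_multi: clipping out-of-range samples in %s", path)
        x = np.clip(x, -1.0, 1.0)
    wavfile.write(path, sset.sample_rate, np.round(x * 32767.0).astype(np.int16))


def zero_pad_align(signals) -> SourceSet:
    """Pad every signal with trailing zeros to the maximum length.

    This is how differing clip durations are aligned before mixing; no
    sample is ever truncated or moved.
    """
    signals = list(signals)
    if not signals:
        raise ValueError("zero_pad_align: empty signal list")
    rates = {s.sample_rate for s in signals}
    if len(rates) != 1:
        raise ValueError(f"zero_pad_align: mixed sample rates {sorted(rates)}")
    target = max(len(s) for s in signals)
    padded = [
        AudioSignal(
            np.pad(s.samples, (0, target - len(s))), s.sample_rate, s.label
        )
        for s in signals
    ]
    if len(padded) == 1:
        # A single aligned signal is returned as a trivial set via private ctor.
        out = SourceSet.__new__(SourceSet)
        out.signals = padded
        return out
    return SourceSet(padded)


def kalman_denoise(signal: AudioSignal, process_var=None, meas_var=None) -> AudioSignal:
    """Scalar (random-walk state) Kalman smoothing of a waveform.

    The state model is x_t = x_{t-1} + w_t, w_t ~ N(0, q); the observation
    is z_t = x_t + v_t, v_t ~ N(0, r).  This is the simplest filter
    consistent with plain "Kalman noise reduction" of a recording.

    Parameters
    ----------
    process_var : float or None
        State innovation variance q.  ``None`` (default) sets
        q = 0.1 * meas_var, which places the filter passband well above
        typical vocalization fundamentals at audio rates while still
        attenuating broadband noise.
    meas_var : float or None
        Observation noise variance r.  ``None`` estimates it from the
        first 100 ms of the recording, assumed noise-only.
    """
    z = signal.samples
    if meas_var is None:
        head = z[: max(2, int(0.1 * signal.sample_rate))]
        meas_var = float(np.var(head))
        if meas_var <= 0:
            meas_var = 1e-10
    if process_var is None:
        process_var = 0.1 * meas_var
    if process_var <= 0 or meas_var <= 0:
        raise ValueError("kalman_denoise: variances must be positive")

    q, r = float(process_var), float(meas_var)
    # Steady-state gain of the scalar random-walk filter (solves the
    # Riccati fixed point); running the recursion to steady state first
    # and then streaming with the fixed gain is numerically identical to
    # the per-sample recursion after the short transient, but we keep the
    # exact per-sample recursion for fidelity at the start of the signal.
    out = np.empty_like(z)
    x = z[0]
    p = r
    out[0] = x
    for t in range(1, z.size):
        p = p + q
        k = p / (p + r)
        x = x + k * (z[t] - x)
        p = (1.0 - k) * p
        out[t] = x
    return AudioSignal(out, signal.sample_rate, signal.label)
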