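"""Run configuration.

One flat record of every tunable the pipeline reads, with the worked-
example defaults: Hann window 512 / hop 256, energy threshold e = 0.05,
ratio tolerance eps1 = 0.01, neighbourhood size G = 6 with variance
threshold eps2 = 0.05, AP capped at 500 iterations with a 50-iteration
stability stop, damping starting at 0.5 with a length-6 adaptation
window.  ``sigma`` is carried as a placeholder for compatibility with
published settings lists but is read by nothing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # STFT
    window_len: int = 512
    hop: int = 256
    window: str = "hann"
    # SSP screens
    energy_threshold: float = 0.05   # e
    eps1: float = 0.01
    eps2: float = 0.05
    group_size: int = 6              # G
    # affinity propagation
    ap_max_iter: int = 500
    ap_stable_iters: int = 50
    lambda_init: float = 0.5
    damping_window: int = 6          # l
    l_max: int = 300                 # AP subsample cap (K-means sees all points)
    # optional Hankel/SVD denoising
    svd_denoise: bool = False
    energy_keep: float = 0.95
    # recovery
    recovery_domain: str = "time"    # 'time' (default) or 'tf' (experimental)
    # evaluation
    scale_align: bool = True
    # reproducibility
    seed: int = 0
    # unused placeholder from published settings lists; documented, not read
    sigma: float = 0.5

    def __post_init__(self):
        if self.window_len <= self.hop or self.hop <= 0:
            raise ValueError("require window_len > hop > 0")
        if not (0.5 <= self.lambda_init <= 1.0):
            raise ValueError("lambda_init must lie in [0.5, 1]")
        if self.recovery_domain not in ("time", "tf"):
            raise ValueError("recovery_domain must be 'time' or 'tf'")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
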