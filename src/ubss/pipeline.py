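"""End-to-end orchestration: simulate -> estimate -> separate -> evaluate.

Every entry point takes a :class:`~ubss.config.RunConfig` and is
deterministic for a fixed config + seed; reports echo the resolved
configuration and the package version so runs are reproducible from their
artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio import MixtureSet, SourceSet, write_wav
from .config import RunConfig
from .estimation import estimate_mixing_matrix, matrix_error
from .metrics import EvalReport, evaluate_separation
from .recovery import recover_sources
from .synth import (BurstSourceSpec, MixingMatrix, generate_sources,
                    make_matrix_angular, make_matrix_random,
                    reference_matrix_3x2, mix)

logger = logging.getLogger("ubss")

__all__ = [
    "simulate",
    "estimate",
    "separate",
    "evaluate",
    "run_experiment",
    "sweep",
    "build_matrix",
]


def build_matrix(matrix_spec, n_sources: int, m_channels: int,
                 seed: int = 0) -> MixingMatrix:
    """Resolve a matrix specification into a MixingMatrix.

    Accepts the literal string ``'reference'`` (the fixed 2x3 worked-
    example matrix), ``('angular', T_deg)``, ``'random'``, an array, or an
    existing MixingMatrix.
    """
    if isinstance(matrix_spec, MixingMatrix):
        return matrix_spec
    if isinstance(matrix_spec, str):
        if matrix_spec == "reference":
            a = reference_matrix_3x2()
            if (m_channels, n_sources) != a.shape:
                raise ValueError("reference matrix is 2x3; adjust the scenario")
            return a
        if matrix_spec == "random":
            return make_matrix_random(m_channels, n_sources, seed)
        raise ValueError(f"unknown matrix spec {matrix_spec!r}")
    if isinstance(matrix_spec, tuple) and matrix_spec[0] == "angular":
        if m_channels != 2:
            raise ValueError("angular matrices are 2-row constructions")
        return make_matrix_angular(matrix_spec[1], n_sources)
    return MixingMatrix(np.asarray(matrix_spec, dtype=float))


def simulate(config: RunConfig, outdir, n_sources: int = 3,
             m_channels: int = 2, duration_s: float = 12.0,
             sample_rate: int = 44100, matrix="reference",
             ubss_strict: bool = True, **spec_kw):
    """Generate sources, mix them, and write WAV + CSV + manifest.

    Returns ``(SourceSet, MixtureSet, MixingMatrix)``.  With
    ``ubss_strict`` a scenario with N <= M is refused (it would not be
    underdetermined).
    """
    if ubss_strict and n_sources <= m_channels:
        raise ValueError(
            f"N={n_sources} <= M={m_channels}: not an underdetermined scenario "
            "(pass ubss_strict=False to allow)"
        )
    a = build_matrix(matrix, n_sources, m_channels, config.seed)
    spec = BurstSourceSpec(n_sources=n_sources, duration_s=duration_s,
                           sample_rate=sample_rate, seed=config.seed, **spec_kw)
    sources = generate_sources(spec)
    mixtures = mix(sources, a)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    src_files, mix_files = [], []
    for i, s in enumerate(sources):
        f = outdir / f"source_{i + 1}.wav"
        write_wav(s, f)
        src_files.append(f.name)
    peak = np.max(np.abs(mixtures.data))
    for i, m in enumerate(mixtures):
        f = outdir / f"mixture_{i + 1}.wav"
        # mixtures of peak-normalised sources can exceed 1; rescale jointly
        scaled = m if peak <= 1 else type(m)(m.samples / peak, m.sample_rate, m.label)
        write_wav(scaled, f)
        mix_files.append(f.name)
    np.savetxt(outdir / "A.csv", np.asarray(a), delimiter=",")
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_sources": n_sources,
        "m_channels": m_channels,
        "duration_s": duration_s,
        "sample_rate": sample_rate,
        "matrix_method": a.method,
        "matrix_params": {k: (v if not hasattr(v, "tolist") else v.tolist())
                          for k, v in a.params.items()},
        "sources": src_files,
        "mixtures": mix_files,
        "mixture_peak_rescale": float(max(peak, 1.0)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return sources, mixtures, a


def estimate(mixtures: MixtureSet, config: RunConfig):
    """Estimate the mixing matrix; thin wrapper around
    :func:`ubss.estimation.estimate_mixing_matrix`."""
    return estimate_mixing_matrix(mixtures, config)


def separate(mixtures: MixtureSet, a, config: RunConfig) -> SourceSet:
    """Recover sources from mixtures with a known or estimated matrix.

    ``config.recovery_domain`` selects the reference time-domain solver
    (default) or the experimental STFT-domain variant.
    """
    if config.recovery_domain == "tf":
        from .recovery import recover_sources_tf

        return recover_sources_tf(mixtures, a, config.window_len, config.hop,
                                  config.window)
    return recover_sources(mixtures, a)


def evaluate(s_true: SourceSet, s_hat: SourceSet,
             config: RunConfig) -> EvalReport:
    """Permutation-aligned, optionally gain-matched evaluation report."""
    if s_true.n_samples != s_hat.n_samples:
        raise ValueError("true and recovered sources differ in length")
    rep = evaluate_separation(s_true, s_hat, scale=config.scale_align,
                              config=config.to_dict())
    rep.config["version"] = __version__
    return rep


def run_experiment(config: RunConfig, n_sources: int = 3, m_channels: int = 2,
                   duration_s: float = 12.0, sample_rate: int = 44100,
                   matrix="reference", seed: int | None = None,
                   **spec_kw) -> dict:
    """One full replicate: simulate, estimate A, separate, evaluate.

    Returns a flat dict with the evaluation metrics, the estimated source
    count, the angular matrix error against the true matrix, and the
    estimation diagnostics.
    """
    cfg = config.replace(seed=int(seed)) if seed is not None else config
    a = build_matrix(matrix, n_sources, m_channels, cfg.seed)
    spec = BurstSourceSpec(n_sources=n_sources, duration_s=duration_s,
                           sample_rate=sample_rate, seed=cfg.seed, **spec_kw)
    sources = generate_sources(spec)
    mixtures = mix(sources, a)

    a_est, cluster, diag = estimate_mixing_matrix(mixtures, cfg)
    recovered = separate(mixtures, a_est, cfg)
    report = evaluate(sources, recovered, cfg)
    return {
        "seed": cfg.seed,
        "duration_s": duration_s,
        "n_sources": n_sources,
        "m_channels": m_channels,
        "n_clusters": diag["n_clusters"],
        "n_ssp": diag["n_ssp"],
        "matrix_error_deg": matrix_error(a, a_est),
        "mean_xi": report.mean_xi,
        "arsnr_db": report.arsnr_db,
        "nmse_ratio": report.nmse_ratio,
        "nmse_db": report.nmse_db,
        "lambda_final": diag["lambda_final"],
        "silhouette": diag["silhouette"],
        "report": report,
        "diagnostics": diag,
    }


_ROW_KEYS = ["n_clusters", "n_ssp", "matrix_error_deg", "mean_xi",
             "arsnr_db", "nmse_ratio", "nmse_db", "lambda_final", "silhouette"]


def sweep(config: RunConfig, durations=None, t_values=None, shapes=None,
          replicates: int = 10, base_seed: int = 1, duration_s: float = 9.0,
          sample_rate: int = 44100, out_csv=None, **spec_kw) -> pd.DataFrame:
    """Metric grids over durations, angular-matrix T values, or N x M shapes.

    One row per grid cell with metric means over ``replicates`` seeded
    replicates (seeds ``base_seed .. base_seed + replicates - 1``).
    Per-cell failures are logged and skipped, the sweep continues.
    """
    cells = []
    if durations:
        cells += [("duration", {"duration_s": float(d), "matrix": "reference",
                                "n_sources": 3, "m_channels": 2}, f"{d} s")
                  for d in durations]
    if t_values:
        cells += [("T", {"duration_s": duration_s,
                         "matrix": ("angular", float(t)),
                         "n_sources": 3, "m_channels": 2}, f"T={t}")
                  for t in t_values]
    if shapes:
        cells += [("shape", {"duration_s": duration_s, "matrix": "random",
                             "n_sources": int(n), "m_channels": int(m)},
                   f"{n}x{m}")
                  for n, m in shapes]
    if not cells:
        raise ValueError("sweep needs at least one of durations/t_values/shapes")

    rows = []
    for kind, kw, label in cells:
        results = []
        for r in range(replicates):
            try:
                results.append(run_experiment(
                    config, sample_rate=sample_rate,
                    seed=base_seed + r, **kw, **spec_kw))
            except Exception:  # pragma: no cover - per-cell robustness
                logger.exception("sweep cell %s replicate %d failed", label, r)
        if not results:
            continue
        row = {"grid": kind, "cell": label, "replicates": len(results)}
        for key in _ROW_KEYS:
            row[key] = float(np.mean([res[key] for res in results]))
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
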