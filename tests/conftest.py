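"""Shared fixtures: small synthetic scenarios generated at test time."""

import numpy as np
import pytest

from ubss import (BurstSourceSpec, RunConfig, generate_sources, mix,
                  reference_matrix_3x2)


@pytest.fixture(scope="session")
def small_cfg():
    """Default pipeline settings with a fixed seed."""
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact 3-source / 2-mixture scene: 6 s at 16 kHz, disjoint bursts.

    Shares the geometry of the full-rate worked example (same STFT
    settings, same mixing matrix) at a fraction of the cost; reused by
    every test that needs a realistic mixture.
    """
    a = reference_matrix_3x2()
    spec = BurstSourceSpec(n_sources=3, duration_s=6.0, sample_rate=16000,
                           seed=1)
    sources = generate_sources(spec)
    mixtures = mix(sources, a)
    return {"spec": spec, "sources": sources, "mixtures": mixtures, "a": a}


@pytest.fixture(scope="session")
def small_estimate(small_scenario, small_cfg):
    """Mixing-matrix estimate for the small scenario (computed once)."""
    from ubss import estimate_mixing_matrix

    a_est, cluster, diag = estimate_mixing_matrix(
        small_scenario["mixtures"], small_cfg)
    return {"a_est": a_est, "cluster": cluster, "diag": diag}
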