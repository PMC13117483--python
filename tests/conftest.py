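"""Shared fixtures: phantoms, gratings, and a cached toy training corpus."""

from __future__ import annotations

import numpy as np
import pytest

from mriwave import (
    apply_artifact,
    generate_phantom_volume,
    sample_artifact_params,
    zscore_normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def phantom():
    """One mid-size phantom volume with noise and bias."""
    return generate_phantom_volume(11, (32, 64, 64), n_tissues=3, noise_sd=4.0, bias_amp=0.1)


@pytest.fixture(scope="session")
def phantom_bank():
    """Six phantoms for Monte-Carlo style checks."""
    return [generate_phantom_volume(300 + i, (32, 64, 64), n_tissues=3,
                                    noise_sd=4.0, bias_amp=0.1) for i in range(6)]


def grating(angle_deg: float, size: int = 128, cycles: float = 8.0) -> np.ndarray:
    """Oriented sinusoidal grating varying along ``angle_deg``."""
    y, x = np.mgrid[0:size, 0:size]
    t = np.deg2rad(angle_deg)
    return np.sin(2 * np.pi * cycles * ((x * np.cos(t) + y * np.sin(t)) / size))


def toy_pairs(seed: int, n_volumes: int = 10, slices_per_volume: int = 20,
              kind: str = "zipper"):
    """z-scored (corrupted, clean) 64x64 slice pairs from seeded phantoms."""
    X, Y = [], []
    for i in range(n_volumes):
        vol = generate_phantom_volume(seed + i, (32, 64, 64), n_tissues=3,
                                      noise_sd=4.0, bias_amp=0.1)
        spec = sample_artifact_params(kind, seed + 900 + i)
        corr = apply_artifact(vol, spec)
        zc, zk = zscore_normalize(vol), zscore_normalize(corr)
        lo = (32 - slices_per_volume) // 2
        for k in range(lo, lo + slices_per_volume):
            X.append(zk.voxels[k])
            Y.append(zc.voxels[k])
    return np.array(X), np.array(Y)


@pytest.fixture(scope="session")
def toy_dataset():
    """200 paired 64x64 slices (zipper corruption), z-scored per volume."""
    return toy_pairs(100)
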