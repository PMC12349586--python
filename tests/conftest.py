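"""Shared fixtures: the default optical system, small rendered stacks, and
a cached multi-seed denoising study used by the ordering property tests."""

from __future__ import annotations

import numpy as np
import pytest

from sprpol import ppbm4d
from sprpol.optics import OpticalSystem
from sprpol.phase import roi_series
from sprpol.synthetic import NoiseModel, Protocol, default_roi, render_video


@pytest.fixture(scope="session")
def system() -> OpticalSystem:
    """Default instrument with its operating angle resolved once."""
    sys_ = OpticalSystem()
    sys_.aoi_resolved
    return sys_


@pytest.fixture(scope="session")
def flat_video(system):
    """Small constant-index stack with known Gaussian noise (and its truth)."""
    protocol = Protocol.constant(n=1.333, duration_s=4.0)
    noise = NoiseModel(sigma_add=2.0, source_cv=0.0, bit_depth=0, seed=11)
    video, truth = render_video(system, protocol, noise, shape=(48, 48), n_frames=8)
    return video, truth


@pytest.fixture(scope="session")
def ordering_study(system):
    """Temporal ROI-phase SDs of raw / pair / no-pair / 1-frame variants
    over 10 seeds on small flat stacks (the published-pattern property data).

    Computed once per session; several tests assert on different aspects.
    """
    shape = (48, 48)
    n_frames = 10
    sigma = 0.6
    roi = default_roi(shape)
    protocol = Protocol.constant(n=1.333, duration_s=n_frames / 2.0)
    configs = {
        "ppbm4d": ppbm4d.PPConfig(sigma=sigma),
        "bm4d_no_pp": ppbm4d.config_for_mode("bm4d_no_pp", sigma=sigma),
        "frames_1": ppbm4d.PPConfig(sigma=sigma, n_frames=1),
    }
    sds: dict[str, list[float]] = {k: [] for k in ["raw", *configs]}
    for seed in range(10):
        noise = NoiseModel(sigma_add=sigma, source_cv=0.0, bit_depth=0, seed=seed)
        video, _ = render_video(system, protocol, noise, shape=shape, n_frames=n_frames)
        sds["raw"].append(roi_series(video, roi).sd())
        for name, cfg in configs.items():
            sds[name].append(roi_series(ppbm4d.denoise(video, cfg), roi).sd())
    return {k: np.asarray(v) for k, v in sds.items()}
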