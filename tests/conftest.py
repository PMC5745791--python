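"""Shared fixtures: small, seeded simulator configurations.

Tests run the full pipeline on reduced problem sizes (fewer channels,
128 Hz) so the suite stays fast; the generators themselves default to the
full 32-channel 512 Hz setup.
"""

import numpy as np
import pytest

from smrbci.synthetic import (LAPLACIAN_NEIGHBOURS, ParadigmSpec, SimConfig,
                              Source, generate_calibration_session)

SMALL_MONTAGE = (
    ["C3"] + LAPLACIAN_NEIGHBOURS["C3"]
    + ["Cz"] + LAPLACIAN_NEIGHBOURS["Cz"]
    + ["Pz", "P3", "P4", "AFz", "Fz", "O1"]
)


def small_config(seed: int = 0, **kw) -> SimConfig:
    defaults = dict(
        sampling_rate=128.0,
        channel_labels=list(SMALL_MONTAGE),
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def calib_session():
    """10 TPC four-class calibration session on the small montage."""
    cfg = small_config(seed=42)
    return cfg, generate_calibration_session(cfg, 10)


@pytest.fixture(scope="session")
def code_map():
    return {i + 1: c for i, c in enumerate(["HAND", "FEET", "SUB", "REST"])}


@pytest.fixture(scope="session")
def calib_trials(calib_session, code_map):
    from smrbci.preprocess import segment

    cfg, sess = calib_session
    return segment(sess.recording, code_map, (-3.0, 5.0))


def two_source_config(seed: int = 0, n_channels: int = 4) -> SimConfig:
    """Two band-limited sources with a random full-rank mixing matrix."""
    rng = np.random.default_rng(seed)
    channels = [f"ch{i}" for i in range(n_channels)]
    sources = [Source("s1", (8.0, 14.0), 8.0), Source("s2", (18.0, 26.0), 8.0)]
    M = rng.standard_normal((2, n_channels))
    return SimConfig(
        sampling_rate=128.0, channel_labels=channels,
        class_set=["A", "B"], sources=sources,
        erd_depth={"A": {"s1": -0.8}, "B": {}},
        mixing_matrix=M, noise_sd=1.0, seed=seed,
    )
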