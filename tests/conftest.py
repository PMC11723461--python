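"""Shared fixtures: small synthetic pools and desk-scale model configs."""

import numpy as np
import pytest

import eegdenoise as ed


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eeg_pool():
    return ed.gen_eeg(ed.GenSpec(n_segments=30, seed=101))


@pytest.fixture(scope="session")
def eog_pool():
    return ed.gen_eog(ed.GenSpec(n_segments=30, seed=102))


@pytest.fixture(scope="session")
def emg_pool():
    return ed.gen_emg(ed.GenSpec(n_segments=30, seed=103))


@pytest.fixture(scope="session")
def ecg_pool():
    return ed.gen_ecg(ed.GenSpec(n_segments=30, seed=104))


@pytest.fixture(scope="session")
def pairs_0db(eeg_pool, eog_pool):
    """Thirty EOG-contaminated pairs at exactly 0 dB."""
    return [
        ed.mix(x, n, ed.solve_lambda(x, n, 0.0))
        for x, n in zip(eeg_pool, eog_pool)
    ]


def tiny_gen_cfg(**overrides):
    """A fast, fully functional generator config (256-sample segments)."""
    kw = dict(input_len=256, pre_dim=4, encoder_dims=(4, 8, 8, 16, 16),
              n_blocks=5, local_partitions=2, gate_hidden=16, attn_heads=1,
              width_scale=1.0, seed=0)
    kw.update(overrides)
    return ed.GeneratorConfig(**kw)


def tiny_disc_cfg(**overrides):
    kw = dict(channels=(4, 4, 8, 8, 8, 8, 16, 16), input_len=256, seed=0)
    kw.update(overrides)
    return ed.DiscriminatorConfig(**kw)


@pytest.fixture()
def tiny_models():
    from eegdenoise.training import build_models

    return build_models(tiny_gen_cfg(), tiny_disc_cfg())


def tiny_pairs(n, seed, snr_db=None, input_len=256):
    """EOG-contaminated pairs on short segments for fast training tests."""
    fs = 512.0
    dur = input_len / fs
    eeg = ed.gen_eeg(ed.GenSpec(n_segments=n, seed=seed, fs=fs, duration_s=dur))
    eog = ed.gen_eog(ed.GenSpec(n_segments=n, seed=seed + 1, fs=fs, duration_s=dur))
    rng = np.random.default_rng(seed + 2)
    out = []
    for x, a in zip(eeg, eog):
        snr = float(rng.integers(-7, 3)) if snr_db is None else snr_db
        out.append(ed.mix(x, a, ed.solve_lambda(x, a, snr)))
        out[-1].snr_db = snr
    return out
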