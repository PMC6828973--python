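"""Shared fixtures: small synthetic cohorts and fully processed trials.

Everything is generated programmatically; heavier cohorts are module-scoped
so the suite builds each at most once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import flexrelax as fr


@pytest.fixture(scope="session")
def small_config() -> fr.SyntheticConfig:
    # one subject per group, one side/repetition, reduced sampling rate:
    # enough structure for every stage, fast enough for unit tests
    return fr.SyntheticConfig(
        n_per_group=(1, 1, 1),
        sampling_rate=1024.0,
        n_repetitions=1,
        sides=("left",),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> fr.SyntheticCohort:
    return fr.generate_cohort(small_config)


@pytest.fixture(scope="session")
def processed_control(small_cohort):
    """(trial, seg, bipolar, envelope, onset_map) for the control subject."""
    trial = next(t for t in small_cohort.trials if t.meta.group == "control")
    seg = fr.segment_phases(trial.angle, trial.sampling_rate)
    bt = fr.quality_screen(fr.derive_bipolar(trial), seg)
    env = fr.envelope(bt)
    omap = fr.build_onset_map(env, seg)
    return trial, seg, bt, env, omap


@pytest.fixture(scope="session")
def processed_no_frp(small_cohort):
    trial = next(t for t in small_cohort.trials if t.meta.group == "lbp_no_frp")
    seg = fr.segment_phases(trial.angle, trial.sampling_rate)
    bt = fr.quality_screen(fr.derive_bipolar(trial), seg)
    env = fr.envelope(bt)
    omap = fr.build_onset_map(env, seg)
    return trial, seg, bt, env, omap


def quiet_quality_screen(trial, seg, cfg=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fr.quality_screen(trial, seg, cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
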