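"""Shared fixtures: simulated trials reused across test modules."""
import numpy as np
import pytest

from kneestab.preprocessing import (estimate_orientation, remove_gyro_bias,
                                    tibia_pitch)
from kneestab.synthetic import SimConfig, simulate_cht, simulate_cmj_grf, \
    simulate_sls


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(noise_sd_acc=0.0, noise_sd_gyro=0.0, noise_sd_mag=0.0,
                     noise_sd_grf=0.0, gyro_bias=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def sls_ideal(noiseless_cfg):
    """Noise-free squat with no lever-arm or sway disturbance: the fused
    pitch equals the analytic angle trajectory to discretisation error."""
    tibia, foot, gt = simulate_sls(noiseless_cfg, seed=11, lever_arm=0.0,
                                   sway_sd=(0.0, 0.0))
    rec = remove_gyro_bias(tibia, (0, 1000))
    orient = estimate_orientation(rec)
    return {"tibia": rec, "foot": foot, "orient": orient,
            "pitch": tibia_pitch(orient), "gt": gt, "raw": tibia}


@pytest.fixture(scope="session")
def sls_noisy(default_cfg):
    """One squat at the default (realistic) sensor noise and bias."""
    tibia, foot, gt = simulate_sls(default_cfg, seed=21)
    rec = remove_gyro_bias(tibia, (0, 1000))
    orient = estimate_orientation(rec)
    return {"tibia": rec, "foot": remove_gyro_bias(foot, (0, 1000)),
            "orient": orient, "pitch": tibia_pitch(orient), "gt": gt}


@pytest.fixture(scope="session")
def cht_ideal(noiseless_cfg):
    foot, tibia, gt = simulate_cht(noiseless_cfg, seed=13)
    return {"foot": foot, "tibia": tibia, "gt": gt}


@pytest.fixture(scope="session")
def cmj_ideal(noiseless_cfg):
    grf, gt = simulate_cmj_grf(noiseless_cfg, jump_height=0.30, seed=17)
    return {"grf": grf, "gt": gt}


def events_in_samples(gt, fs):
    return {k: v * fs for k, v in gt.event_times.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
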