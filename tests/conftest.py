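import numpy as np
import pytest

import stairgaze as sg
from stairgaze.synth import noise_free


@pytest.fixture(scope="session")
def group_params():
    return sg.default_group_params()


@pytest.fixture(scope="session")
def clean_walk(group_params):
    """One noise-free descending walk of a stairs-relevant participant."""
    params = noise_free(group_params["stairs_relevant"])
    return sg.generate_walk(params, direction="descending", rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def clean_walk_result(clean_walk):
    rec, _ = clean_walk
    return sg.analyze_recording(rec)


@pytest.fixture(scope="session")
def small_cohort(group_params):
    """Four participants per group, both directions, default noise."""
    return sg.generate_cohort(group_params, 4, seed=11)


def random_gaze_trace(rng, n=None):
    """A random but saccade-bearing gaze trace for oracle comparisons:
    drifting fixations, injected minimum-jerk jumps, white noise, and an
    occasional invalid (blink) span."""
    n = n or int(rng.integers(200, 2000))
    dt = 0.005
    t = np.arange(n) * dt
    az = np.zeros(n)
    el = np.zeros(n)
    pos = rng.uniform(-5, 5, 2)
    drift = rng.uniform(-8, 8, 2)
    i = 0
    while i < n:
        dur = int(rng.integers(40, 200))
        j = min(n, i + dur)
        steps = np.arange(j - i) * dt
        az[i:j] = pos[0] + drift[0] * steps
        el[i:j] = pos[1] + drift[1] * steps
        pos = pos + drift * (j - i) * dt
        # saccade to a new target
        amp = rng.uniform(0.5, 12.0)
        theta = rng.uniform(0, 2 * np.pi)
        target = pos + amp * np.array([np.sin(theta), np.cos(theta)])
        sdur = max(4, int(round((0.02 + 0.002 * amp) / dt)))
        k = min(n, j + sdur)
        if k > j:
            tau = np.linspace(0, 1, k - j, endpoint=False)
            prof = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
            az[j:k] = pos[0] + (target[0] - pos[0]) * prof
            el[j:k] = pos[1] + (target[1] - pos[1]) * prof
        pos = target
        drift = rng.uniform(-8, 8, 2)
        i = k
    noise_sd = rng.uniform(0.0, 0.2)
    az = az + rng.normal(0, noise_sd, n)
    el = el + rng.normal(0, noise_sd, n)
    valid = np.ones(n, dtype=bool)
    for _ in range(int(rng.integers(0, 3))):
        a = int(rng.integers(0, n))
        valid[a : a + int(rng.integers(5, 40))] = False
    return sg.GazeTrace(t, az, el, valid)
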