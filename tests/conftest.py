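import numpy as np
import pytest

import phonoseq as pq


def make_session(style="compositional", repeats=8, seed=0, snr=2.0,
                 alignment=None, gains=None, **code_kw):
    """Small CVCVC session on a 3-consonant inventory, z-scored."""
    cset = pq.build_full_factorial(["K", "N", "SH"], 3)
    cfg = pq.GeneratorConfig(seed=seed, snr=snr)
    code = pq.make_ground_truth_code(
        cfg, cset, alignment=alignment, gains=gains, style=style, **code_kw
    )
    plan = pq.make_trial_plan(cset, repeats=repeats, seed=seed)
    session = pq.simulate_session(code, plan, cfg)
    return pq.zscore_session(session), code, cfg


def make_noiseless_session(repeats=2, seed=0, **code_kw):
    """Noise-free session: features equal the ground-truth means exactly."""
    cset = pq.build_full_factorial(["K", "N", "SH"], 3)
    cfg = pq.GeneratorConfig(seed=seed, trial_noise_sd=0.0, bin_noise_sd=0.0,
                             drift_sd=0.0)
    code = pq.make_ground_truth_code(cfg, cset, **code_kw)
    plan = pq.make_trial_plan(cset, repeats=repeats, seed=seed)
    return pq.simulate_session(code, plan, cfg), code, cfg


@pytest.fixture(scope="session")
def standard_session():
    """Shared mid-size compositional session (27 conditions x 10 trials)."""
    session, code, cfg = make_session(repeats=10, seed=42)
    return session, code, cfg


@pytest.fixture(scope="session")
def noiseless_session():
    session, code, cfg = make_noiseless_session(seed=7)
    return session, code, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
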