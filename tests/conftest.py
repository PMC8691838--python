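import pytest

from burstpipe.synthetic import (
    SITES,
    BehaviorGenParams,
    CouplingRule,
    LfpGenParams,
    SiteRateProfile,
    simulate_behavior,
    simulate_lfp,
)


@pytest.fixture(scope="session")
def small_trials():
    """One short behavioral session (48 trials)."""
    return simulate_behavior(BehaviorGenParams(n_trials=48, seed=11))


@pytest.fixture(scope="session")
def coupled_session(small_trials):
    """Short LFP session with deterministic STN->SMC coupling at +50 ms."""
    params = LfpGenParams(seed=12, coupling=[CouplingRule("STN", "SMC", 50.0, 1.0)])
    rec, truth = simulate_lfp(small_trials, params)
    return rec, truth, params


@pytest.fixture(scope="session")
def sparse_session():
    """Medium session with sparse homogeneous bursts (recovery testing)."""
    trials = simulate_behavior(BehaviorGenParams(n_trials=96, seed=21))
    profiles = {s: SiteRateProfile(0.1, []) for s in SITES}
    params = LfpGenParams(seed=22, rate_profiles=profiles)
    rec, truth = simulate_lfp(trials, params)
    return trials, rec, truth
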