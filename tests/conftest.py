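import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ppdecode as pp
from ppdecode.smc import _slice_spikes
from ppdecode.tuning import KinematicSeries

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

# comparison-study conditions: 15-neuron, 240-s sessions, first 120 s train
COMPARISON_TRAIN_BINS = 12_000
COMPARISON_SEEDS = tuple(range(300, 308))
CONTROL_SEEDS = tuple(range(320, 328))


def simulate_session(config: pp.SimulationConfig):
    rng = np.random.default_rng(config.seed)
    kin = pp.simulate_kinematics(config, rng)
    tuning = pp.draw_true_tuning(config, rng)
    spikes = pp.simulate_ensemble(kin, tuning, rng=rng)
    return spikes, kin, tuning


@pytest.fixture(scope="session")
def small_session():
    """One small coupled session for unit tests (8 neurons, 120 s)."""
    cfg = pp.SimulationConfig(n_neurons=8, duration=120.0, seed=42)
    return (*simulate_session(cfg), cfg)


@pytest.fixture(scope="session")
def coupled_sessions():
    """The eight coupled comparison sessions."""
    out = []
    for seed in COMPARISON_SEEDS:
        cfg = pp.SimulationConfig(n_neurons=15, duration=240.0, seed=seed)
        out.append(simulate_session(cfg))
    return out


@pytest.fixture(scope="session")
def coupled_report(coupled_sessions):
    pairs = [(s, k) for s, k, _ in coupled_sessions]
    return pp.run_comparison(
        pairs, train_seconds=120.0, n_particles=300, decode_seed=11,
        n_decode_runs=3,
    )


@pytest.fixture(scope="session")
def control_report():
    configs = [
        pp.SimulationConfig(
            n_neurons=15, duration=240.0, seed=seed, coupling_scale=0.0
        )
        for seed in CONTROL_SEEDS
    ]
    return pp.run_comparison(
        configs, train_seconds=120.0, n_particles=300, decode_seed=11,
        n_decode_runs=3,
    )


@pytest.fixture(scope="session")
def fitted_full_decoders(coupled_sessions):
    """Full-model pipelines fitted on each coupled session's training span."""
    out = []
    for spikes, kin, _ in coupled_sessions:
        dec = pp.SMCDecoder(kind="full", n_particles=200, random_state=11)
        dec.fit(
            _slice_spikes(spikes, 0, COMPARISON_TRAIN_BINS),
            KinematicSeries(
                t=kin.t[:COMPARISON_TRAIN_BINS], x=kin.x[:COMPARISON_TRAIN_BINS]
            ),
        )
        out.append((dec, spikes, kin))
    return out
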