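import numpy as np
import pytest

from splicechrom import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(seed=7, n_genes=60, n_true_events=12)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small end-to-end synthetic dataset shared across tests."""
    ann = sim.simulate_annotation(small_config)
    counts, expr, truth = sim.simulate_junction_counts(small_config, ann)
    peaks, truth = sim.simulate_peaks(ann, truth, small_config)
    track = sim.simulate_signal_track(ann, truth, small_config)
    return {
        "config": small_config,
        "annotation": ann,
        "counts": counts,
        "expression": expr,
        "truth": truth,
        "peaks": peaks,
        "track": track,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
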