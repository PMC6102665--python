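import numpy as np
import pytest

from gaitattractor import attractor as core
from gaitattractor import preprocessing as prep
from gaitattractor import synthetic as syn


@pytest.fixture(scope="session")
def default_subject():
    return syn.generate_subject(11)


@pytest.fixture(scope="session")
def quiet_spec():
    """Population with low stride-to-stride noise, for recovery tests."""
    return syn.PopulationSpec(within_noise_sigma=0.02)


def attractors_from_recording(rec, n_per_condition=None, use_filter=True):
    """Build the four B/E attractors from a synthetic recording using the
    ground-truth events (bypassing windowing and detection)."""
    from gaitattractor.preprocessing import StrideCycle, lowpass_filter, normalize_cycle

    n = n_per_condition or rec.n_strides_per_condition
    atts = {}
    for foot in ("left", "right"):
        ts = rec.recordings[foot]
        if use_filter:
            ts = lowpass_filter(ts)
        idx = rec.ground_truth_events[foot].indices
        total = len(idx)
        # the final stride's end is unmarked, so condition E uses the last
        # n-1 fully event-bounded strides
        for cond, lo, hi in (("B", 0, n), ("E", total - n, total - 1)):
            strides = [StrideCycle(ts.samples[a:b], foot, cond)
                       for a, b in zip(idx[lo:hi], idx[lo + 1:hi + 1])]
            cycles = [normalize_cycle(s) for s in strides]
            atts[(foot, cond)] = core.compute_attractor(cycles)
    return atts


@pytest.fixture(scope="session")
def small_attractor_factory():
    def make(mean, deviation=None, foot="left", condition="B", n_strides=2):
        mean = np.asarray(mean, dtype=float)
        dev = (np.zeros(mean.shape[0]) if deviation is None
               else np.asarray(deviation, dtype=float))
        return core.Attractor(mean_cycle=mean, deviation=dev,
                              n_strides=n_strides, foot=foot,
                              condition=condition)
    return make
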