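"""Synthetic cohort generator: determinism, ground-truth consistency and
the designed condition-contrast algebra."""

import numpy as np
import pytest

from gaitattractor import attractor as core
from gaitattractor import synthetic as syn
from gaitattractor.exceptions import ConfigurationError


def test_generate_subject_deterministic():
    a = syn.generate_subject(1)
    b = syn.generate_subject(1)
    for foot in ("left", "right"):
        assert np.array_equal(a.harmonic_coeffs[foot], b.harmonic_coeffs[foot])
        assert np.array_equal(a.ortho_coeffs[foot], b.ortho_coeffs[foot])
    assert a.stride_period == b.stride_period
    assert a.speed == b.speed


def test_generate_subject_distinct_seeds():
    a = syn.generate_subject(1)
    b = syn.generate_subject(2)
    assert not np.array_equal(a.harmonic_coeffs["left"], b.harmonic_coeffs["left"])


def test_harmonic_structure_k3():
    spec = syn.PopulationSpec(n_harmonics=3)
    subj = syn.generate_subject(5, spec)
    for foot in ("left", "right"):
        assert subj.harmonic_coeffs[foot].shape == (3, 3, 2)


@pytest.mark.parametrize("kwargs", [
    {"stride_period_mean": -1.0},
    {"within_noise_sigma": -0.1},
    {"speed_mean": 0.0},
])
def test_invalid_population_spec_raises(kwargs):
    with pytest.raises(ConfigurationError):
        syn.PopulationSpec(**kwargs)


def test_null_effect_no_noise_gives_identical_segments():
    spec = syn.PopulationSpec(within_noise_sigma=0.0)
    subj = syn.generate_subject(3, spec)
    rec = syn.synthesize_recording(subj, syn.ConditionEffect(), 5, seed=9)
    for foot in ("left", "right"):
        idx = rec.ground_truth_events[foot].indices
        ts = rec.recordings[foot].samples
        first = ts[idx[0]:idx[1]]
        for i in range(1, 9):
            np.testing.assert_array_equal(ts[idx[i]:idx[i] + first.shape[0]], first)
        np.testing.assert_array_equal(rec.true_base_cycles[foot]["B"],
                                      rec.true_base_cycles[foot]["E"])


def test_event_count_and_spacing():
    spec = syn.PopulationSpec(stride_period_mean=1.0, stride_period_sd=0.0,
                              within_noise_sigma=0.0)
    subj = syn.generate_subject(4, spec)
    rec = syn.synthesize_recording(subj, syn.ConditionEffect(), 10, rate=400, seed=1)
    for foot in ("left", "right"):
        idx = rec.ground_truth_events[foot].indices
        assert len(idx) == 20
        assert np.all(np.diff(idx) == 400)


def test_event_jitter_bounded_by_four_sigma():
    spec = syn.PopulationSpec(stride_period_mean=1.0, stride_period_sd=0.0,
                              within_noise_sigma=1.0)
    subj = syn.generate_subject(4, spec)
    rec = syn.synthesize_recording(subj, syn.ConditionEffect(), 25, rate=400, seed=1)
    jit = subj.timing_jitter_cv
    assert jit > 0
    for foot in ("left", "right"):
        gaps = np.diff(rec.ground_truth_events[foot].indices)
        assert np.all(np.abs(gaps - 400) <= 4 * jit * 400 + 1)


def test_epsilon_shift_matches_direct_harmonic_evaluation():
    """The B→E pattern shift equals ε·(AC RMS)·orthogonal shape, verified
    by independently re-evaluating the amplitude/phase harmonic series."""
    spec = syn.PopulationSpec(within_noise_sigma=0.0)
    subj = syn.generate_subject(8, spec)
    eps = 0.3
    rec = syn.synthesize_recording(subj, syn.ConditionEffect(eps, 1, 1), 3,
                                   seed=0, m=64)
    tau = np.arange(64) / 64
    for foot in ("left", "right"):
        # independent oracle: direct summation of amp·sin(2πkφ + phase)
        def evaluate(coeffs, dc):
            out = np.tile(dc, (64, 1))
            for ax in range(3):
                for k in range(coeffs.shape[1]):
                    amp, ph = coeffs[ax, k]
                    out[:, ax] += amp * np.sin(2 * np.pi * (k + 1) * tau + ph)
            return out

        base = evaluate(subj.harmonic_coeffs[foot], subj.dc[foot])
        shape = evaluate(subj.ortho_coeffs[foot], np.zeros(3))
        expected_E = base + eps * subj.ac_rms[foot] * shape
        np.testing.assert_allclose(rec.true_base_cycles[foot]["B"], base,
                                   atol=1e-10)
        np.testing.assert_allclose(rec.true_base_cycles[foot]["E"], expected_E,
                                   atol=1e-10)
        diff = rec.true_base_cycles[foot]["E"] - rec.true_base_cycles[foot]["B"]
        rms = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
        # phase-averaged RMS of the unit shape is 1 by construction
        assert rms == pytest.approx(eps * subj.ac_rms[foot], rel=0.02)


def test_true_delta_M_null_and_linearity(default_subject):
    assert syn.true_delta_M(default_subject, syn.ConditionEffect(0.0, 1, 1)) == 0.0
    d1 = syn.true_delta_M(default_subject, syn.ConditionEffect(0.2, 1, 1))
    d2 = syn.true_delta_M(default_subject, syn.ConditionEffect(0.4, 1, 1))
    assert d2 == pytest.approx(2 * d1, rel=1e-9)


def test_true_delta_M_monotone_in_epsilon(default_subject):
    grid = [0.0, 0.1, 0.2, 0.3, 0.4, 1.0]
    vals = [syn.true_delta_M(default_subject, syn.ConditionEffect(e, 1, 1))
            for e in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_true_delta_M_consistent_with_attractor_module(default_subject):
    """true_delta_M is definitionally the δM of the noiseless base cycles."""
    eff = syn.ConditionEffect(0.25, 1, 1)
    m = 128
    tau = np.arange(m) / m
    atts = {}
    for foot in ("left", "right"):
        for cond, eps in (("B", 0.0), ("E", 0.25)):
            cyc = default_subject.evaluate_cycle(foot, tau, epsilon=eps)
            atts[(foot, cond)] = core.Attractor(cyc, np.zeros(m), 2, foot, cond)
    expected = core.delta_M(atts[("right", "B")], atts[("right", "E")],
                            atts[("left", "B")], atts[("left", "E")],
                            v=default_subject.speed)
    assert syn.true_delta_M(default_subject, eff, m=m) == pytest.approx(
        expected, rel=1e-12)


def test_effect_validation():
    with pytest.raises(ConfigurationError):
        syn.ConditionEffect(pattern_shift_epsilon=1.5)
    with pytest.raises(ConfigurationError):
        syn.ConditionEffect(variability_factor=0.0)
    with pytest.raises(ConfigurationError):
        syn.synthesize_recording(syn.generate_subject(1), syn.ConditionEffect(),
                                 n_strides_per_condition=1)


def test_cohort_zero_spread_shares_base_cycle():
    recs, _ = syn.generate_cohort(3, 0.0, 0.5, syn.ConditionEffect(), seed=2,
                                  n_strides_per_condition=3)
    ref = recs[0].subject.harmonic_coeffs["left"]
    for rec in recs[1:]:
        np.testing.assert_allclose(rec.subject.harmonic_coeffs["left"], ref,
                                   atol=1e-12)


def test_cohort_deterministic():
    a, ma = syn.generate_cohort(3, 0.3, 1.0, syn.ConditionEffect(0.1, 1.2, 1),
                                seed=6, n_strides_per_condition=4)
    b, mb = syn.generate_cohort(3, 0.3, 1.0, syn.ConditionEffect(0.1, 1.2, 1),
                                seed=6, n_strides_per_condition=4)
    for ra, rb in zip(a, b):
        for foot in ("left", "right"):
            np.testing.assert_array_equal(ra.recordings[foot].samples,
                                          rb.recordings[foot].samples)
            np.testing.assert_array_equal(ra.ground_truth_events[foot].indices,
                                          rb.ground_truth_events[foot].indices)
    assert [m.six_mwd for m in ma] == [m.six_mwd for m in mb]


def test_cohort_study_size():
    recs, mans = syn.generate_cohort(24, 0.34, 1.0, syn.ConditionEffect(),
                                     seed=3, n_strides_per_condition=2)
    assert len(recs) == 24
    assert len({m.subject_id for m in mans}) == 24


def test_study_cohort_structure():
    sessions = syn.generate_study_cohort(seed=4, n_healthy=2, n_patients=2,
                                         duration_s=60.0)
    labels = [(m.group, m.assessment) for _, m in sessions]
    assert labels.count(("healthy", "baseline")) == 2
    for a in ("baseline", "week10", "month12"):
        assert labels.count(("patient", a)) == 2
    for rec, man in sessions:
        assert man.six_mwd == pytest.approx(rec.subject.speed * 360.0)
        if man.group == "patient":
            assert 0.0 <= man.odi_percent <= 100.0


def test_turn_segment_corrupts_one_stride_and_outlier_guard_is_separate():
    from gaitattractor import preprocessing as prep

    spec = syn.PopulationSpec(within_noise_sigma=0.0)
    subj = syn.generate_subject(14, spec)
    rec = syn.synthesize_recording(subj, syn.ConditionEffect(), 5, seed=0)
    turned = syn.insert_turn_segment(rec, stride_index=3, seed=1)
    idx = turned.ground_truth_events["left"].indices
    a, b = idx[3], idx[4]
    clean = rec.recordings["left"].samples
    assert not np.allclose(turned.recordings["left"].samples[a:b], clean[a:b])
    np.testing.assert_array_equal(turned.recordings["left"].samples[:a], clean[:a])
    # stride lengths unchanged, so the corrupted cycle passes the length
    # guard but inflates the deviation profile instead
    window = prep.ConditionWindow("B", 0, len(idx) - 1, 5.0, 5.0, 1.0)
    strides = prep.cut_strides(turned.recordings["left"],
                               turned.ground_truth_events["left"], window)
    assert len(strides) == len(idx) - 1


def test_jitter_events_strictly_increasing():
    ev = syn.jitter_events(
        syn.synthesize_recording(syn.generate_subject(1), syn.ConditionEffect(),
                                 5, seed=0).ground_truth_events["left"],
        sd_samples=5.0, seed=2)
    assert np.all(np.diff(ev.indices) > 0)
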