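"""Attractor computation and the δM/δD/δF metrics against hand-worked
values, brute-force oracles and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitattractor import attractor as core
from gaitattractor.exceptions import ComputationError
from gaitattractor.preprocessing import NormalizedCycle


def _cycles(stack, foot="left", condition="B"):
    return [NormalizedCycle(samples=s, foot=foot, condition=condition)
            for s in stack]


# --- independent brute-force oracles (nested loops, no vectorization) ----

def brute_attractor(stack):
    n, m, _ = stack.shape
    mean = np.zeros((m, 3))
    for j in range(m):
        for ax in range(3):
            s = 0.0
            for i in range(n):
                s += stack[i, j, ax]
            mean[j, ax] = s / n
    dev = np.zeros(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            d2 = 0.0
            for ax in range(3):
                d2 += (stack[i, j, ax] - mean[j, ax]) ** 2
            s += d2
        dev[j] = (s / n) ** 0.5
    return mean, dev


def brute_delta_M(rB, rE, lB, lE, v):
    m = rB.shape[0]
    total = 0.0
    for j in range(m):
        for ax in range(3):
            total += (rB[j, ax] - rE[j, ax]) ** 2
            total += (lB[j, ax] - lE[j, ax]) ** 2
    return (total / (m * v * v)) ** 0.5


def brute_delta_D(drB, drE, dlB, dlE):
    m = len(drB)
    total = 0.0
    for j in range(m):
        total += (drB[j] - drE[j]) ** 2 + (dlB[j] - dlE[j]) ** 2
    return (total / m) ** 0.5


# --- compute_attractor ---------------------------------------------------

def test_identical_cycles_give_zero_deviation():
    cycle = np.arange(12.0).reshape(4, 3)
    att = core.compute_attractor(_cycles(np.stack([cycle] * 5)))
    assert np.allclose(att.mean_cycle, cycle)
    assert np.allclose(att.deviation, 0.0)
    assert att.n_strides == 5


def test_two_constant_cycles_hand_arithmetic():
    # values {0} and {2} on one embedded axis: mean 1, RMS of {-1,+1} = 1
    zeros = np.zeros((4, 3))
    twos = np.zeros((4, 3))
    twos[:, 0] = 2.0
    att = core.compute_attractor(_cycles(np.stack([zeros, twos])))
    assert np.allclose(att.mean_cycle[:, 0], 1.0)
    assert np.allclose(att.deviation, 1.0)


@pytest.mark.parametrize("bad", ["mixed_m", "mixed_foot", "single"])
def test_attractor_input_contracts(bad):
    a = NormalizedCycle(np.zeros((4, 3)), "left", "B")
    if bad == "mixed_m":
        b = NormalizedCycle(np.zeros((5, 3)), "left", "B")
    elif bad == "mixed_foot":
        b = NormalizedCycle(np.zeros((4, 3)), "right", "B")
    else:
        b = None
    with pytest.raises(ComputationError):
        core.compute_attractor([a] if b is None else [a, b])


def test_attractor_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(2, 4)
        m = rng.integers(4, 6)
        stack = rng.normal(size=(n, m, 3))
        att = core.compute_attractor(_cycles(stack))
        mean, dev = brute_attractor(stack)
        assert np.max(np.abs(att.mean_cycle - mean)) <= 1e-12
        assert np.max(np.abs(att.deviation - dev)) <= 1e-12


# --- delta metrics -------------------------------------------------------

def _toy_delta_M_attractors(make):
    """m=2, both feet: per-point B-E difference vectors (1,0,0), (2,0,0)."""
    B = make(np.zeros((2, 3)))
    E = make(np.array([[1.0, 0, 0], [2.0, 0, 0]]), condition="E")
    return B, E


def test_delta_M_hand_value_sqrt5(small_attractor_factory):
    B, E = _toy_delta_M_attractors(small_attractor_factory)
    dM = core.delta_M(B, E, B, E, v=1.0)
    assert dM == pytest.approx(np.sqrt(5.0), abs=1e-9)
    assert core.delta_M(B, E, B, E, v=1.0, sqrt_mode=False) == pytest.approx(5.0, abs=1e-9)


def test_delta_M_zero_on_self_comparison(small_attractor_factory):
    A = small_attractor_factory(np.random.default_rng(0).normal(size=(7, 3)))
    assert core.delta_M(A, A, A, A, v=1.3) == 0.0
    assert core.delta_M(A, A, A, A, v=1.3, sqrt_mode=False) == 0.0


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_delta_M_speed_scale_invariance(small_attractor_factory, c):
    rng = np.random.default_rng(3)
    atts = [small_attractor_factory(rng.normal(size=(9, 3))) for _ in range(4)]
    v = 1.2
    base = core.delta_M(*atts, v=v)
    scaled = [small_attractor_factory(a.mean_cycle * c) for a in atts]
    assert core.delta_M(*scaled, v=c * v) == pytest.approx(base, rel=1e-12)


def test_delta_M_errors(small_attractor_factory):
    A = small_attractor_factory(np.zeros((4, 3)))
    B = small_attractor_factory(np.zeros((5, 3)))
    with pytest.raises(ComputationError):
        core.delta_M(A, A, A, B, v=1.0)
    with pytest.raises(ComputationError):
        core.delta_M(A, A, A, A, v=0.0)


def test_delta_D_hand_value_five():
    # m=1: right-foot difference 3, left-foot difference 4 -> sqrt(25) = 5
    dD = core.delta_D([3.0], [0.0], [4.0], [0.0])
    assert dD == pytest.approx(5.0, abs=1e-9)
    assert core.delta_D([3.0], [0.0], [4.0], [0.0], sqrt_mode=False) == pytest.approx(25.0)
    assert core.delta_D([1.0, 2], [1.0, 2], [0.5, 1], [0.5, 1]) == 0.0


def test_delta_metrics_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        m = int(rng.integers(1, 6))
        cycles = rng.normal(size=(4, m, 3))
        devs = np.abs(rng.normal(size=(4, m)))
        v = float(rng.uniform(0.5, 2.0))
        atts = [core.Attractor(cycles[i], devs[i], 2, "left", "B")
                for i in range(4)]
        assert core.delta_M(*atts, v=v) == pytest.approx(
            brute_delta_M(*cycles, v), abs=1e-12)
        assert core.delta_D(*devs) == pytest.approx(
            brute_delta_D(*devs), abs=1e-12)


def test_delta_F_product_and_errors():
    assert core.delta_F(2.0, 0.5) == 1.0
    assert core.delta_F(0.0, 123.4) == 0.0
    assert core.delta_F(np.sqrt(5.0), 5.0) == pytest.approx(5 * np.sqrt(5.0), abs=1e-9)
    with pytest.raises(ComputationError):
        core.delta_F(-0.1, 1.0)


def test_condition_swap_symmetry(small_attractor_factory):
    rng = np.random.default_rng(5)
    rB, rE, lB, lE = [small_attractor_factory(rng.normal(size=(6, 3)),
                                              deviation=np.abs(rng.normal(size=6)))
                      for _ in range(4)]
    v = 1.1
    assert core.delta_M(rB, rE, lB, lE, v=v) == pytest.approx(
        core.delta_M(rE, rB, lE, lB, v=v), rel=1e-14)
    assert core.delta_D(rB.deviation, rE.deviation, lB.deviation, lE.deviation) == \
        pytest.approx(core.delta_D(rE.deviation, rB.deviation,
                                   lE.deviation, lB.deviation), rel=1e-14)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(cycles=arrays(np.float64, (4, 5, 3),
                     elements=st.floats(-50, 50, allow_nan=False)),
       devs=arrays(np.float64, (4, 5), elements=st.floats(0, 10)),
       v=st.floats(0.2, 3.0))
def test_metric_invariants_property(cycles, devs, v):
    """δM, δD ≥ 0, δF ≡ δM·δD, and both vanish on self-comparison."""
    atts = [core.Attractor(cycles[i], devs[i], 2, "left", "B") for i in range(4)]
    dM = core.delta_M(*atts, v=v)
    dD = core.delta_D(*devs)
    assert dM >= 0 and dD >= 0
    assert core.delta_F(dM, dD) == dM * dD
    assert core.delta_M(atts[0], atts[0], atts[2], atts[2], v=v) == 0.0


# --- reference attractor & variability summaries -------------------------

def test_reference_of_identical_attractors(small_attractor_factory):
    A = small_attractor_factory(np.random.default_rng(1).normal(size=(5, 3)))
    ref = core.reference_attractor([A, A, A])
    assert np.allclose(ref.mean_cycle, A.mean_cycle)
    assert ref.between_subject_D <= 1e-12


def test_reference_hand_arithmetic(small_attractor_factory):
    zeros = small_attractor_factory(np.zeros((4, 3)))
    twos_mean = np.zeros((4, 3))
    twos_mean[:, 0] = 2.0
    twos = small_attractor_factory(twos_mean)
    ref = core.reference_attractor([zeros, twos])
    assert np.allclose(ref.mean_cycle[:, 0], 1.0)
    assert ref.between_subject_D == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(ref.between_subject_sd, 1.0)


def test_reference_mixed_m_errors(small_attractor_factory):
    with pytest.raises(ComputationError):
        core.reference_attractor([small_attractor_factory(np.zeros((4, 3))),
                                  small_attractor_factory(np.zeros((5, 3)))])


def test_summarize_within_D_values(small_attractor_factory):
    att0 = small_attractor_factory(np.zeros((3, 3)))
    assert core.summarize_within_D(att0) == 0.0
    att_c = small_attractor_factory(np.zeros((3, 3)), deviation=[2.5, 2.5, 2.5])
    assert core.summarize_within_D(att_c) == pytest.approx(2.5, abs=1e-12)
    att = small_attractor_factory(np.zeros((2, 3)), deviation=[3.0, 4.0])
    assert core.summarize_within_D(att) == pytest.approx(np.sqrt(12.5), abs=1e-9)
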