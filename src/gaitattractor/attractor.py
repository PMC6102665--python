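"""Attractor computation and the δM/δD/δF change metrics.

The attractor of a quasi-periodic movement signal is the mean limit cycle:
with every stride time-normalized to m phase points, the attractor
A̅(τ_j) is the pointwise 3D mean of the n stride cycles, and the deviation
profile D̄(τ_j) is the pointwise root-mean-square Euclidean distance of the
cycles from it.

Three scalars compare two walking conditions B (beginning) and E (end),
using both feet (r, l):

    δM = sqrt( 1/(m v²) Σ_j [ ‖A̅_rB(τ_j) − A̅_rE(τ_j)‖² + ‖A̅_lB(τ_j) − A̅_lE(τ_j)‖² ] )
    δD = sqrt( 1/m     Σ_j [ (D̄_rB(τ_j) − D̄_rE(τ_j))² + (D̄_lB(τ_j) − D̄_lE(τ_j))² ] )
    δF = δM · δD

δM quantifies the change in the acceleration *pattern* between conditions
(normalized by the average walking speed v, which makes it dimensionless
and invariant to a joint rescaling of accelerations and speed); δD the
change in the *variability* around the attractor; δF is the attractor-based
index used as a motor-fatigue marker in earlier work (cut-off δF = 4,
reported in the docs, deliberately not implemented as a classifier).

Both metrics exist with and without the outer square root (``sqrt_mode``);
the root form is the default because only it has the speed-scale
invariance property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ComputationError, ValidationError


@dataclass
class Attractor:
    """Per-foot mean cycle and deviation profile over n strides."""

    mean_cycle: np.ndarray  # (m, 3) m/s^2
    deviation: np.ndarray  # (m,) m/s^2, pointwise RMS distance of cycles
    n_strides: int
    foot: str
    condition: str  # "B" or "E"

    def __post_init__(self):
        self.mean_cycle = np.asarray(self.mean_cycle, dtype=float)
        self.deviation = np.asarray(self.deviation, dtype=float)
        if self.mean_cycle.ndim != 2 or self.mean_cycle.shape[1] != 3:
            raise ValidationError("mean_cycle must be (m, 3)")
        if self.deviation.shape != (self.mean_cycle.shape[0],):
            raise ValidationError("deviation must have one value per phase point")
        if np.any(self.deviation < 0):
            raise ValidationError("deviation profile must be non-negative")
        if self.n_strides < 2:
            raise ValidationError("an attractor requires at least 2 strides")

    @property
    def m(self) -> int:
        return self.mean_cycle.shape[0]


@dataclass
class AttractorComparison:
    """δM/δD/δF between conditions B and E for one subject."""

    delta_M: float
    delta_D: float
    delta_F: float
    v: float  # average speed used in δM, m/s
    m: int
    sqrt_mode: bool
    attractors: dict = field(default_factory=dict)  # keys ("left"|"right", "B"|"E")


@dataclass
class ReferenceAttractor:
    """Group-mean attractor and the between-subject dispersion around it."""

    mean_cycle: np.ndarray  # (m, 3)
    between_subject_sd: np.ndarray  # (m,) pointwise RMS distance of subjects
    between_subject_D: float  # scalar summary, same functional form as within-D
    n_subjects: int
    foot: str
    condition: str


def compute_attractor(cycles) -> Attractor:
    """Average ≥2 phase-normalized stride cycles into an attractor.

    ``cycles`` are :class:`~gaitattractor.preprocessing.NormalizedCycle`
    objects sharing m, foot and condition. D̄(τ_j) is the RMS (over strides)
    of the 3D Euclidean distance from the mean at each phase point.
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        raise ComputationError("attractor undefined for fewer than 2 cycles")
    m = cycles[0].m
    foot = cycles[0].foot
    condition = cycles[0].condition
    for c in cycles:
        if c.m != m:
            raise ComputationError(f"mixed phase-grid sizes: {c.m} vs {m}")
        if c.foot != foot:
            raise ComputationError(f"mixed foot labels: {c.foot} vs {foot}")
        if c.condition != condition:
            raise ComputationError(f"mixed conditions: {c.condition} vs {condition}")
    stack = np.stack([c.samples for c in cycles])  # (n, m, 3)
    mean = stack.mean(axis=0)
    dev = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    return Attractor(mean_cycle=mean, deviation=dev, n_strides=len(cycles),
                     foot=foot, condition=condition)


def delta_M(att_rB: Attractor, att_rE: Attractor, att_lB: Attractor,
            att_lE: Attractor, v: float, sqrt_mode: bool = True) -> float:
    """Change in acceleration pattern between conditions B and E."""
    ms = {att_rB.m, att_rE.m, att_lB.m, att_lE.m}
    if len(ms) != 1:
        raise ComputationError(f"attractors disagree on m: {sorted(ms)}")
    if v <= 0:
        raise ComputationError("average speed v must be positive")
    m = ms.pop()
    total = (np.sum((att_rB.mean_cycle - att_rE.mean_cycle) ** 2)
             + np.sum((att_lB.mean_cycle - att_lE.mean_cycle) ** 2))
    value = total / (m * v**2)
    return float(np.sqrt(value)) if sqrt_mode else float(value)


def delta_D(dev_rB, dev_rE, dev_lB, dev_lE, sqrt_mode: bool = True) -> float:
    """Change in variability around the attractor between conditions.

    Arguments are the four deviation profiles D̄(τ_j), as arrays.
    """
    dev_rB, dev_rE = np.asarray(dev_rB, float), np.asarray(dev_rE, float)
    dev_lB, dev_lE = np.asarray(dev_lB, float), np.asarray(dev_lE, float)
    shapes = {dev_rB.shape, dev_rE.shape, dev_lB.shape, dev_lE.shape}
    if len(shapes) != 1 or dev_rB.ndim != 1:
        raise ComputationError(f"deviation profiles disagree on m: {shapes}")
    m = dev_rB.size
    value = (np.sum((dev_rB - dev_rE) ** 2) + np.sum((dev_lB - dev_lE) ** 2)) / m
    return float(np.sqrt(value)) if sqrt_mode else float(value)


def delta_F(dM: float, dD: float) -> float:
    """Attractor-based index: exactly the product δM·δD."""
    if dM < 0 or dD < 0:
        raise ComputationError("δM and δD must be non-negative")
    return dM * dD


def compare_conditions(attractors: dict, v: float, sqrt_mode: bool = True) -> AttractorComparison:
    """Assemble the full B-vs-E comparison from four attractors.

    ``attractors`` maps ``(foot, condition)`` to :class:`Attractor` for
    foot in {left, right} and condition in {B, E}.
    """
    try:
        rB, rE = attractors[("right", "B")], attractors[("right", "E")]
        lB, lE = attractors[("left", "B")], attractors[("left", "E")]
    except KeyError as exc:
        raise ComputationError(f"missing attractor {exc}") from None
    dM = delta_M(rB, rE, lB, lE, v=v, sqrt_mode=sqrt_mode)
    dD = delta_D(rB.deviation, rE.deviation, lB.deviation, lE.deviation,
                 sqrt_mode=sqrt_mode)
    return AttractorComparison(delta_M=dM, delta_D=dD, delta_F=delta_F(dM, dD),
                               v=v, m=rB.m, sqrt_mode=sqrt_mode,
                               attractors=dict(attractors))


def reference_attractor(attractors) -> ReferenceAttractor:
    """Group-mean attractor over subjects, plus between-subject dispersion.

    All attractors must share m, foot and condition, and be heel-strike
    aligned on the common phase grid. ``between_subject_D`` is the RMS over
    subjects of each subject's RMS distance from the reference — the same
    functional form as the within-subject D̄ summary, so the two numbers
    are directly comparable.
    """
    attractors = list(attractors)
    if len(attractors) < 2:
        raise ComputationError("a reference attractor requires at least 2 subjects")
    m = attractors[0].m
    foot = attractors[0].foot
    condition = attractors[0].condition
    for a in attractors:
        if a.m != m:
            raise ComputationError(f"mixed phase-grid sizes: {a.m} vs {m}")
        if a.foot != foot or a.condition != condition:
            raise ComputationError("mixed foot or condition labels")
    stack = np.stack([a.mean_cycle for a in attractors])  # (n_subj, m, 3)
    ref = stack.mean(axis=0)
    sq = np.sum((stack - ref) ** 2, axis=2)  # (n_subj, m)
    pointwise = np.sqrt(sq.mean(axis=0))
    between_D = float(np.sqrt(sq.mean()))
    return ReferenceAttractor(mean_cycle=ref, between_subject_sd=pointwise,
                              between_subject_D=between_D,
                              n_subjects=len(attractors), foot=foot,
                              condition=condition)


def summarize_within_D(attractor: Attractor) -> float:
    """Scalar within-subject variability: RMS of D̄(τ_j) over the cycle."""
    return float(np.sqrt(np.mean(attractor.deviation**2)))
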