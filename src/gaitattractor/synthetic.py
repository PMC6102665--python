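"""Synthetic bilateral foot-acceleration cohorts with known ground truth.

The generator emulates the statistical structure the attractor analysis
assumes: each subject walks with a subject-specific quasi-periodic 3D
foot-acceleration limit cycle (a truncated Fourier series per axis per
foot), strides repeat with stride-to-stride waveform variability, and a
condition contrast (beginning B vs end E of the walk) shifts the pattern
and scales the variability by controllable amounts. Ground-truth
heel-strike events, the noiseless base cycles at both conditions, and the
average walking speed are returned alongside the signals.

Model summary
-------------
* Base cycle: per axis a(φ) = dc + Σ_k amp_k·sin(2πkφ + phase_k), K=5
  harmonics of the stride frequency by default. With the default 1.25 s
  stride period all harmonics sit at ≤ 4 Hz, below the analysis filter's
  4.5 Hz cutoff.
* The vertical axis carries a fixed gait template — a truncated-sawtooth
  swing-phase burst riding on gravity — phase-anchored so that the
  acceleration-magnitude minimum (the quiet stance moment, i.e. initial
  contact) falls exactly at phase 0. Each subject's individual harmonics
  are re-anchored the same way after sampling, so ground-truth heel
  strikes always coincide with the subject's own pre-swing magnitude
  minimum.
* Between-subject heterogeneity and within-subject stride-to-stride
  variability are both drawn in harmonic-coefficient space with per-(cos,
  sin) standard deviations ∝ 1/k². Random coefficient perturbations give a
  phase-independent pointwise deviation variance, so the within-subject
  deviation profile D̄ ≈ within_noise_sigma and the between/within ratio
  equals the ratio of the two coefficient spreads, in expectation.
* Condition E mixes a unit-RMS harmonic shape orthogonal to the base cycle
  into the pattern: cycle_E = cycle_B + ε·(AC RMS of base)·shape. The true
  pattern change is therefore exactly linear in ε.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ComputationError, ConfigurationError
from .signal_io import FEET, GRAVITY_MS2, AccelerationTimeSeries, EventList

# --- fixed gait template -------------------------------------------------
#
# Vertical-axis wave: a ripple-free asymmetric swing burst, a truncated
# sawtooth with Lanczos-sigma-smoothed harmonic amplitudes
# a_k = sinc(k/5)^0.2 / k for k = 1..4, phase-shifted so its single
# minimum (initial contact) sits at phase 0; the single peak follows at
# 0.21 of a period (≤0.22 after 4.5 Hz two-pass filtering), comfortably
# inside the heel-strike detector's 0.25-period search-back window.
_SAW_SHIFT = 0.8946645  # phase of the wave's minimum before shifting
_SAW_AMPS = (0.9867514275913405, 0.4728999810806849,
             0.2907098759293726, 0.18695443572849754)
_SAW_DEPTH = 1.419710113591454  # |min| of the smoothed wave
# Swing-phase burst amplitude. Large relative to the stride-to-stride noise
# so the stance valley of the magnitude stays a sharp, unambiguous feature:
# initial-contact timing error scales as noise/curvature at the valley.
_AMP_Z = 12.0  # m/s^2

# Small fixed horizontal templates (medio-lateral x, anterior-posterior y),
# (cos, sin) coefficient pairs per harmonic.
_X_COEFFS = [(1.10, 0.60), (-0.45, 0.35), (0.16, -0.12), (0.05, 0.04)]
_Y_COEFFS = [(0.80, -0.50), (0.30, 0.25), (-0.10, 0.08), (0.03, -0.03)]


def _template_cos_sin(n_harmonics: int) -> tuple[np.ndarray, np.ndarray]:
    """Template harmonic coefficients, shape (3, K, 2) [(cos, sin)], and DC."""
    coeffs = np.zeros((3, n_harmonics, 2))
    for k in range(1, min(len(_SAW_AMPS), n_harmonics) + 1):
        ang = 2 * np.pi * k * _SAW_SHIFT
        amp = _AMP_Z * _SAW_AMPS[k - 1]
        coeffs[2, k - 1, 0] = amp * np.sin(ang)  # cos coefficient
        coeffs[2, k - 1, 1] = amp * np.cos(ang)  # sin coefficient
        coeffs[0, k - 1] = _X_COEFFS[k - 1]
        coeffs[1, k - 1] = _Y_COEFFS[k - 1]
    # vertical DC such that the stance minimum reads gravity (stationary
    # foot = 1 g) and the axis never crosses zero, which would fold the
    # magnitude signal and split the stance valley in two
    dc = np.array([0.0, 0.0, GRAVITY_MS2 + _AMP_Z * _SAW_DEPTH])
    return coeffs, dc


def template_ac_rms(n_harmonics: int = 5) -> float:
    """Phase-averaged RMS of the template's 3D AC (gravity-removed) content."""
    coeffs, _ = _template_cos_sin(n_harmonics)
    return float(np.sqrt(np.sum(coeffs**2) / 2.0))


def _coeff_sds(target_rms: float, n_harmonics: int,
               axis_weights=(1 / 3, 1 / 3, 1 / 3)) -> np.ndarray:
    """Per-coefficient sds, shape (3, K, 2), for a target pointwise 3D RMS.

    Each (cos, sin) coefficient of harmonic k gets sd ∝ 1/k²; random
    coefficients then produce a phase-independent pointwise 3D deviation
    variance equal to target_rms², split across axes by ``axis_weights``
    (fractions of variance).
    """
    k = np.arange(1, n_harmonics + 1)
    w = 1.0 / k**2
    per_axis = target_rms * np.sqrt(np.asarray(axis_weights, dtype=float))
    scale = per_axis / np.sqrt(np.sum(w**2))  # (3,)
    sds = np.zeros((3, n_harmonics, 2))
    sds[:, :, 0] = scale[:, None] * w
    sds[:, :, 1] = scale[:, None] * w
    return sds


# Between-subject variance allocation: individual gait signatures are
# expressed mostly in the horizontal accelerations; the vertical swing
# burst is shared across subjects (which also keeps the magnitude profile,
# hence heel-strike detectability, stable across the population).
_BETWEEN_AXIS_WEIGHTS = (0.45, 0.45, 0.10)


def _eval_cos_sin(coeffs: np.ndarray, dc: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Evaluate a harmonic series at phases in [0, 1); returns (n, 3)."""
    n_harm = coeffs.shape[1]
    k = np.arange(1, n_harm + 1)
    ang = 2 * np.pi * np.outer(phases, k)  # (n, K)
    cos, sin = np.cos(ang), np.sin(ang)
    out = cos @ coeffs[:, :, 0].T + sin @ coeffs[:, :, 1].T  # (n, 3)
    return out + dc


def _rotate_phase(coeffs: np.ndarray, shift: float) -> np.ndarray:
    """Coefficients of φ ↦ value(φ + shift)."""
    n_harm = coeffs.shape[1]
    out = np.empty_like(coeffs)
    for ki in range(n_harm):
        ang = 2 * np.pi * (ki + 1) * shift
        c, s = coeffs[:, ki, 0], coeffs[:, ki, 1]
        # cos/sin pair rotates like a 2-vector
        out[:, ki, 0] = c * np.cos(ang) + s * np.sin(ang)
        out[:, ki, 1] = -c * np.sin(ang) + s * np.cos(ang)
    return out


def _cos_sin_to_amp_phase(coeffs: np.ndarray) -> np.ndarray:
    """(cos, sin) -> (amplitude, phase) with value = amp·sin(2πkφ + phase)."""
    c, s = coeffs[..., 0], coeffs[..., 1]
    return np.stack([np.hypot(c, s), np.arctan2(c, s)], axis=-1)


def _amp_phase_to_cos_sin(coeffs: np.ndarray) -> np.ndarray:
    amp, ph = coeffs[..., 0], coeffs[..., 1]
    return np.stack([amp * np.sin(ph), amp * np.cos(ph)], axis=-1)


def _anchor_shift(coeffs: np.ndarray, dc: np.ndarray,
                  search_back: float = 0.25, grid: int = 4000) -> float:
    """Phase of initial contact on a noiseless cycle.

    Mimics the heel-strike convention: the magnitude minimum closest before
    the cycle's dominant magnitude peak, searching back ``search_back`` of a
    period (circularly). Returns the phase to subtract so it lands at 0.
    """
    phi = np.arange(grid) / grid
    mag = np.linalg.norm(_eval_cos_sin(coeffs, dc, phi), axis=1)
    p = int(np.argmax(mag))
    # circular local minima
    left, right = np.roll(mag, 1), np.roll(mag, -1)
    minima = np.nonzero((mag < left) & (mag <= right))[0]
    if minima.size == 0:
        return 0.0
    back = (p - minima) % grid  # circular distance looking backwards
    back[back == 0] = grid
    window = minima[back <= int(search_back * grid)]
    if window.size == 0:
        # fall back to the global magnitude minimum
        return float(np.argmin(mag)) / grid
    # closest preceding minimum
    best = window[np.argmin((p - window) % grid)]
    return float(best) / grid


def _detector_residual(coeffs: np.ndarray, dc: np.ndarray, period: float,
                       rate: float = 400.0, n_strides: int = 8) -> float:
    """Median phase offset of the analysis heel-strike detector on a
    rendered noiseless cycle train, relative to the stride starts.

    Used to refine the anchor so that ground-truth events coincide with
    what the detector reports on the filtered signal (the analytic anchor
    above ignores filtering and peak-separation logic).
    """
    from . import preprocessing as prep

    n_i = max(4, int(round(period * rate)))
    phi = np.arange(n_i) / n_i
    cycle = _eval_cos_sin(coeffs, dc, phi)
    lead = cycle[n_i // 2:]
    samples = np.concatenate([lead] + [cycle] * n_strides, axis=0)
    starts = lead.shape[0] + n_i * np.arange(n_strides)
    ts = AccelerationTimeSeries(samples=samples, rate=rate, foot="left")
    try:
        detected = prep.detect_heel_strikes(prep.lowpass_filter(ts)).indices
    except Exception:
        return 0.0
    offsets = []
    for s in starts:
        d = detected[np.argmin(np.abs(detected - s))] - s
        if abs(d) < 0.4 * n_i:
            offsets.append(d)
    if not offsets:
        return 0.0
    return float(np.median(offsets)) / n_i


# --- domain types --------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of the simulated walking population.

    The source study gives no distributional account of healthy-population
    attractor heterogeneity, so these values are this package's own choice
    of a realistic older-adult population: stride times near 1.25 s,
    preferred speeds near 1.14 m/s (a 6-minute walk distance near 410 m),
    stride-to-stride waveform variability of ~1 m/s² pointwise RMS, and a
    between-subject pattern dispersion roughly three times that.
    """

    n_harmonics: int = 5
    stride_period_mean: float = 1.25  # s
    stride_period_sd: float = 0.06  # s
    speed_mean: float = 1.141  # m/s
    speed_sd: float = 0.179  # m/s
    within_noise_sigma: float = 1.0  # m/s^2, pointwise RMS
    between_spread: float = 0.34  # dimensionless, × template AC RMS (≈3.2 m/s²)
    timing_jitter_per_sigma: float = 0.01  # stride-period CV per (m/s^2)
    sensor_noise_sigma: float = 0.0  # m/s^2 additive white noise

    def __post_init__(self):
        if self.n_harmonics < 1:
            raise ConfigurationError("need at least one harmonic")
        for name in ("stride_period_mean", "speed_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("stride_period_sd", "speed_sd", "within_noise_sigma",
                     "between_spread", "timing_jitter_per_sigma",
                     "sensor_noise_sigma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"{name} must be a finite non-negative scale")


def between_spread_for_dispersion(target_rms: float,
                                  spec: PopulationSpec | None = None) -> float:
    """Spread value giving a population pattern dispersion of target_rms m/s²."""
    spec = spec or PopulationSpec()
    return target_rms / template_ac_rms(spec.n_harmonics)


@dataclass
class ConditionEffect:
    """Contrast between the beginning (B) and end (E) of the walk.

    ``pattern_shift_epsilon`` mixes an orthogonal harmonic shape into the
    base cycle at E (0 = identical pattern, scaled by the base cycle's AC
    RMS); ``variability_factor`` multiplies the stride-to-stride noise at
    E; ``speed_factor`` multiplies the average speed at E. The identity
    effect (0, 1, 1) makes B and E identically distributed.
    """

    pattern_shift_epsilon: float = 0.0
    variability_factor: float = 1.0
    speed_factor: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.pattern_shift_epsilon <= 1.0:
            raise ConfigurationError("pattern_shift_epsilon must be in [0, 1]")
        if self.variability_factor <= 0 or self.speed_factor <= 0:
            raise ConfigurationError("variability and speed factors must be positive")


@dataclass
class SubjectModel:
    """One subject's walking model (both feet)."""

    subject_id: str
    #: per-foot (3, K, 2) arrays of (amplitude m/s², phase rad) per harmonic
    harmonic_coeffs: dict[str, np.ndarray]
    dc: dict[str, np.ndarray]  # per-foot (3,) DC offsets (gravity on z)
    #: per-foot unit-RMS orthogonal shape, (amplitude, phase) form
    ortho_coeffs: dict[str, np.ndarray]
    ac_rms: dict[str, float]  # per-foot AC RMS of the base cycle
    stride_period: float  # s
    within_noise_sigma: float  # m/s^2
    speed: float  # m/s
    timing_jitter_cv: float = 0.0  # stride-period coefficient of variation

    def __post_init__(self):
        if self.stride_period <= 0 or self.speed <= 0:
            raise ConfigurationError("stride_period and speed must be positive")
        if self.within_noise_sigma < 0:
            raise ConfigurationError("within_noise_sigma must be non-negative")

    @property
    def n_harmonics(self) -> int:
        return self.harmonic_coeffs["left"].shape[1]

    def _base_cos_sin(self, foot: str, epsilon: float = 0.0) -> np.ndarray:
        base = _amp_phase_to_cos_sin(self.harmonic_coeffs[foot])
        if epsilon:
            base = base + epsilon * self.ac_rms[foot] * _amp_phase_to_cos_sin(
                self.ortho_coeffs[foot])
        return base

    def evaluate_cycle(self, foot: str, phases: np.ndarray,
                       epsilon: float = 0.0) -> np.ndarray:
        """Noiseless base cycle at the given phases in [0, 1); (n, 3)."""
        return _eval_cos_sin(self._base_cos_sin(foot, epsilon), self.dc[foot],
                             np.asarray(phases, dtype=float))


@dataclass
class SyntheticRecording:
    """Bilateral recording plus every piece of ground truth."""

    recordings: dict[str, AccelerationTimeSeries]
    ground_truth_events: dict[str, EventList]
    #: per foot: {"B": (m, 3), "E": (m, 3)} noiseless cycles on the phase grid
    true_base_cycles: dict[str, dict[str, np.ndarray]]
    subject: SubjectModel
    effect: ConditionEffect
    rate: float
    n_strides_per_condition: int
    n_strides_between: int = 0
    group: str = "healthy"
    assessment: str = "baseline"


# --- operations ----------------------------------------------------------

def generate_subject(seed: int, population_params: PopulationSpec | None = None,
                     subject_id: str | None = None) -> SubjectModel:
    """Draw one subject from the population; deterministic in the seed."""
    spec = population_params or PopulationSpec()
    rng = np.random.default_rng(seed)
    template, dc = _template_cos_sin(spec.n_harmonics)
    spread_rms = spec.between_spread * template_ac_rms(spec.n_harmonics)
    sds = (_coeff_sds(spread_rms, spec.n_harmonics, _BETWEEN_AXIS_WEIGHTS)
           if spread_rms > 0 else None)
    ortho_sds = _coeff_sds(1.0, spec.n_harmonics)

    period = float(np.clip(rng.normal(spec.stride_period_mean, spec.stride_period_sd),
                           0.7 * spec.stride_period_mean,
                           1.5 * spec.stride_period_mean))
    speed = float(max(rng.normal(spec.speed_mean, spec.speed_sd), 0.3))

    coeffs, orthos, rmss, dcs = {}, {}, {}, {}
    for foot in FEET:
        base = template.copy()
        if sds is not None:
            base = base + rng.normal(0.0, sds)
        # re-anchor so the subject's own initial-contact minimum is phase 0:
        # coarse analytic anchor, then refinement against the actual
        # detector on a rendered noiseless, filtered cycle train
        # (refinement at the population's nominal period, so identical
        # coefficient draws anchor identically regardless of subject period)
        base = _rotate_phase(base, _anchor_shift(base, dc))
        for _ in range(3):
            residual = _detector_residual(base, dc, spec.stride_period_mean)
            if abs(residual) * spec.stride_period_mean * 400.0 <= 1.0:
                break
            base = _rotate_phase(base, residual)
        # orthogonal condition-shift shape: Gram-Schmidt then unit RMS,
        # inner product <f, g> = Σ (c_f c_g + s_f s_g)/2 (L2 over phase)
        g = rng.normal(0.0, ortho_sds)
        flat_b, flat_g = base.ravel(), g.ravel()
        denom = flat_b @ flat_b
        if denom > 0:
            flat_g = flat_g - (flat_g @ flat_b) / denom * flat_b
        g = flat_g.reshape(g.shape)
        g_rms = np.sqrt(np.sum(g**2) / 2.0)
        if g_rms == 0:
            raise ComputationError("degenerate orthogonal shape draw")
        g = g / g_rms
        coeffs[foot] = _cos_sin_to_amp_phase(base)
        orthos[foot] = _cos_sin_to_amp_phase(g)
        rmss[foot] = float(np.sqrt(np.sum(base**2) / 2.0))
        dcs[foot] = dc.copy()

    return SubjectModel(
        subject_id=subject_id or f"S{seed}",
        harmonic_coeffs=coeffs, dc=dcs, ortho_coeffs=orthos, ac_rms=rmss,
        stride_period=period, within_noise_sigma=spec.within_noise_sigma,
        speed=speed,
        timing_jitter_cv=spec.timing_jitter_per_sigma * spec.within_noise_sigma,
    )


def synthesize_recording(subject: SubjectModel, effect: ConditionEffect,
                         n_strides_per_condition: int, rate: float = 400.0,
                         seed: int = 0, n_strides_between: int = 0,
                         m: int = 200, sensor_noise_sigma: float = 0.0,
                         lead_in_fraction: float = 0.5) -> SyntheticRecording:
    """Render a recording: n B-strides, an optional ramped middle block,
    and n E-strides, with ground-truth events at every stride start.

    A ``lead_in_fraction`` of a stride of noiseless signal precedes the
    first heel strike (the right foot gets an extra half stride so the feet
    alternate), so the first event is an interior minimum for detectors.
    Stride periods jitter with CV ``subject.timing_jitter_cv`` (clipped at
    ±4 sd); with zero within-noise the recording is exactly periodic.
    """
    if n_strides_per_condition < 2:
        raise ConfigurationError(
            "need at least 2 strides per condition (attractor undefined below)")
    if rate < 50:
        raise ConfigurationError("sampling rate must be at least 50 /s")
    if n_strides_between < 0:
        raise ConfigurationError("n_strides_between must be non-negative")

    rng = np.random.default_rng(seed)
    n_total = 2 * n_strides_per_condition + n_strides_between
    sigma = subject.within_noise_sigma
    noise_sds = (_coeff_sds(sigma, subject.n_harmonics) if sigma > 0 else None)
    jit = subject.timing_jitter_cv

    recordings, events, true_cycles = {}, {}, {}
    tau = np.arange(m) / m
    for fi, foot in enumerate(FEET):
        base_B = subject._base_cos_sin(foot, 0.0)
        base_E = subject._base_cos_sin(foot, effect.pattern_shift_epsilon)
        dc = subject.dc[foot]
        lead = lead_in_fraction + 0.5 * fi  # right foot offset by half a stride
        lead_n = int(round(lead * subject.stride_period * rate))
        chunks = []
        if lead_n > 0:
            phi = 1.0 - lead + np.arange(lead_n) / (subject.stride_period * rate)
            chunks.append(_eval_cos_sin(base_B, dc, np.mod(phi, 1.0)))
        starts = np.empty(n_total, dtype=np.int64)
        pos = lead_n
        for i in range(n_total):
            if i < n_strides_per_condition:
                lam = 0.0
            elif i >= n_strides_per_condition + n_strides_between:
                lam = 1.0
            else:
                lam = (i - n_strides_per_condition + 1) / (n_strides_between + 1)
            coeff = base_B + lam * (base_E - base_B)
            scale = 1.0 + lam * (effect.variability_factor - 1.0)
            if noise_sds is not None:
                coeff = coeff + rng.normal(0.0, noise_sds) * scale
            if jit > 0:
                period_i = subject.stride_period * (
                    1.0 + float(np.clip(rng.normal(0.0, jit), -4 * jit, 4 * jit)))
            else:
                period_i = subject.stride_period
            n_i = max(4, int(round(period_i * rate)))
            phi = np.arange(n_i) / n_i
            chunks.append(_eval_cos_sin(coeff, dc, phi))
            starts[i] = pos
            pos += n_i
        samples = np.concatenate(chunks, axis=0)
        if sensor_noise_sigma > 0:
            samples = samples + rng.normal(0.0, sensor_noise_sigma, samples.shape)
        recordings[foot] = AccelerationTimeSeries(samples=samples, rate=rate,
                                                  foot=foot)
        events[foot] = EventList(indices=starts, foot=foot)
        true_cycles[foot] = {
            "B": _eval_cos_sin(base_B, dc, tau),
            "E": _eval_cos_sin(base_E, dc, tau),
        }

    # equalize lengths across feet (the right foot starts half a stride
    # later) by padding the shorter foot at quiet stance level: the last
    # stride ends at the stance valley, so the pad is nearly continuous,
    # contains no swing peak, and every emitted stride stays complete
    n_max = max(ts.n_samples for ts in recordings.values())
    for foot in FEET:
        ts = recordings[foot]
        short = n_max - ts.n_samples
        if short > 0:
            base_E = subject._base_cos_sin(foot, effect.pattern_shift_epsilon)
            stance = _eval_cos_sin(base_E, subject.dc[foot], np.zeros(1))
            tail = np.repeat(stance, short, axis=0)
            recordings[foot] = AccelerationTimeSeries(
                samples=np.concatenate([ts.samples, tail], axis=0),
                rate=rate, foot=foot)

    return SyntheticRecording(
        recordings=recordings, ground_truth_events=events,
        true_base_cycles=true_cycles, subject=subject, effect=effect,
        rate=rate, n_strides_per_condition=n_strides_per_condition,
        n_strides_between=n_strides_between)


def true_delta_M(subject: SubjectModel, effect: ConditionEffect,
                 m: int = 200) -> float:
    """Exact δM between the noiseless B and E base cycles (both feet).

    Uses the same formula (sqrt mode) as the analysis applied to the
    noiseless cycles, with v the mean of the B and E average speeds; serves
    as ground truth for parameter-recovery experiments.
    """
    from . import attractor as core

    tau = np.arange(m) / m
    atts = {}
    for foot in FEET:
        for cond, eps in (("B", 0.0), ("E", effect.pattern_shift_epsilon)):
            cycle = subject.evaluate_cycle(foot, tau, epsilon=eps)
            atts[(foot, cond)] = core.Attractor(
                mean_cycle=cycle, deviation=np.zeros(m), n_strides=2,
                foot=foot, condition=cond)
    v = subject.speed * (1.0 + effect.speed_factor) / 2.0
    return core.delta_M(atts[("right", "B")], atts[("right", "E")],
                        atts[("left", "B")], atts[("left", "E")], v=v)


def generate_cohort(n_subjects: int, between_spread: float, within_sigma: float,
                    effect: ConditionEffect, seed: int,
                    spec: PopulationSpec | None = None,
                    n_strides_per_condition: int = 15, rate: float = 400.0,
                    n_strides_between: int = 0, m: int = 200):
    """Generate a single-assessment cohort with shared population settings.

    Returns ``(recordings, manifests)`` where manifests carry the ground
    truth speed as the 6-minute walk distance (speed × 360 s). With
    ``between_spread = 0`` every subject shares one base cycle.
    """
    from .signal_io import SessionManifest

    if n_subjects < 2:
        raise ConfigurationError("a cohort needs at least 2 subjects")
    base_spec = spec or PopulationSpec()
    cohort_spec = dataclasses.replace(base_spec, between_spread=between_spread,
                                      within_noise_sigma=within_sigma)
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    recording_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    recordings, manifests = [], []
    for i in range(n_subjects):
        subject = generate_subject(int(subject_seeds[i]), cohort_spec,
                                   subject_id=f"S{i:03d}")
        rec = synthesize_recording(subject, effect, n_strides_per_condition,
                                   rate=rate, seed=int(recording_seeds[i]),
                                   n_strides_between=n_strides_between, m=m)
        recordings.append(rec)
        manifests.append(SessionManifest(subject_id=subject.subject_id,
                                         group="healthy", assessment="baseline",
                                         six_mwd=subject.speed * 360.0))
    return recordings, manifests


def insert_turn_segment(recording: SyntheticRecording, stride_index: int,
                        seed: int = 0, amplitude: float = 2.0) -> SyntheticRecording:
    """Overwrite one stride with irregular low-amplitude turning motion.

    Robustness-test helper (turns are not simulated by default: the
    analysis windows cover straight walkway passes). The corrupted stride
    keeps its heel-strike markers, so downstream outlier guards — not the
    generator — must handle it.
    """
    rng = np.random.default_rng(seed)
    out_recordings = {}
    for foot in FEET:
        ts = recording.recordings[foot]
        idx = recording.ground_truth_events[foot].indices
        if not 0 <= stride_index < len(idx) - 1:
            raise ConfigurationError("stride_index out of range")
        a, b = int(idx[stride_index]), int(idx[stride_index + 1])
        samples = ts.samples.copy()
        n = b - a
        t = np.arange(n) / n
        wobble = amplitude * np.column_stack([
            np.sin(2 * np.pi * (2.3 * t + rng.uniform(0, 1))),
            np.sin(2 * np.pi * (1.7 * t + rng.uniform(0, 1))),
            np.sin(2 * np.pi * (2.9 * t + rng.uniform(0, 1))),
        ])
        samples[a:b] = recording.subject.dc[foot] + wobble
        out_recordings[foot] = AccelerationTimeSeries(samples=samples,
                                                      rate=ts.rate, foot=foot)
    return dataclasses.replace(recording, recordings=out_recordings)


def jitter_events(events: EventList, sd_samples: float, seed: int = 0) -> EventList:
    """Ground-truth events with Gaussian timing jitter, for detector and
    annotation-robustness tests (ground truth itself stays exact)."""
    rng = np.random.default_rng(seed)
    idx = events.indices + np.round(rng.normal(0, sd_samples,
                                               events.indices.size)).astype(np.int64)
    idx = np.sort(idx)
    idx = idx[np.concatenate([[True], np.diff(idx) > 0])]
    return EventList(indices=idx[idx >= 0], foot=events.foot)


# Study-sized cohort defaults: group sizes, walking speeds and their change
# after treatment, and the disability covariate follow the reported healthy
# (n=24) and patient (n=19, three assessments) samples; the per-group
# condition effects are this package's choice of a contrast in which
# patients change pattern and variability during the walk more than
# healthy subjects do.
STUDY_EFFECTS = {
    ("healthy", "baseline"): ConditionEffect(0.05, 1.05, 1.0),
    ("patient", "baseline"): ConditionEffect(0.12, 1.35, 1.0),
    ("patient", "week10"): ConditionEffect(0.14, 1.45, 1.0),
    ("patient", "month12"): ConditionEffect(0.14, 1.45, 1.0),
}
_PATIENT_SPEED = {"baseline": (1.004, 0.280), "week10": 0.100, "month12": 0.108}
_ODI = {"baseline": (27.9, 16.9), "week10": (8.5, 13.0), "month12": (11.4, 13.5)}


def generate_study_cohort(seed: int, n_healthy: int = 24, n_patients: int = 19,
                          spec: PopulationSpec | None = None,
                          duration_s: float = 360.0, rate: float = 400.0,
                          m: int = 200, walkway_length: float = 30.0,
                          effects: dict | None = None):
    """Full synthetic study: healthy subjects once, patients at three
    assessments, each a 6-minute walk.

    Returns a list of ``(SyntheticRecording, SessionManifest)`` sessions.
    """
    from .signal_io import SessionManifest

    base_spec = spec or PopulationSpec()
    effects = effects or STUDY_EFFECTS
    rng = np.random.default_rng(seed)
    sessions = []

    def _n_strides(speed, period):
        n_cond = int(np.ceil(1.4 * walkway_length / (speed * period)))
        total = max(int(round(duration_s / period)), 2 * n_cond + 1)
        return n_cond, total - 2 * n_cond

    for i in range(n_healthy):
        subject = generate_subject(int(rng.integers(0, 2**31 - 1)), base_spec,
                                   subject_id=f"H{i:03d}")
        n_cond, n_mid = _n_strides(subject.speed, subject.stride_period)
        rec = synthesize_recording(subject, effects[("healthy", "baseline")],
                                   n_cond, rate=rate,
                                   seed=int(rng.integers(0, 2**31 - 1)),
                                   n_strides_between=n_mid, m=m)
        rec.group, rec.assessment = "healthy", "baseline"
        sessions.append((rec, SessionManifest(
            subject_id=subject.subject_id, group="healthy",
            assessment="baseline", walkway_length=walkway_length,
            six_mwd=subject.speed * 360.0)))

    pat_spec = dataclasses.replace(
        base_spec, speed_mean=_PATIENT_SPEED["baseline"][0],
        speed_sd=_PATIENT_SPEED["baseline"][1])
    for i in range(n_patients):
        subject = generate_subject(int(rng.integers(0, 2**31 - 1)), pat_spec,
                                   subject_id=f"P{i:03d}")
        base_speed = max(subject.speed, 0.4)
        for assessment in ("baseline", "week10", "month12"):
            if assessment == "baseline":
                speed = base_speed
            else:
                speed = max(base_speed + _PATIENT_SPEED[assessment]
                            + float(rng.normal(0.0, 0.05)), 0.4)
            odi_mean, odi_sd = _ODI[assessment]
            odi = float(np.clip(rng.normal(odi_mean, odi_sd), 0.0, 100.0))
            subj = dataclasses.replace(subject, speed=speed)
            n_cond, n_mid = _n_strides(speed, subj.stride_period)
            rec = synthesize_recording(subj, effects[("patient", assessment)],
                                       n_cond, rate=rate,
                                       seed=int(rng.integers(0, 2**31 - 1)),
                                       n_strides_between=n_mid, m=m)
            rec.group, rec.assessment = "patient", assessment
            sessions.append((rec, SessionManifest(
                subject_id=subj.subject_id, group="patient",
                assessment=assessment, walkway_length=walkway_length,
                six_mwd=speed * 360.0, odi_percent=odi)))
    return sessions
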