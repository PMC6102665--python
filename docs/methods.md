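# Methods

This note documents the analysis model, the synthetic-data model, the
numerical choices, and the limits of what the test suite demonstrates.

## Analysis pipeline

Stage order for one subject is fixed: read → low-pass filter → heel-strike
events → window selection → stride cutting → time normalization →
attractors → δM/δD/δF.

**Filtering.** 4th-order Butterworth low-pass at 4.5 Hz (both
configurable), applied forward–backward (`scipy.signal.filtfilt`).
Zero-phase filtering doubles the attenuation (amplitude gain
1/(1+(f/f_c)^8)) but introduces no group delay, so events detected on the
filtered signal align with the raw signal. Filtering precedes stride
cutting: the filter sees one continuous record and no per-stride edge
transients.

**Heel-strike detection.** Accelerometer-only, on the filtered signal:
(1) the dominant stride period is the autocorrelation peak of the
acceleration magnitude in the lag range 0.5–2.5 s; (2) swing-phase peaks
are local maxima of the magnitude with minimum separation 0.7·period and
prominence ≥ 10% of the magnitude range (the prominence guard keeps
sub-0.1 m/s² ripples around quiet standing segments from registering as
swing peaks); (3) each event is the closest local minimum preceding a
peak within 0.25·period — physically, the quiet stance moment just before
the swing burst, i.e. initial contact. A recording with no
autocorrelation peak in range raises a detection error so the caller can
fall back to an annotation file; annotations, when supplied, take
precedence over detection.

**Windows.** The analysis compares the first and last walkway-length
(default 30 m) stretches of the walk. Distance is accrued as elapsed
time × nominal speed, the nominal speed being the 6-minute walk distance
divided by 360 s; per-pass timing hardware is not assumed. Each window's
average speed v is walkway length / elapsed time, and the v entering δM
is the mean of the B- and E-window speeds over both feet. Windows that
would overlap (too-short recording) are an error.

**Stride cutting and normalization.** Stride i spans samples
[event_i, event_{i+1}) (0-based, half-open everywhere). Strides shorter
than 0.4× or longer than 1.6× the within-window median length are
discarded — a guard against corrupted cycles such as hallway turns; the
discarded count is reported per window and foot. Surviving strides are
resampled to m = 200 phase points (configurable; the protocol itself does
not fix m) by cubic splines per axis over normalized phase [0, 1), the
first point anchored at heel strike. The final sub-sample of phase is
cubic extrapolation, benign for band-limited cycles.

**Attractor and metrics.** The attractor is the pointwise 3D mean of the
normalized cycles; D̄(τ_j) is the pointwise RMS Euclidean distance of
cycles from it (an RMS rather than an ad-hoc spread so that it is
directly comparable to a standard deviation; the summary statistic
reported per subject is the RMS of D̄ over the cycle). δM, δD, δF are as
in the README. Both δM and δD are implemented with and without the outer
square root (`sqrt_mode`); the rooted form is the default because only it
makes δM invariant under a joint rescaling of accelerations and speed —
the natural requirement for a speed-corrected pattern distance. The
attractor equation's residual term (the deviation of each individual
cycle from the mean at the matched phase) averages out by construction
and is dropped. The motor-fatigue cut-off δF = 4 from earlier
multiple-sclerosis work is documented here for context but deliberately
not implemented as a classifier.

**Reference attractor.** The healthy-group reference is the pointwise
mean of the individual B-condition attractors (heel-strike aligned on the
common phase grid; no time warping or amplitude normalization). The
between-subject dispersion is the RMS over subjects of each subject's RMS
distance from the reference — the same functional form as the
within-subject summary, so the between/within ratio is a pure number. An
optional speed-correction flag divides each attractor by the subject's v
before averaging (default off), mirroring the secondary check that
between-subject pattern differences survive speed normalization.

**Group statistics.** Shapiro–Wilk normality screening (scipy); our own
Mann–Whitney U between healthy and patient groups — exact two-sided p by
enumeration of rank configurations (midranks for ties; p = probability of
a U at least as far from its null mean as observed) when the combined
sample is ≤ 16, and a tie- plus continuity-corrected normal approximation
otherwise (the study-sized 24 vs 19 comparison uses the approximation;
tests exercise the exact branch); one-way repeated-measures ANOVA across
the three patient assessments with (k−1, (n−1)(k−1)) degrees of freedom,
listwise deletion of incomplete cases (count reported) and no sphericity
correction (flagged in the output; a Greenhouse–Geisser option was
considered and left out to match the plain within-subject F); Bonferroni
post-hoc pairwise comparisons implemented as paired t-tests with p
multiplied by the number of pairs and capped at 1. Covariate adjustment
(age, BMI) is out of scope. Cohort runs use a partial-failure policy:
a failing subject is skipped and reported, not fatal.

## Synthetic-data model

The generator produces the statistical structure the analysis assumes,
with exact ground truth, not biomechanically detailed signals.

**Base cycle.** Per axis and foot, a truncated Fourier series in stride
phase: dc + Σ_k amp_k·sin(2πkφ + phase_k), K = 5 harmonics by default.
With the default stride period of 1.25 s (a slowish older-adult cadence
of 96 steps/min) all harmonics sit at ≤ 4 Hz, inside the 4.5 Hz analysis
passband. The vertical axis carries a fixed swing-burst template — a
ripple-free smoothed-sawtooth wave (harmonic amplitudes
sinc(k/5)^0.2 / k, amplitude scale 12 m/s²) whose single sharp minimum is
the stance valley and whose single peak follows 0.21 of a period later.
The vertical DC offset puts the stance minimum at 1 g (a stationary foot
measures gravity) and keeps the axis positive, so the magnitude signal
mirrors the vertical axis. The burst is deliberately large relative to
the stride-to-stride noise: the timing error of the detected initial
contact scales as noise over valley curvature, and this scale keeps it
well inside the ±25 ms matching tolerance. Horizontal axes carry small
fixed templates.

**Heterogeneity and variability.** Both between-subject individuality
and within-subject stride-to-stride variability are Gaussian draws in
harmonic-coefficient space with per-(cos, sin) standard deviations ∝ 1/k².
Random coefficient perturbations of this form give a *phase-independent*
pointwise deviation variance, so the within-subject deviation profile is
flat at ≈ `within_noise_sigma` (default 1.0 m/s²) and the expected
between/within ratio equals the ratio of the two coefficient spreads —
the calibration the variability-decomposition experiment relies on. The
1/k² decay also keeps the energy where the filter passband is flat
(passband bias on δM recovery < 0.1%, computed analytically from the
two-pass gains). Between-subject variance is split (0.45, 0.45, 0.10)
across the (x, y, z) axes: individual signatures are expressed mostly in
the horizontal accelerations, which keeps the magnitude profile — and
hence heel-strike detectability — stable across the population. The
default between-subject spread (0.34 × the template's AC RMS ≈ 3.2 m/s²)
makes the population dispersion roughly three times the within-subject
level, the regime reported for healthy older adults. Each subject's
cycle is re-anchored after sampling so that phase 0 is the initial
contact the detector itself would report on the noiseless filtered
cycle; ground-truth events therefore mark exactly the feature the
detector estimates.

**Recordings.** A recording is n B-strides, an optional middle block
whose effect ramps linearly from B to E, and n E-strides, with the right
foot offset by half a stride and a half-stride noiseless lead-in before
the first heel strike (so the first event is an interior minimum). Stride
periods jitter with a coefficient of variation of 0.01 per unit of
`within_noise_sigma`, clipped at ±4 sd — zero noise means an exactly
periodic, bit-reproducible signal. Feet are length-equalized by padding
the shorter record at quiet stance level, never by truncation (which
could chop the final swing peak). Additive white sensor noise is a
separate, default-zero term. The condition contrast mixes
ε · (AC RMS of the base cycle) of a unit-RMS harmonic shape *orthogonal*
to the base cycle into the E-condition pattern — so the true δM is
exactly linear in ε — and multiplies the stride-to-stride noise by
`variability_factor`. `true_delta_M` evaluates the same δM formula on the
noiseless cycles, providing the recovery ground truth.

**Study-sized cohort.** 24 healthy subjects (one assessment) and 19
patients (baseline, 10-week, 12-month), 6-minute walks at 400 Hz. Walking
speeds, their post-treatment improvements and the disability covariate
follow the reported group statistics (healthy 1.141 ± 0.179 m/s; patients
1.004 ± 0.280 m/s at baseline, improving by ≈ 0.10 m/s after treatment);
the per-group condition effects (healthy ε = 0.05, variability ×1.05;
patients ε = 0.12–0.14, ×1.35–1.45) are this package's choice of a
contrast in which patients change pattern and variability during the walk
distinctly more than controls — the direction, not the magnitudes, of the
reported findings.

**What the generator does not emulate.** No gyroscope/magnetometer
channels, no sensor drift or bias, no ground-reaction mechanics, no
fatigue drift within a condition, no turns by default (an explicit
turn-segment inserter exists for robustness tests), and speed changes do
not alter the cycle shape or cadence. Passing tests therefore show the
*pipeline* is correct and well calibrated under the assumed structure
(quasi-periodicity, coefficient-space noise, heel-strike-anchored
phase), not that real pathological gait satisfies those assumptions.

## Numerical choices and degenerate inputs

- Sample indices 0-based, intervals half-open; events strictly increasing
  and validated on read.
- Attractors require ≥ 2 cycles with identical m, foot and condition;
  mixed inputs raise errors rather than broadcasting.
- Unit conversion (g → m/s², 1 g = 9.80665 m/s²) happens exactly once at
  read time, tracked by a flag.
- Exact Mann–Whitney null distributions are cached per (n_a, n_b) for the
  tie-free case; tied samples are enumerated per call.
- A constant signal raises in detection (no periodicity) and in
  Shapiro–Wilk (W undefined); an RM-ANOVA with zero error mean square
  returns F = 0 when the treatment effect is also zero.
- End-to-end runs are deterministic given config and seed; every output
  carries the configuration echo and its hash. Full-study problem sizes
  (81 six-minute sessions at 400 Hz) analyze in well under a minute per
  cohort on one CPU, so validation re-runs the whole pipeline rather than
  caching intermediates.

## Known limitations

- The heel-strike detector is accelerometer-only and tuned to walking
  (period 0.5–2.5 s); running or severely shuffling gait may need
  different extrema logic.
- Window distance accounting assumes steady average speed; with pass
  timing hardware the elapsed-time × nominal-speed model could be
  replaced by measured distances (the seam is `select_windows`).
- The vendor CSV schema of commercial IMU systems is not documented; the
  dialect layer covers delimiter/column/unit variation but real exports
  may need a custom mapping.
- δM depends on v, so speed measurement error propagates into the
  pattern metric; δD does not share this dependence.
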