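"""Reading and writing recordings, event annotations, manifests and result tables.

All interchange formats are plain text: CSV for recordings, events,
manifests and tables; JSON for structured results and config echoes.
The recording CSV dialect is configurable because inertial-sensor vendors
export in undocumented, mutually incompatible schemas; the default dialect
is the one the synthetic generator writes (one row per sample, six columns,
left foot then right foot, axes x/y/z).

Sample indices are 0-based and intervals half-open ``[start, end)``
throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError, ValidationError

#: Standard gravity, used for the g -> m/s^2 conversion.
GRAVITY_MS2 = 9.80665

FEET = ("left", "right")


@dataclass
class CsvDialect:
    """Column layout and unit declaration of a recording CSV.

    ``columns`` maps each foot to its three axis column names, in x/y/z
    order. ``units_in`` declares the units on disk; values are always
    converted to m/s^2 on read (1 g = 9.80665 m/s^2) and the conversion is
    applied exactly once, tracked by the ``units_in`` flag on the series.
    """

    delimiter: str = ","
    units_in: str = "m/s2"  # "m/s2" or "g"
    rate: float = 400.0
    columns: dict[str, tuple[str, str, str]] = field(
        default_factory=lambda: {
            "left": ("left_ax", "left_ay", "left_az"),
            "right": ("right_ax", "right_ay", "right_az"),
        }
    )

    def __post_init__(self):
        if self.units_in not in ("m/s2", "g"):
            raise ConfigurationError(f"unknown units: {self.units_in!r}")
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")


@dataclass
class AccelerationTimeSeries:
    """One sensor's uniformly sampled triaxial acceleration record.

    ``samples`` is an (n, 3) float array in m/s^2. No timestamps are stored;
    the sampling rate is metadata (the analysis is phase-based).
    """

    samples: np.ndarray
    rate: float
    foot: str
    units_in: str = "m/s2"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("acceleration samples must be finite")
        if self.foot not in FEET:
            raise ValidationError(f"foot must be one of {FEET}, got {self.foot!r}")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EventList:
    """Strictly increasing heel-strike sample indices for one foot."""

    indices: np.ndarray
    foot: str

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValidationError("event indices must be one-dimensional")
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValidationError("event indices must be strictly increasing")
        if self.indices.size and self.indices[0] < 0:
            raise ValidationError("event indices must be non-negative")
        if self.foot not in FEET:
            raise ValidationError(f"foot must be one of {FEET}, got {self.foot!r}")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SessionManifest:
    """Metadata for one gait-analysis session (one subject, one assessment)."""

    subject_id: str
    group: str = "healthy"  # "healthy" or "patient"
    assessment: str = "baseline"  # "baseline", "week10", "month12"
    walkway_length: float = 30.0
    six_mwd: float | None = None  # 6-minute walk distance, metres
    odi_percent: float | None = None  # opaque covariate, 0-100

    def __post_init__(self):
        if self.walkway_length <= 0:
            raise ValidationError("walkway_length must be positive")
        if self.group not in ("healthy", "patient"):
            raise ValidationError(f"unknown group {self.group!r}")


def read_recording(path, dialect: CsvDialect | None = None) -> dict[str, AccelerationTimeSeries]:
    """Read a recording CSV into per-foot series, converting to m/s^2.

    Raises :class:`ParseError` with a 1-based file line number for missing
    columns, non-numeric cells, non-finite values, or inconsistent row
    counts across feet.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse {path}: {exc}") from None

    wanted = [c for cols in dialect.columns.values() for c in cols]
    missing = [c for c in wanted if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)

    try:
        # numpy's parser is correctly rounded, giving exact round trips
        numeric = frame[wanted].astype(np.float64)
    except (TypeError, ValueError):
        numeric = frame[wanted].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        # +2: header line plus 1-based counting
        raise ParseError(f"{path}: non-numeric or non-finite value", line=row + 2)

    scale = GRAVITY_MS2 if dialect.units_in == "g" else 1.0
    out = {}
    for foot, cols in dialect.columns.items():
        out[foot] = AccelerationTimeSeries(
            samples=numeric[list(cols)].to_numpy(dtype=float) * scale,
            rate=dialect.rate,
            foot=foot,
            units_in=dialect.units_in,
        )
    return out


def write_recording(path, recordings: dict[str, AccelerationTimeSeries],
                    dialect: CsvDialect | None = None) -> None:
    """Write per-foot series to one CSV in the given dialect.

    Values are written in the dialect's declared units at full double
    precision, so ``read_recording`` round-trips exactly.
    """
    dialect = dialect or CsvDialect()
    n = {foot: ts.n_samples for foot, ts in recordings.items()}
    if len(set(n.values())) > 1:
        raise ValidationError(f"feet have different lengths: {n}")
    scale = 1.0 / GRAVITY_MS2 if dialect.units_in == "g" else 1.0
    data = {}
    for foot, cols in dialect.columns.items():
        if foot not in recordings:
            raise ValidationError(f"missing foot {foot!r}")
        for j, col in enumerate(cols):
            data[col] = recordings[foot].samples[:, j] * scale
    pd.DataFrame(data).to_csv(path, sep=dialect.delimiter, index=False,
                              float_format="%.17g")


def read_events(path) -> dict[str, EventList]:
    """Read per-foot heel-strike annotations (columns ``left``, ``right``).

    Feet may have different event counts; shorter columns are padded with
    blanks on disk. An empty file yields empty event lists — downstream
    stages decide whether that is sufficient.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame()
    out = {}
    for foot in FEET:
        if foot in frame.columns:
            vals = pd.to_numeric(frame[foot], errors="coerce").dropna()
            if not np.allclose(vals, np.round(vals)):
                raise ParseError(f"{path}: non-integer event index in {foot!r}")
            idx = vals.to_numpy(dtype=np.int64)
        else:
            idx = np.empty(0, dtype=np.int64)
        out[foot] = EventList(indices=idx, foot=foot)
    return out


def write_events(path, events: dict[str, EventList]) -> None:
    series = {foot: pd.Series(ev.indices) for foot, ev in events.items()}
    pd.concat(series, axis=1).to_csv(path, index=False)


def read_manifest(path) -> list[SessionManifest]:
    """Read a cohort manifest CSV (one row per subject-assessment)."""
    frame = pd.read_csv(path)
    required = {"subject_id", "group", "assessment"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}", line=1)
    out = []
    for _, row in frame.iterrows():
        out.append(SessionManifest(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            assessment=str(row["assessment"]),
            walkway_length=float(row.get("walkway_length", 30.0) or 30.0),
            six_mwd=_opt_float(row.get("six_mwd")),
            odi_percent=_opt_float(row.get("odi_percent")),
        ))
    return out


def _opt_float(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def manifest_frame(manifests: list[SessionManifest]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in manifests])


def write_results(cohort_result, out_dir) -> dict[str, Path]:
    """Write a cohort result as tidy CSV tables plus a JSON summary.

    Emits ``subjects.csv`` (one row per subject-assessment with the
    comparison metrics), ``groups.csv`` (per-group summaries), ``stats.csv``
    (test statistics and p-values), ``reference_attractor.csv`` and
    ``results.json`` (everything, plus the config echo). Values survive a
    CSV round trip to 12 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, frame: pd.DataFrame):
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.12g")
        paths[name] = p

    _write("subjects", cohort_result.subject_table)
    _write("groups", cohort_result.group_table)
    _write("stats", cohort_result.stats_table)
    if cohort_result.reference_table is not None:
        _write("reference_attractor", cohort_result.reference_table)

    payload = {
        "config": cohort_result.config_echo,
        "config_hash": cohort_result.config_hash,
        "variability": cohort_result.variability,
        "failures": cohort_result.failures,
        "log": cohort_result.log,
        "subjects": json.loads(
            cohort_result.subject_table.to_json(orient="records", double_precision=15) or "[]"),
        "groups": json.loads(
            cohort_result.group_table.to_json(orient="records", double_precision=15) or "[]"),
        "stats": json.loads(
            cohort_result.stats_table.to_json(orient="records", double_precision=15) or "[]"),
    }
    jpath = out_dir / "results.json"
    jpath.write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["json"] = jpath
    return paths
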