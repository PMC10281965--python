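"""Data model, file I/O and validation for stylus pen recordings.

A recording is one participant's single-stroke tracing of one guide shape
on a tablet: an ordered series of samples ``(t, x, y, pressure)``.
Coordinates are screen points with the origin at the top-left and y
growing downward; pressure is in device units on ``[0, 4.166667]``;
timestamps are seconds since first pen contact, nominally at 120
samples/second.

On disk a recording is a CSV (``t,x,y,pressure``) plus a JSON metadata
sidecar sharing the basename (``<name>.meta.json``). A cohort is a
directory of recordings with a ``manifest.csv`` indexing them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Device pressure ceiling of the tablet stylus (device units).
DEVICE_PRESSURE_MAX = 4.166667

#: Nominal tablet frame rate (samples per second).
DEVICE_FRAME_RATE = 120.0

SHAPES = ("spiral", "square", "triangular")
GROUPS = ("nonCM", "CM")

_META_FIELDS = ("participant_id", "shape", "group", "age", "sex",
                "joa_score", "nominal_rate", "seed")


class ValidationError(ValueError):
    """A recording violated a structural invariant.

    Attributes
    ----------
    rule : str
        Short identifier of the first violated rule.
    row : int or None
        Zero-based row index of the offending sample, when applicable.
    source : str or None
        File the recording was read from, when applicable.
    """

    def __init__(self, rule: str, message: str, row: int | None = None,
                 source: str | None = None):
        self.rule = rule
        self.row = row
        self.source = source
        prefix = f"{source}: " if source else ""
        suffix = f" (row {row})" if row is not None else ""
        super().__init__(f"{prefix}{message}{suffix}")


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    message: str
    row: int | None = None


@dataclass
class PenRecording:
    """One single-stroke tracing: parallel sample arrays plus metadata."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    participant_id: str
    shape: str
    group: str | None = None
    nominal_rate: float = DEVICE_FRAME_RATE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Elapsed drawing time, last minus first timestamp (seconds)."""
        return float(self.t[-1] - self.t[0])

    def equals(self, other: "PenRecording", atol: float = 0.0) -> bool:
        return (
            self.participant_id == other.participant_id
            and self.shape == other.shape
            and self.group == other.group
            and self.t.size == other.t.size
            and np.allclose(self.t, other.t, atol=atol, rtol=0)
            and np.allclose(self.x, other.x, atol=atol, rtol=0)
            and np.allclose(self.y, other.y, atol=atol, rtol=0)
            and np.allclose(self.pressure, other.pressure, atol=atol, rtol=0)
        )


def validate_recording(rec: PenRecording,
                       gap_tolerance: float | None = None
                       ) -> list[ValidationIssue]:
    """Check a recording against the structural invariants.

    Returns a list of issues (empty when valid). A gap between
    consecutive samples larger than ``gap_tolerance`` (default three
    nominal sample periods) flags the recording as multi-stroke: the
    participants were instructed to trace in one stroke, so a long gap
    indicates a pen lift.
    """
    if gap_tolerance is None:
        gap_tolerance = 3.0 / rec.nominal_rate
    issues: list[ValidationIssue] = []
    if rec.n_samples < 2:
        issues.append(ValidationIssue("min_samples",
                                      f"{rec.n_samples} sample(s); need >= 2"))
        return issues
    for name, arr in (("t", rec.t), ("x", rec.x), ("y", rec.y),
                      ("pressure", rec.pressure)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            issues.append(ValidationIssue(
                "finite", f"non-finite {name}", int(bad[0])))
    if np.isfinite(rec.t).all():
        if rec.t[0] < 0:
            issues.append(ValidationIssue("t_nonnegative",
                                          "negative timestamp", 0))
        dt = np.diff(rec.t)
        nonmono = np.flatnonzero(dt <= 0)
        if nonmono.size:
            issues.append(ValidationIssue(
                "t_increasing", "timestamps not strictly increasing",
                int(nonmono[0]) + 1))
        gaps = np.flatnonzero(dt > gap_tolerance)
        if gaps.size and not rec.meta.get("multi_stroke", False):
            issues.append(ValidationIssue(
                "multi_stroke",
                f"inter-sample gap {dt[gaps[0]]:.4f} s exceeds tolerance "
                f"{gap_tolerance:.4f} s", int(gaps[0]) + 1))
    if np.isfinite(rec.pressure).all():
        low = np.flatnonzero(rec.pressure < 0)
        high = np.flatnonzero(rec.pressure > DEVICE_PRESSURE_MAX)
        if low.size:
            issues.append(ValidationIssue(
                "pressure_range", "pressure below 0", int(low[0])))
        if high.size:
            issues.append(ValidationIssue(
                "pressure_range",
                f"pressure above device maximum {DEVICE_PRESSURE_MAX}",
                int(high[0])))
    if rec.shape not in SHAPES:
        issues.append(ValidationIssue("shape", f"unknown shape {rec.shape!r}"))
    if rec.group is not None and rec.group not in GROUPS:
        issues.append(ValidationIssue("group", f"unknown group {rec.group!r}"))
    return issues


def assert_valid(rec: PenRecording, source: str | None = None,
                 gap_tolerance: float | None = None) -> None:
    """Raise :class:`ValidationError` on the first violated rule."""
    issues = validate_recording(rec, gap_tolerance=gap_tolerance)
    if issues:
        first = issues[0]
        raise ValidationError(first.rule, first.message, first.row, source)


def keep_longest_stroke(rec: PenRecording,
                        gap_tolerance: float | None = None) -> PenRecording:
    """Return the longest contiguous segment of a multi-stroke recording.

    Timestamps of the retained segment are re-zeroed to first contact.
    """
    if gap_tolerance is None:
        gap_tolerance = 3.0 / rec.nominal_rate
    breaks = np.flatnonzero(np.diff(rec.t) > gap_tolerance)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [rec.n_samples]))
    seg = int(np.argmax(ends - starts))
    sl = slice(starts[seg], ends[seg])
    out = dataclasses.replace(
        rec, t=rec.t[sl] - rec.t[sl][0], x=rec.x[sl], y=rec.y[sl],
        pressure=rec.pressure[sl])
    out.meta = dict(rec.meta)
    out.meta["kept_longest_stroke"] = True
    return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") \
        if path.suffix == ".csv" else Path(str(path) + ".meta.json")


def read_recording(path: str | Path, validate: bool = True) -> PenRecording:
    """Read a recording CSV and its JSON metadata sidecar.

    Raises :class:`ValidationError` naming the file and offending row on
    missing columns, non-increasing timestamps, out-of-range pressure or
    fewer than 2 samples.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["t", "x", "y", "pressure"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError("columns",
                              f"missing column(s) {missing}", source=str(path))
    meta_path = _sidecar_path(path)
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    extra = {k: v for k, v in meta.items()
             if k not in ("participant_id", "shape", "group", "nominal_rate")}
    rec = PenRecording(
        t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy(),
        pressure=df["pressure"].to_numpy(),
        participant_id=str(meta.get("participant_id", path.stem)),
        shape=meta.get("shape", "spiral"),
        group=meta.get("group"),
        nominal_rate=float(meta.get("nominal_rate", DEVICE_FRAME_RATE)),
        meta=extra,
    )
    if validate:
        assert_valid(rec, source=str(path))
    return rec


def write_recording(rec: PenRecording, path: str | Path) -> Path:
    """Write a recording CSV plus sidecar; round-trips at >= 12 significant
    digits. Returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": rec.t, "x": rec.x, "y": rec.y,
                       "pressure": rec.pressure})
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {"participant_id": rec.participant_id, "shape": rec.shape,
            "nominal_rate": rec.nominal_rate}
    if rec.group is not None:
        meta["group"] = rec.group
    for k, v in rec.meta.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        meta[k] = v
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


@dataclass
class Cohort:
    """A collection of recordings plus per-participant metadata.

    ``participants`` has one row per participant with columns
    ``participant_id, group, age, sex`` and ``joa_score`` (severity score
    on 0-17, CM participants only; NaN otherwise). Each
    ``(participant, shape)`` pair appears at most once — the study design
    keeps only the third, non-practice tracing.
    """

    recordings: list[PenRecording]
    participants: pd.DataFrame

    def __post_init__(self):
        seen = set()
        for rec in self.recordings:
            key = (rec.participant_id, rec.shape)
            if key in seen:
                raise ValidationError(
                    "duplicate", f"duplicate recording for {key}")
            seen.add(key)
        if "joa_score" in self.participants.columns:
            cm = self.participants[self.participants["group"] == "CM"]
            joa = cm["joa_score"].to_numpy(dtype=float)
            if np.isnan(joa).any() or (joa < 0).any() or (joa > 17).any():
                raise ValidationError(
                    "joa_range", "every CM participant needs a severity "
                    "score in [0, 17]")

    def __len__(self) -> int:
        return len(self.recordings)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write all recordings plus a ``manifest.csv``; returns the manifest
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    pmeta = cohort.participants.set_index("participant_id")
    for rec in cohort.recordings:
        fname = f"{rec.participant_id}_{rec.shape}.csv"
        write_recording(rec, out_dir / fname)
        row = {"path": fname, "participant_id": rec.participant_id,
               "shape": rec.shape, "group": rec.group}
        if rec.participant_id in pmeta.index:
            for col in ("age", "sex", "joa_score"):
                if col in pmeta.columns:
                    row[col] = pmeta.loc[rec.participant_id, col]
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(cohort_dir: str | Path, validate: bool = True,
                keep_longest: bool = False) -> Cohort:
    """Load a cohort directory via its manifest.

    Invalid recordings are skipped with a logged warning unless
    ``keep_longest`` salvages multi-stroke ones by keeping the longest
    contiguous segment.
    """
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    recordings = []
    for _, row in manifest.iterrows():
        path = cohort_dir / row["path"]
        try:
            rec = read_recording(path, validate=False)
            issues = validate_recording(rec) if validate else []
            if issues and keep_longest and all(
                    i.rule == "multi_stroke" for i in issues):
                rec = keep_longest_stroke(rec)
                issues = validate_recording(rec)
            if issues:
                raise ValidationError(issues[0].rule, issues[0].message,
                                      issues[0].row, str(path))
            recordings.append(rec)
        except (ValidationError, OSError, pd.errors.ParserError) as exc:
            logger.warning("skipping %s: %s", path, exc)
    pcols = [c for c in ("participant_id", "group", "age", "sex", "joa_score")
             if c in manifest.columns]
    participants = manifest[pcols].drop_duplicates("participant_id")
    participants = participants.reset_index(drop=True)
    return Cohort(recordings=recordings, participants=participants)
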