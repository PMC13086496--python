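"""Encoder heading streams: data model, I/O, and preprocessing.

A :class:`HeadingTrack` is one individual's azimuth time series as written
by the flight-simulator encoder: nominally 5 samples per second with a
0.9-degree angular resolution, headings in compass degrees relative to
magnetic north.  This module validates raw long-format CSV exports,
detects flight cessations (stalls), applies the inclusion rule, cuts
tracks into experimental phases and time bins, and computes the
per-individual orientation vectors and the turn-rate stability metric.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import (
    IndividualVector,
    individual_vector_from_angles,
    signed_angle_diff,
    wrap_degrees,
)
from .design import ExperimentDesign

__all__ = [
    "HeadingTrack",
    "TrackValidationReport",
    "DEFAULT_SCHEMA",
    "read_tracks",
    "write_tracks",
    "detect_cessations",
    "filter_individuals",
    "ExclusionRecord",
    "PhaseSlice",
    "segment_phases",
    "TimeBin",
    "bin_samples",
    "individual_vector",
    "StabilityResult",
    "mean_abs_turn_rate",
]


@dataclass(frozen=True)
class HeadingTrack:
    """One individual's timestamped azimuth stream.

    ``t`` is seconds from trial start (strictly increasing after
    validation); ``azimuth_deg`` holds compass headings in ``[0, 360)``.
    ``nominal_rate`` and ``encoder_step`` describe the acquisition
    hardware and drive expected-sample counts and quantization checks.
    """

    individual_id: str
    t: np.ndarray
    azimuth_deg: np.ndarray
    group: str = ""
    nominal_rate: float = 5.0
    encoder_step: float = 0.9

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        az = wrap_degrees(np.asarray(self.azimuth_deg, dtype=float))
        if t.shape != az.shape or t.ndim != 1:
            raise ValueError("HeadingTrack: t and azimuth must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("HeadingTrack: timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "azimuth_deg", az)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        """Covered duration: last timestamp plus one nominal sample period."""
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1] + 1.0 / self.nominal_rate)

    def is_quantized(self, tol: float = 1e-9) -> bool:
        """Whether every azimuth sits on the encoder grid."""
        steps = self.azimuth_deg / self.encoder_step
        return bool(np.all(np.abs(steps - np.round(steps)) <= tol / self.encoder_step))

    def rotated(self, delta_deg: float) -> "HeadingTrack":
        """Copy of the track with every heading rotated clockwise by delta."""
        return replace(self, azimuth_deg=wrap_degrees(self.azimuth_deg + delta_deg))


@dataclass
class TrackValidationReport:
    """What validation changed or rejected while reading raw rows."""

    n_rows_read: int = 0
    n_rows_kept: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)
    n_duplicates_collapsed: int = 0

    def summary(self) -> str:
        return (
            f"{self.n_rows_kept}/{self.n_rows_read} rows kept, "
            f"{len(self.rejected_rows)} rejected, "
            f"{self.n_duplicates_collapsed} duplicate timestamps collapsed"
        )


DEFAULT_SCHEMA: Mapping[str, str] = {
    "individual_id": "individual_id",
    "group": "group",
    "t": "t_s",
    "azimuth": "azimuth_deg",
}


def read_tracks(
    source: str | Path | io.IOBase,
    schema: Mapping[str, str] = DEFAULT_SCHEMA,
    nominal_rate: float = 5.0,
    encoder_step: float = 0.9,
) -> tuple[list[HeadingTrack], TrackValidationReport]:
    """Read a long-format CSV of encoder samples into per-individual tracks.

    Required columns (via ``schema``): individual id, time in seconds,
    azimuth in degrees; a group column is optional.  Azimuths in
    ``[0, 360]`` are accepted (360 wraps to 0); values outside that range
    are rejected row-wise and reported.  Duplicate ``(id, t)`` rows are
    collapsed to the first occurrence and counted.  Rows are sorted by
    time within each individual.
    """
    df = pd.read_csv(source)
    if df.shape[0] == 0:
        raise ValueError("read_tracks: input contains no data rows")
    for key in ("individual_id", "t", "azimuth"):
        col = schema[key]
        if col not in df.columns:
            raise ValueError(f"read_tracks: missing required column {col!r}")
    group_col = schema.get("group")
    has_group = group_col is not None and group_col in df.columns

    report = TrackValidationReport(n_rows_read=int(df.shape[0]))

    t = pd.to_numeric(df[schema["t"]], errors="coerce")
    az = pd.to_numeric(df[schema["azimuth"]], errors="coerce")
    for col_label, series in ((schema["t"], t), (schema["azimuth"], az)):
        bad = series.isna() & df[col_label].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"read_tracks: non-numeric value in column {col_label!r} at data row {row}"
            )
    missing = t.isna() | az.isna()
    for row in np.flatnonzero(missing.to_numpy()):
        report.rejected_rows.append((int(row), "missing value"))
    out_of_range = (~missing) & ((az < 0.0) | (az > 360.0))
    for row in np.flatnonzero(out_of_range.to_numpy()):
        report.rejected_rows.append((int(row), f"azimuth {az.iloc[row]} outside [0, 360]"))

    keep = ~(missing | out_of_range)
    df = df.loc[keep].copy()
    df["_t"] = t[keep]
    df["_az"] = az[keep].to_numpy() % 360.0

    tracks: list[HeadingTrack] = []
    for ind_id, sub in df.groupby(schema["individual_id"], sort=True):
        sub = sub.sort_values("_t", kind="mergesort")
        dup = sub["_t"].duplicated(keep="first")
        report.n_duplicates_collapsed += int(dup.sum())
        sub = sub.loc[~dup]
        group = str(sub[group_col].iloc[0]) if has_group else ""
        tracks.append(
            HeadingTrack(
                individual_id=str(ind_id),
                t=sub["_t"].to_numpy(dtype=float),
                azimuth_deg=sub["_az"].to_numpy(dtype=float),
                group=group,
                nominal_rate=nominal_rate,
                encoder_step=encoder_step,
            )
        )
    report.n_rows_kept = int(sum(tr.n_samples for tr in tracks))
    return tracks, report


def write_tracks(tracks: Sequence[HeadingTrack], path: str | Path | io.IOBase) -> None:
    """Write tracks back to the long-format CSV schema read_tracks accepts."""
    frames = [
        pd.DataFrame(
            {
                "individual_id": tr.individual_id,
                "group": tr.group,
                "t_s": tr.t,
                "azimuth_deg": tr.azimuth_deg,
            }
        )
        for tr in tracks
    ]
    if not frames:
        raise ValueError("write_tracks: no tracks to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def detect_cessations(
    track: HeadingTrack, window_s: float = 10.0
) -> list[tuple[float, float]]:
    """Find flight stalls: maximal runs of unchanged encoder readings.

    A stall is an interval of length >= ``window_s`` during which the
    quantized azimuth value never changes.  A run of equal samples ends at
    the timestamp of the first differing sample (or, at the end of the
    track, one nominal sample period after the last sample).  Returns
    disjoint, time-sorted ``(start_s, end_s)`` intervals.
    """
    if window_s <= 0:
        raise ValueError("detect_cessations: window_s must be positive")
    t, az = track.t, track.azimuth_deg
    if t.size == 0:
        return []
    dt = 1.0 / track.nominal_rate
    changes = np.flatnonzero(az[1:] != az[:-1]) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [t.size]))  # exclusive sample index
    out = []
    for i0, i1 in zip(starts, ends):
        start = float(t[i0])
        end = float(t[i1]) if i1 < t.size else float(t[-1] + dt)
        if end - start >= window_s:
            out.append((start, end))
    return out


@dataclass(frozen=True)
class ExclusionRecord:
    individual_id: str
    n_cessations: int
    reason: str


def filter_individuals(
    tracks: Sequence[HeadingTrack],
    max_cessations: int = 3,
    window_s: float = 10.0,
) -> tuple[list[HeadingTrack], list[ExclusionRecord]]:
    """Apply the inclusion rule: keep individuals with at most
    ``max_cessations`` flight stalls ("fewer than four" at the default).
    """
    kept, excluded = [], []
    for tr in tracks:
        n_cess = len(detect_cessations(tr, window_s=window_s))
        if n_cess <= max_cessations:
            kept.append(tr)
        else:
            excluded.append(
                ExclusionRecord(
                    individual_id=tr.individual_id,
                    n_cessations=n_cess,
                    reason=f"{n_cess} cessations > allowed {max_cessations}",
                )
            )
    return kept, excluded


@dataclass(frozen=True)
class PhaseSlice:
    """Samples of one track falling inside one phase window [start, end)."""

    individual_id: str
    group: str
    phase_id: str
    start_s: float
    duration_s: float
    t: np.ndarray
    azimuth_deg: np.ndarray
    nominal_rate: float

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def expected_samples(self) -> int:
        return int(round(self.duration_s * self.nominal_rate))

    def completeness(self) -> float:
        exp = self.expected_samples
        return self.n_samples / exp if exp else 0.0


def segment_phases(
    track: HeadingTrack,
    design: ExperimentDesign,
    tol_s: float | None = None,
) -> dict[str, PhaseSlice]:
    """Cut a track into the design's half-open phase windows.

    A sample at exactly a phase boundary belongs to the later phase.  If
    the track is shorter than the design (beyond ``tol_s``, default one
    nominal sample period) the missing phases are named in the error.
    """
    if tol_s is None:
        tol_s = 1.0 / track.nominal_rate
    coverage = track.duration_s
    missing = [pid for pid, start, end in design.windows() if end > coverage + tol_s]
    if missing:
        raise ValueError(
            f"segment_phases: track {track.individual_id!r} covers {coverage:.1f} s, "
            f"missing phases: {', '.join(missing)}"
        )
    out: dict[str, PhaseSlice] = {}
    for pid, start, end in design.windows():
        lo = np.searchsorted(track.t, start, side="left")
        hi = np.searchsorted(track.t, end, side="left")
        out[pid] = PhaseSlice(
            individual_id=track.individual_id,
            group=track.group,
            phase_id=pid,
            start_s=start,
            duration_s=end - start,
            t=track.t[lo:hi],
            azimuth_deg=track.azimuth_deg[lo:hi],
            nominal_rate=track.nominal_rate,
        )
    return out


@dataclass(frozen=True)
class TimeBin:
    """One time bin of a phase slice; ``defined`` is False when the bin
    holds fewer than the completeness threshold of expected samples."""

    phase_id: str
    bin_index: int
    t_start_s: float
    t_mid_s: float
    duration_s: float
    t: np.ndarray
    azimuth_deg: np.ndarray
    defined: bool

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


def bin_samples(
    phase_slice: PhaseSlice,
    bin_s: float = 30.0,
    completeness: float = 0.8,
) -> list[TimeBin]:
    """Subdivide a phase slice into half-open time bins of ``bin_s`` seconds.

    A 300-s phase at the default 30-s bin yields exactly 10 bins.  A
    trailing partial bin (when ``bin_s`` does not divide the phase
    duration) and any bin holding less than ``completeness`` of its
    expected samples are flagged ``defined=False`` rather than silently
    analyzed.
    """
    if bin_s <= 0:
        raise ValueError("bin_samples: bin_s must be positive")
    n_bins = int(np.ceil(phase_slice.duration_s / bin_s - 1e-9))
    bins: list[TimeBin] = []
    for k in range(n_bins):
        b_start = phase_slice.start_s + k * bin_s
        b_end = min(b_start + bin_s, phase_slice.start_s + phase_slice.duration_s)
        lo = np.searchsorted(phase_slice.t, b_start, side="left")
        hi = np.searchsorted(phase_slice.t, b_end, side="left")
        dur = b_end - b_start
        expected = dur * phase_slice.nominal_rate
        n_in = hi - lo
        full_width = abs(dur - bin_s) < 1e-9
        defined = full_width and expected > 0 and n_in >= completeness * expected
        bins.append(
            TimeBin(
                phase_id=phase_slice.phase_id,
                bin_index=k,
                t_start_s=b_start,
                t_mid_s=b_start + dur / 2.0,
                duration_s=dur,
                t=phase_slice.t[lo:hi],
                azimuth_deg=phase_slice.azimuth_deg[lo:hi],
                defined=bool(defined),
            )
        )
    return bins


def individual_vector(phase_slice: PhaseSlice) -> IndividualVector:
    """Mean vector plus Rayleigh test over one individual's phase slice."""
    return individual_vector_from_angles(
        phase_slice.azimuth_deg, phase_slice.individual_id, phase_slice.phase_id
    )


@dataclass(frozen=True)
class StabilityResult:
    """Flight-stability metric: mean absolute heading change per second."""

    individual_id: str
    mean_abs_turn: float
    n_steps: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_abs_turn <= 180.0 + 1e-9):
            raise ValueError("StabilityResult: mean_abs_turn outside [0, 180]")


def mean_abs_turn_rate(
    source: HeadingTrack | PhaseSlice,
    max_gap_s: float = 1.0,
) -> StabilityResult:
    """Average directional change per second of flight.

    The heading at each integer second mark is the first sample at or
    after the mark (marks with no sample within ``max_gap_s`` are
    undefined); the metric is the mean absolute minimal-angle difference
    between consecutive defined second marks.  Result lies in [0, 180]
    degrees/second and is invariant under global rotation of the track.
    """
    t = np.asarray(source.t, dtype=float)
    az = np.asarray(source.azimuth_deg, dtype=float)
    if t.size < 2:
        raise ValueError("mean_abs_turn_rate: need at least 2 samples")
    first = int(np.ceil(t[0] - 1e-9))
    last = int(np.floor(t[-1] + 1e-9))
    marks = np.arange(first, last + 1, dtype=float)
    if marks.size < 2:
        raise ValueError("mean_abs_turn_rate: need at least 2 whole seconds of data")
    idx = np.searchsorted(t, marks - 1e-9, side="left")
    idx = np.clip(idx, 0, t.size - 1)
    ok = t[idx] - marks <= max_gap_s
    headings = az[idx]
    # differences only between consecutive defined marks
    pair_ok = ok[1:] & ok[:-1]
    if not np.any(pair_ok):
        raise ValueError("mean_abs_turn_rate: no consecutive usable second marks")
    diffs = np.abs(signed_angle_diff(headings[1:], headings[:-1]))[pair_ok]
    return StabilityResult(
        individual_id=getattr(source, "individual_id", ""),
        mean_abs_turn=float(diffs.mean()),
        n_steps=int(diffs.size),
    )
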