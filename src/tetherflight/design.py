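"""Experiment designs: ordered phases of a tethered-flight trial.

A trial is a contiguous sequence of phases starting at t = 0.  Each phase
fixes the magnetic condition (NMF = natural magnetic field, CMF = field
with the horizontal component reversed by 180 degrees), the azimuth of
the visual cue, and the expected (seasonal goal) direction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .circular import signed_angle_diff, wrap_degrees

__all__ = ["PhaseSpec", "ExperimentDesign", "MAGNETIC_CONDITIONS"]

MAGNETIC_CONDITIONS = ("NMF", "CMF")


@dataclass(frozen=True)
class PhaseSpec:
    """One experimental phase (default length 300 s = 5 min)."""

    phase_id: str
    duration_s: float = 300.0
    magnetic_condition: str = "NMF"
    cue_azimuth_deg: float = 180.0
    expected_dir_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"phase {self.phase_id}: duration must be positive")
        if self.magnetic_condition not in MAGNETIC_CONDITIONS:
            raise ValueError(
                f"phase {self.phase_id}: magnetic_condition must be one of {MAGNETIC_CONDITIONS}"
            )
        object.__setattr__(self, "cue_azimuth_deg", wrap_degrees(self.cue_azimuth_deg))
        object.__setattr__(self, "expected_dir_deg", wrap_degrees(self.expected_dir_deg))

    @property
    def magnetic_goal_deg(self) -> float:
        """Expected direction as realized inside the arena.

        Under CMF the horizontal field component is reversed, so the
        direction the magnetic sense reports as the seasonal goal is
        rotated by 180 degrees relative to the NMF goal.
        """
        if self.magnetic_condition == "NMF":
            return self.expected_dir_deg
        return wrap_degrees(self.expected_dir_deg + 180.0)

    def is_conflict(self, tol_deg: float = 1.0) -> bool:
        """True when the visual cue and the magnetic goal disagree."""
        return abs(signed_angle_diff(self.cue_azimuth_deg, self.magnetic_goal_deg)) > tol_deg


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered, contiguous phase plan starting at t = 0."""

    phases: tuple[PhaseSpec, ...]

    def __init__(self, phases: Sequence[PhaseSpec]):
        phases = tuple(phases)
        if not phases:
            raise ValueError("ExperimentDesign: at least one phase required")
        ids = [p.phase_id for p in phases]
        if len(set(ids)) != len(ids):
            raise ValueError("ExperimentDesign: duplicate phase ids")
        object.__setattr__(self, "phases", phases)

    @property
    def phase_ids(self) -> list[str]:
        return [p.phase_id for p in self.phases]

    @property
    def total_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.phases))

    def phase_start_s(self, phase_id: str) -> float:
        start = 0.0
        for p in self.phases:
            if p.phase_id == phase_id:
                return start
            start += p.duration_s
        raise KeyError(f"unknown phase id {phase_id!r}")

    def phase(self, phase_id: str) -> PhaseSpec:
        for p in self.phases:
            if p.phase_id == phase_id:
                return p
        raise KeyError(f"unknown phase id {phase_id!r}")

    def windows(self) -> list[tuple[str, float, float]]:
        """Half-open phase windows ``(phase_id, start_s, end_s)``."""
        out, start = [], 0.0
        for p in self.phases:
            out.append((p.phase_id, start, start + p.duration_s))
            start += p.duration_s
        return out

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {"phases": [asdict(p) for p in self.phases]}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        if "phases" not in d:
            raise ValueError("design: missing 'phases' key")
        return cls([PhaseSpec(**p) for p in d["phases"]])

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentDesign":
        """Load a design from YAML or JSON (sniffed by suffix)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
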