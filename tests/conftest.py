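"""Shared fixtures: tiny hand-built tracks and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from tetherflight import ExperimentDesign, HeadingTrack, PhaseSpec, scenario_preset, simulate_cohort


@pytest.fixture
def make_track():
    """Factory for encoder-like tracks from an azimuth array at 5 Hz."""

    def _make(azimuth_deg, individual_id="m1", group="g", rate=5.0, step=0.9):
        az = np.asarray(azimuth_deg, dtype=float)
        t = np.arange(az.size) / rate
        return HeadingTrack(
            individual_id=individual_id,
            t=t,
            azimuth_deg=az,
            group=group,
            nominal_rate=rate,
            encoder_step=step,
        )

    return _make


@pytest.fixture
def five_phase_design() -> ExperimentDesign:
    """The standard five-by-300-s congruent design (goal south)."""
    return scenario_preset("fall_control").design


@pytest.fixture
def single_phase_design() -> ExperimentDesign:
    return ExperimentDesign([PhaseSpec(phase_id="I", duration_s=60.0)])


@pytest.fixture(scope="session")
def control_cohort():
    """One small oriented control cohort shared across tests (n=8)."""
    scenario = scenario_preset("fall_control", n_individuals=8, seed=42)
    tracks, truth = simulate_cohort(scenario)
    return scenario, tracks, truth
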