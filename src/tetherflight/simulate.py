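"""Synthetic encoder-like flight tracks with known ground truth.

The generator is a goal-biased wrapped random walk (an Ornstein-Uhlenbeck
pull on the circle, Euler-integrated at the encoder sampling rate): at
each step the heading relaxes toward the individual's goal direction with
gain ``g`` (1/s) and diffuses with intensity ``sigma`` (degrees per
square-root second).  Each individual's goal is the phase's visual-cue
azimuth plus a personal von Mises offset.  During cue-conflict phases the
gain decays exponentially with time constant ``tau`` — modelling the
delayed recognition of the conflict — and is restored as soon as the cues
re-align.  Output headings are quantized to the encoder step (0.9 degrees)
and sampled at the nominal 5 Hz, so every downstream stage sees data with
the statistical structure of the real recordings.

This generative mechanism is an artifact of the package: it is calibrated
to reproduce the qualitative phase phenomenology (stable goal-oriented
flight, gradual loss of group orientation after a conflict, high-turning
unstable flight without visual cues), not inferred from any animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .circular import signed_angle_diff, wrap_degrees
from .design import ExperimentDesign, PhaseSpec
from .tracks import HeadingTrack

__all__ = [
    "SimulationScenario",
    "TrackTruth",
    "CohortTruth",
    "simulate_track",
    "simulate_cohort",
    "scenario_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic cohort.

    ``gain`` (1/s) is the pull toward the goal, ``noise_sigma``
    (deg/sqrt(s)) the heading diffusion, ``goal_scatter_kappa`` the von
    Mises concentration of per-individual goal offsets, ``decay_tau_s``
    the e-folding time of the gain after a cue conflict begins.
    ``conflict_onset_s`` is normally None (derived from the design's
    conflict phases).  ``start`` is "uniform" (random initial heading) or
    "goal" (start on the goal).
    """

    name: str
    design: ExperimentDesign
    n_individuals: int = 25
    goal_dir: float = 180.0
    goal_scatter_kappa: float = 8.0
    gain: float = 0.5
    noise_sigma: float = 10.0
    conflict_onset_s: float | None = None
    decay_tau_s: float = 45.0
    sample_rate: float = 5.0
    encoder_step: float = 0.9
    start: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("scenario: n_individuals must be >= 1")
        if self.gain < 0 or self.noise_sigma < 0:
            raise ValueError("scenario: gain and noise_sigma must be >= 0")
        if self.decay_tau_s <= 0:
            raise ValueError("scenario: decay_tau_s must be positive")
        if self.sample_rate <= 0 or self.encoder_step <= 0:
            raise ValueError("scenario: sample_rate and encoder_step must be positive")
        if self.goal_scatter_kappa < 0:
            raise ValueError("scenario: goal_scatter_kappa must be >= 0")
        if self.start not in ("uniform", "goal"):
            raise ValueError("scenario: start must be 'uniform' or 'goal'")
        object.__setattr__(self, "goal_dir", wrap_degrees(self.goal_dir))

    @property
    def n_steps(self) -> int:
        return int(round(self.design.total_duration_s * self.sample_rate))

    def step_times(self) -> np.ndarray:
        return np.arange(self.n_steps) / self.sample_rate

    def gain_profile(self) -> np.ndarray:
        """Effective gain at every sample time.

        Within a contiguous run of conflict phases the gain decays as
        ``g * exp(-(t - t_onset)/tau)`` from the run's onset (or from
        ``conflict_onset_s`` if that lies inside the run); elsewhere it is
        the full ``gain``.
        """
        t = self.step_times()
        g_eff = np.full(t.size, self.gain, dtype=float)
        run_start: float | None = None
        for pid, start, end in self.design.windows():
            if self.design.phase(pid).is_conflict():
                if run_start is None:
                    run_start = start
                    if self.conflict_onset_s is not None and start <= self.conflict_onset_s < end:
                        run_start = float(self.conflict_onset_s)
                mask = (t >= start) & (t < end)
                g_eff[mask] = self.gain * np.exp(-(t[mask] - run_start) / self.decay_tau_s)
            else:
                run_start = None
        return g_eff

    def cue_profile(self) -> np.ndarray:
        """Visual-cue azimuth at every sample time."""
        t = self.step_times()
        cue = np.empty(t.size, dtype=float)
        for pid, start, end in self.design.windows():
            mask = (t >= start) & (t < end)
            cue[mask] = self.design.phase(pid).cue_azimuth_deg
        return cue


@dataclass(frozen=True)
class TrackTruth:
    """Ground truth for one simulated individual."""

    individual_id: str
    goal_offset_deg: float
    theta0_deg: float
    goals_by_phase: dict[str, float]


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for a simulated cohort; bit-reproducible from the
    scenario (including its seed)."""

    scenario: SimulationScenario
    individuals: tuple[TrackTruth, ...]
    gain_1hz: np.ndarray  # effective gain sampled once per second

    @property
    def goal_offsets_deg(self) -> np.ndarray:
        return np.array([tr.goal_offset_deg for tr in self.individuals])


def _individual_draws(scenario: SimulationScenario, index: int) -> tuple[float, float, np.ndarray]:
    """Per-individual substream draws: (goal offset, theta0, noise array).

    Substreams are spawned from the master seed, so individual ``index``
    gets the same draws regardless of cohort size or simulation order.
    """
    child = np.random.SeedSequence(scenario.seed).spawn(index + 1)[index]
    rng = np.random.default_rng(child)
    if scenario.goal_scatter_kappa > 0:
        offset = float(np.rad2deg(rng.vonmises(0.0, scenario.goal_scatter_kappa)))
    else:
        offset = float(rng.uniform(-180.0, 180.0))
    theta0_uniform = float(rng.uniform(0.0, 360.0))
    noise = rng.standard_normal(scenario.n_steps - 1)
    return offset, theta0_uniform, noise


def _integrate(
    scenario: SimulationScenario,
    offsets: np.ndarray,
    theta0: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Euler-integrate the heading SDE; columns are individuals."""
    dt = 1.0 / scenario.sample_rate
    g_eff = scenario.gain_profile()
    cue = scenario.cue_profile()
    sig_step = scenario.noise_sigma * np.sqrt(dt)
    n_steps = scenario.n_steps
    theta = np.empty((n_steps, offsets.size), dtype=float)
    theta[0] = theta0
    goals = cue[:, None] + offsets[None, :]  # (n_steps, n)
    for k in range(n_steps - 1):
        pull = g_eff[k] * signed_angle_diff(goals[k], theta[k]) * dt
        theta[k + 1] = theta[k] + pull + sig_step * noise[k]
    return theta


def _quantize(theta: np.ndarray, step: float) -> np.ndarray:
    return (np.round(theta / step) * step) % 360.0


def _build_truth(scenario: SimulationScenario, index: int, offset: float, theta0: float) -> TrackTruth:
    goals = {
        p.phase_id: wrap_degrees(p.cue_azimuth_deg + offset) for p in scenario.design.phases
    }
    return TrackTruth(
        individual_id=f"sim{index:03d}",
        goal_offset_deg=offset,
        theta0_deg=theta0,
        goals_by_phase=goals,
    )


def simulate_track(
    scenario: SimulationScenario, individual_index: int
) -> tuple[HeadingTrack, TrackTruth]:
    """Simulate one individual's encoder track (deterministic given the
    scenario seed and the individual index)."""
    if not (0 <= individual_index < scenario.n_individuals):
        raise ValueError("simulate_track: individual_index out of range")
    offset, theta0_u, noise = _individual_draws(scenario, individual_index)
    first_cue = scenario.design.phases[0].cue_azimuth_deg
    theta0 = theta0_u if scenario.start == "uniform" else wrap_degrees(first_cue + offset)
    theta = _integrate(scenario, np.array([offset]), np.array([theta0]), noise[:, None])
    truth = _build_truth(scenario, individual_index, offset, theta0)
    track = HeadingTrack(
        individual_id=truth.individual_id,
        group=scenario.name,
        t=scenario.step_times(),
        azimuth_deg=_quantize(theta[:, 0], scenario.encoder_step),
        nominal_rate=scenario.sample_rate,
        encoder_step=scenario.encoder_step,
    )
    return track, truth


def simulate_cohort(
    scenario: SimulationScenario,
) -> tuple[list[HeadingTrack], CohortTruth]:
    """Simulate the whole cohort (vectorized over individuals).

    Column ``i`` reproduces :func:`simulate_track`'s output for index
    ``i`` bit-for-bit, because each individual draws from its own spawned
    substream.
    """
    n = scenario.n_individuals
    offsets = np.empty(n)
    theta0 = np.empty(n)
    noise = np.empty((scenario.n_steps - 1, n))
    first_cue = scenario.design.phases[0].cue_azimuth_deg
    for i in range(n):
        off, th0_u, nz = _individual_draws(scenario, i)
        offsets[i] = off
        theta0[i] = th0_u if scenario.start == "uniform" else wrap_degrees(first_cue + off)
        noise[:, i] = nz
    theta = _integrate(scenario, offsets, theta0, noise)
    az = _quantize(theta, scenario.encoder_step)
    t = scenario.step_times()
    tracks = []
    truths = []
    for i in range(n):
        truth = _build_truth(scenario, i, float(offsets[i]), float(theta0[i]))
        truths.append(truth)
        tracks.append(
            HeadingTrack(
                individual_id=truth.individual_id,
                group=scenario.name,
                t=t,
                azimuth_deg=az[:, i],
                nominal_rate=scenario.sample_rate,
                encoder_step=scenario.encoder_step,
            )
        )
    sec_idx = np.arange(0, scenario.n_steps, int(round(scenario.sample_rate)))
    truth = CohortTruth(
        scenario=scenario,
        individuals=tuple(truths),
        gain_1hz=scenario.gain_profile()[sec_idx],
    )
    return tracks, truth


def _five_phase_design(
    cue: Sequence[float], magnetic: Sequence[str], expected: float = 180.0
) -> ExperimentDesign:
    ids = ["I", "II", "III", "IV", "V"][: len(cue)]
    return ExperimentDesign(
        [
            PhaseSpec(
                phase_id=pid,
                duration_s=300.0,
                magnetic_condition=mag,
                cue_azimuth_deg=c,
                expected_dir_deg=expected,
            )
            for pid, c, mag in zip(ids, cue, magnetic)
        ]
    )


def _preset_fall_conflict() -> SimulationScenario:
    # Fall cue-conflict trial: cue at the seasonal goal (south) while the
    # horizontal field is reversed in phases II-III, realigned in IV
    # (cue moved to the CMF goal) and restored in V.
    design = _five_phase_design(
        cue=[180.0, 180.0, 180.0, 0.0, 180.0],
        magnetic=["NMF", "CMF", "CMF", "CMF", "NMF"],
    )
    return SimulationScenario(name="fall_conflict", design=design)


def _preset_fall_control() -> SimulationScenario:
    # Congruent control: cue and magnetic goal stay aligned throughout.
    # Only the conflict flag and the cue azimuth enter the dynamics, so
    # holding NMF is generatively equivalent to the congruent-CMF design.
    design = _five_phase_design(
        cue=[180.0] * 5,
        magnetic=["NMF"] * 5,
    )
    return SimulationScenario(name="fall_control", design=design)


def _preset_no_visual_cues() -> SimulationScenario:
    # No usable visual cue: zero goal pull and strong heading diffusion;
    # two 10-min blocks (NMF then CMF) split into 5-min phases.
    design = _five_phase_design(
        cue=[180.0] * 4,
        magnetic=["NMF", "NMF", "CMF", "CMF"],
    )
    return SimulationScenario(
        name="no_visual_cues",
        design=design,
        gain=0.0,
        noise_sigma=45.0,
    )


_PRESETS = {
    "fall_conflict": _preset_fall_conflict,
    "fall_control": _preset_fall_control,
    "no_visual_cues": _preset_no_visual_cues,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def scenario_preset(name: str, **overrides) -> SimulationScenario:
    """Return a named scenario preset, optionally overriding fields.

    Presets: ``fall_conflict`` (five-phase cue-conflict trial),
    ``fall_control`` (congruent cues throughout), ``no_visual_cues``
    (zero goal pull, high diffusion).
    """
    try:
        scenario = _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    if overrides:
        scenario = replace(scenario, **overrides)
    return scenario
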