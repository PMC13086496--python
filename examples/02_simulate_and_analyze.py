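"""Simulate an oriented control cohort and run the per-phase analysis.

The control preset keeps the visual cue and the magnetic goal congruent
through five 5-minute phases, so the group should stay significantly
oriented near the 180-degree seasonal goal throughout.
"""

from tetherflight import (
    filter_individuals,
    group_orientation_by_phase,
    scenario_preset,
    simulate_cohort,
)

scenario = scenario_preset("fall_control", n_individuals=15, seed=42)
tracks, truth = simulate_cohort(scenario)
kept, excluded = filter_individuals(tracks)  # the <4-cessations inclusion rule
print(f"simulated {len(tracks)} tracks, {len(kept)} pass the inclusion rule")

results = group_orientation_by_phase(kept, scenario.design, n_mc=10_000, n_boot=1000, seed=7)
print(f"\n{'phase':>5} {'n':>3} {'MV':>7} {'R*':>6} {'p_mc':>8} {'95% arc':>18} sig")
for res in results:
    o = res.orientation
    print(
        f"{o.phase_id:>5} {o.n:>3} {o.mv_dir:>6.1f}  {o.rstar:>5.2f} {o.p_mc:>8.4f} "
        f"[{o.ci_low:>6.1f}, {o.ci_high:>6.1f}]  {'*' if o.sig_05 else '-'}"
    )
print(
    "\nMV near 180 deg with R* well above ~1 in every phase: the cohort holds\n"
    "its seasonal goal whenever the cues stay congruent."
)
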