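# tetherflight

Orientation analysis for tethered-flight experiments on migratory
insects, plus a synthetic flight-track generator for validating every
stage of the analysis without instrument data.

In a tethered-flight assay a moth flies on a vertical shaft at the
center of a cylindrical arena while an optical encoder records its
compass heading (azimuth relative to magnetic north) five times per
second at 0.9° resolution. Trials are divided into consecutive phases
(typically five 5-minute phases) in which the visual-cue azimuth and the
horizontal magnetic field are manipulated — aligned with the seasonal
migratory goal, or placed in conflict. The scientific questions are
whether a cohort of individually tested animals shares a flight
direction, how quickly group orientation degrades when visual and
magnetic cues disagree, and whether flight itself destabilizes when
visual cues are absent.

## Statistics implemented

**Per individual.** Over a phase's samples, the mean resultant vector
gives the mean direction θ̄ and the directedness
r = ‖n⁻¹ Σ (cos θᵢ, sin θᵢ)‖ ∈ [0, 1]; uniformity is tested with the
Rayleigh test (z = n r², p by the standard large-sample series
approximation).

**Per group: Moore's modified Rayleigh test (MMRT).** Individuals are
ranked by r ascending (average ranks on ties); with ranks iⱼ and mean
directions θⱼ,

    C = Σ iⱼ cos θⱼ,  S = Σ iⱼ sin θⱼ,
    R* = √(C² + S²) / n^{3/2},  MV = atan2(S, C),

so both the agreement of directions and the ranking of directedness
contribute. R* is bounded by (n+1)/(2√n), attained when all directions
coincide. Significance comes from a seeded Monte-Carlo null (uniform
directions, ranks fixed), and a bootstrap over individuals yields a 95%
confidence arc for the MV. As a rule of thumb recovered by the null
calibration, R* > 1 marks significant collective orientation at the 5%
level for typical cohort sizes.

**Time courses and comparisons.** Each phase can be subdivided into 30-s
bins (ten per 5-minute phase) with an R* per bin, exposing gradual
orientation loss. Per-individual metrics (r, or the turn-rate stability
metric: mean |heading change| per second) are compared across groups
with Wilcoxon rank-sum / signed-rank tests, Friedman tests across
phases, Benjamini–Hochberg FDR control, and a compact letter display.

**Synthetic cohorts.** A goal-biased wrapped random walk with
per-individual von Mises goal offsets, encoder quantization, and
exponential gain decay after a cue conflict generates cohorts with full
ground truth; presets cover the congruent-cue control, the cue-conflict
trial, and the no-visual-cue condition.

## Worked example

```python
from tetherflight import group_orientation_by_phase, scenario_preset, simulate_cohort

scenario = scenario_preset("fall_control", n_individuals=15, seed=42)
tracks, truth = simulate_cohort(scenario)
results = group_orientation_by_phase(tracks, scenario.design, seed=7)
for res in results:
    o = res.orientation
    print(o.phase_id, round(o.mv_dir, 1), round(o.rstar, 2), o.p_mc, o.sig_05)
```

prints (see `examples/02_simulate_and_analyze.py` for the formatted
version):

```
phase   n      MV     R*     p_mc            95% arc sig
    I  15  182.8   1.96   0.0001 [ 169.6,  193.9]  *
   II  15  186.6   1.96   0.0001 [ 173.0,  196.4]  *
  III  15  183.6   1.94   0.0001 [ 170.5,  194.8]  *
   IV  15  189.1   1.98   0.0001 [ 178.7,  197.4]  *
    V  15  187.9   1.99   0.0001 [ 178.8,  196.3]  *
```

The cohort's rank-weighted mean vector stays within a few degrees of the
180° seasonal goal, R* ≈ 2 is far above the ≈1.02 critical radius, and
the Monte-Carlo p sits at its floor — significant group orientation in
every phase, as expected when the cues stay congruent. Under the
cue-conflict preset the 30-s R* series instead collapses below the
critical radius during the second conflict phase and recovers after the
cues re-align (`examples/03_conflict_timeseries.py`):

```
phase  bins above crit   mean R*   conflict?
    I          10/10       2.44      no
   II           9/10       2.00      yes
  III           3/10       0.75      yes
   IV          10/10       2.44      no
    V          10/10       2.44      no
```

The command-line interface wraps the same pipeline:

```sh
tetherflight simulate fall_conflict --out-dir runs/sim --n 25 --seed 1
tetherflight analyze --tracks runs/sim/tracks.csv --design runs/sim/design.yaml \
    --out-dir runs/results --seed 1
```

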