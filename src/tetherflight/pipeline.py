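"""Group-level analyses over cohorts of heading tracks.

Reproduces the experiment's analysis chain: per-phase group orientation
(individual mean vectors -> Moore's modified Rayleigh test with
Monte-Carlo significance and a bootstrap confidence arc), the 30-s-binned
R* time series that exposes delayed disorientation, and nonparametric
comparisons of per-individual metrics (Wilcoxon rank-sum / signed-rank,
Friedman across phases) with Benjamini-Hochberg FDR control and a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .circular import (
    ConfidenceArc,
    GroupOrientation,
    IndividualVector,
    bootstrap_ci,
    group_moore,
    mean_vector,
    moore_null,
    moore_pvalue,
    rank_weighted_resultant,
)
from .design import ExperimentDesign
from .tracks import HeadingTrack, PhaseSlice, bin_samples, individual_vector, segment_phases

__all__ = [
    "PhaseGroupResult",
    "group_orientation_by_phase",
    "RstarSeries",
    "rstar_timeseries",
    "bh_adjust",
    "ComparisonTable",
    "compare_groups",
    "friedman_phases",
]


@dataclass(frozen=True)
class PhaseGroupResult:
    """One group's orientation summary for one phase."""

    group: str
    phase_id: str
    orientation: GroupOrientation
    vectors: tuple[IndividualVector, ...]

    def __post_init__(self) -> None:
        if self.orientation.n != len(self.vectors):
            raise ValueError("PhaseGroupResult: n mismatch with individual vectors")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def group_orientation_by_phase(
    tracks: Sequence[HeadingTrack],
    design: ExperimentDesign,
    n_mc: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    group: str | None = None,
) -> list[PhaseGroupResult]:
    """Per-phase group orientation: Moore's test + Monte-Carlo p + CI arc.

    For every phase of the design, each individual's slice yields a mean
    vector; Moore's modified Rayleigh test gives the rank-weighted MV and
    R*, a seeded Monte-Carlo null gives ``p_mc`` and the significance
    radii, and a bootstrap over individuals gives the ``level`` arc.  The
    Monte-Carlo null depends only on the cohort size, so it is computed
    once and shared across phases.
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("group_orientation_by_phase: need at least 2 individuals")
    if group is None:
        group = tracks[0].group
    null_seed, *boot_seeds = _child_seeds(seed, 1 + len(design.phases))
    segments = [segment_phases(tr, design) for tr in tracks]
    n = len(tracks)
    null = moore_null(n, n_mc, null_seed)
    results = []
    for boot_seed, phase in zip(boot_seeds, design.phases):
        vectors = tuple(individual_vector(seg[phase.phase_id]) for seg in segments)
        mv_dir, rstar = group_moore(vectors)
        mp = moore_pvalue(rstar, n, null=null)
        arc = bootstrap_ci(vectors, n_boot=n_boot, level=level, seed=boot_seed)
        orientation = GroupOrientation(
            phase_id=phase.phase_id,
            n=n,
            mv_dir=mv_dir,
            rstar=rstar,
            p_mc=mp.p_mc,
            crit_05=mp.crit_05,
            crit_01=mp.crit_01,
            ci_low=arc.ci_low,
            ci_high=arc.ci_high,
        )
        results.append(
            PhaseGroupResult(
                group=group, phase_id=phase.phase_id, orientation=orientation, vectors=vectors
            )
        )
    return results


@dataclass(frozen=True)
class RstarSeries:
    """Time-binned Moore R* series for one group.

    ``table`` columns: phase_id, bin_index, t_mid_s, rstar, n.  Bins where
    fewer than two individuals have a defined vector carry ``rstar=nan``.
    """

    group: str
    table: pd.DataFrame


def rstar_timeseries(
    tracks: Sequence[HeadingTrack],
    design: ExperimentDesign,
    bin_s: float = 30.0,
    completeness: float = 0.8,
    group: str | None = None,
) -> RstarSeries:
    """Moore's R* in consecutive time bins (default ten 30-s bins per
    300-s phase).

    Each individual contributes its bin-level mean vector; individuals
    whose bin is undefined (incomplete data or fewer than 2 samples) are
    dropped from that bin only.
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("rstar_timeseries: need at least 2 individuals")
    if group is None:
        group = tracks[0].group
    binned = []  # per individual: dict (phase, bin_index) -> TimeBin
    for tr in tracks:
        segs = segment_phases(tr, design)
        per = {}
        for pid, sl in segs.items():
            for b in bin_samples(sl, bin_s=bin_s, completeness=completeness):
                per[(pid, b.bin_index)] = b
        binned.append(per)
    keys = sorted(
        {k for per in binned for k in per},
        key=lambda k: (design.phase_start_s(k[0]), k[1]),
    )
    records = []
    for pid, bidx in keys:
        dirs, rs = [], []
        t_mid = None
        for per in binned:
            b = per.get((pid, bidx))
            if b is None:
                continue
            t_mid = b.t_mid_s
            if not b.defined or b.n_samples < 2:
                continue
            d, r = mean_vector(b.azimuth_deg)
            if np.isnan(d):
                continue
            dirs.append(d)
            rs.append(r)
        n_in = len(dirs)
        if n_in >= 2:
            _, rstar = rank_weighted_resultant(np.array(dirs), np.array(rs))
        else:
            rstar = float("nan")
        records.append(
            {
                "phase_id": pid,
                "bin_index": bidx,
                "t_mid_s": t_mid,
                "rstar": rstar,
                "n": n_in,
            }
        )
    return RstarSeries(group=group, table=pd.DataFrame.from_records(records))


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ComparisonTable:
    """Pairwise nonparametric comparisons with FDR control.

    ``table`` columns: group_a, group_b, test, statistic, p_raw, p_adj,
    paired.  ``letters`` maps each group to its compact letter display:
    two groups share a letter iff their adjusted p is >= alpha.
    """

    table: pd.DataFrame
    letters: dict[str, str]
    alpha: float = 0.05


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum via Mann-Whitney U; exact when small and tie-free."""
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired values; identical samples give p=1."""
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d[d != 0]
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties and np.all(d != 0)) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _letters_from_partition(groups: Sequence[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Every maximal clique of the graph gets a letter, so any two groups
    that do not differ share at least one letter and significantly
    different groups never share one.  Deterministic: cliques are sorted
    by their member names.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for pair in nonsig:
        a, b = sorted(pair)
        g.add_edge(a, b)
    cliques = sorted(sorted(c) for c in nx.find_cliques(g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = alphabet[i % len(alphabet)]
        for member in clique:
            letters[member] += ch
    return letters


def compare_groups(
    metric_table: pd.DataFrame,
    plan: Sequence[tuple[str, str, bool]],
    alpha: float = 0.05,
) -> ComparisonTable:
    """Pairwise comparisons of a per-individual metric between groups.

    ``metric_table`` needs columns ``group``, ``individual_id``,
    ``value``.  ``plan`` lists ``(group_a, group_b, paired)``; paired
    comparisons use the Wilcoxon signed-rank test on individuals present
    in both groups (an error if the ids do not match), unpaired ones the
    rank-sum test.  All p-values are Benjamini-Hochberg adjusted across
    the plan, and the letter display partitions groups at ``alpha``.
    """
    required = {"group", "individual_id", "value"}
    if not required.issubset(metric_table.columns):
        raise ValueError(f"compare_groups: metric_table needs columns {sorted(required)}")
    by_group = {
        str(g): sub.set_index("individual_id")["value"]
        for g, sub in metric_table.groupby("group")
    }
    rows = []
    for ga, gb, paired in plan:
        if ga not in by_group or gb not in by_group:
            missing = ga if ga not in by_group else gb
            raise ValueError(f"compare_groups: group {missing!r} not in metric table")
        va, vb = by_group[ga], by_group[gb]
        if paired:
            common = va.index.intersection(vb.index)
            if len(common) < 2:
                raise ValueError(
                    f"compare_groups: paired comparison {ga!r} vs {gb!r} "
                    "has fewer than 2 shared individual_ids"
                )
            stat, p = _signed_rank(
                va.loc[common].to_numpy(float), vb.loc[common].to_numpy(float)
            )
            test = "wilcoxon_signed_rank"
        else:
            stat, p = _rank_sum(va.to_numpy(float), vb.to_numpy(float))
            test = "wilcoxon_rank_sum"
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "test": test,
                "statistic": stat,
                "p_raw": p,
                "paired": bool(paired),
            }
        )
    table = pd.DataFrame.from_records(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    groups = sorted(by_group)
    tested = {frozenset((r["group_a"], r["group_b"])) for r in rows}
    nonsig = {
        frozenset((ga, gb))
        for ga, gb in ((r.group_a, r.group_b) for r in table.itertuples())
        if table.loc[
            (table.group_a == ga) & (table.group_b == gb), "p_adj"
        ].iloc[0]
        >= alpha
    }
    # untested pairs are not claimed different
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            if frozenset((ga, gb)) not in tested:
                nonsig.add(frozenset((ga, gb)))
    letters = _letters_from_partition(groups, nonsig)
    return ComparisonTable(table=table, letters=letters, alpha=alpha)


def friedman_phases(matrix: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Friedman test across phases (columns) for repeated measures on the
    same individuals (rows).

    The matrix must be complete; requires >= 2 individuals and >= 2
    phases.  For >= 3 phases this is the standard chi-square Friedman
    statistic; for exactly 2 phases the same rank statistic is computed
    directly (scipy requires three samples).  Rows that are entirely tied
    contribute zero, so identical columns give statistic 0 and p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("friedman_phases: need a 2-D matrix, >= 2 rows and >= 2 columns")
    if np.any(np.isnan(m)):
        raise ValueError("friedman_phases: matrix has missing cells (no imputation)")
    n, k = m.shape
    if np.all(m == m[:, [0]]):
        return 0.0, 1.0
    if k >= 3:
        stat, p = stats.friedmanchisquare(*[m[:, j] for j in range(k)])
        return float(stat), float(p)
    # k == 2: Friedman rank statistic with average ranks, chi-square df=1
    ranks = stats.rankdata(m, axis=1)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(
        (col_sums - n * (k + 1) / 2.0) ** 2
    )
    # tie correction as in the standard formulation
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    stat /= c
    return float(stat), float(stats.chi2.sf(stat, k - 1))
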