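"""Directional statistics for heading data.

All public angles are compass degrees: measured clockwise from magnetic
north, normalized into ``[0, 360)``.  With that convention the *north*
component of a unit heading is ``cos(theta)`` and the *east* component is
``sin(theta)``, so ``atan2(east, north)`` recovers the compass angle.
Radians appear only inside function bodies.

The module provides the per-individual layer (mean resultant vector and
the Rayleigh uniformity test) and the group layer used for cohorts of
individually tested animals: Moore's modified Rayleigh test, which ranks
individuals by their directedness ``r`` and tests the rank-weighted
resultant, together with a seeded Monte-Carlo null for its significance
and a bootstrap confidence arc for the rank-weighted mean direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "wrap_degrees",
    "signed_angle_diff",
    "mean_vector",
    "rayleigh_test",
    "RayleighResult",
    "IndividualVector",
    "individual_vector_from_angles",
    "rank_weighted_resultant",
    "group_moore",
    "moore_rstar_max",
    "moore_null",
    "moore_pvalue",
    "MoorePValue",
    "bootstrap_ci",
    "ConfidenceArc",
    "GroupOrientation",
]

#: resultant lengths below this are treated as exactly zero (direction undefined)
_ZERO_RESULTANT_TOL = 1e-12


def wrap_degrees(angle):
    """Normalize angles (scalar or array) into ``[0, 360)``."""
    wrapped = np.asarray(angle, dtype=float) % 360.0
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def signed_angle_diff(a, b):
    """Minimal signed rotation taking heading ``b`` onto heading ``a``.

    Returns degrees in ``(-180, 180]``; the 180-degree tie resolves to
    ``+180``.  Accepts scalars or broadcastable arrays.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def _components(angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rad = np.deg2rad(angles_deg)
    return np.cos(rad), np.sin(rad)  # (north, east)


def mean_vector(angles_deg: Sequence[float] | np.ndarray, min_n: int = 1) -> tuple[float, float]:
    """Mean direction and resultant length of a set of headings.

    Returns ``(mean_dir, r)`` with ``mean_dir`` in ``[0, 360)`` and
    ``r`` in ``[0, 1]``.  When the unit vectors cancel (``r`` numerically
    zero) the direction is undefined and returned as ``nan`` — callers
    must check, it is never silently reported as 0.

    Raises ``ValueError`` on an empty input or fewer than ``min_n`` samples.
    """
    ang = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if ang.size == 0:
        raise ValueError("mean_vector: empty set of angles")
    if min_n < 1:
        raise ValueError("mean_vector: min_n must be >= 1")
    if ang.size < min_n:
        raise ValueError(f"mean_vector: {ang.size} samples < required min_n={min_n}")
    north, east = _components(ang)
    c, s = float(north.mean()), float(east.mean())
    r = float(np.hypot(c, s))
    if r < _ZERO_RESULTANT_TOL:
        return float("nan"), 0.0
    mean_dir = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    return mean_dir, r


class RayleighResult(NamedTuple):
    r: float
    z: float
    p: float


def rayleigh_test(angles_deg: Sequence[float] | np.ndarray) -> RayleighResult:
    """Rayleigh test of uniformity for a single individual's headings.

    ``z = n * r**2``; the p-value uses the standard large-sample series
    approximation ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with
    ``R = n*r``, clamped into ``[0, 1]``.  Rotation-invariant.
    """
    ang = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    n = ang.size
    if n < 2:
        raise ValueError("rayleigh_test: need at least 2 samples")
    _, r = mean_vector(ang)
    if np.isnan(r):  # pragma: no cover - mean_vector never returns nan r
        r = 0.0
    big_r = n * r
    z = n * r * r
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r)) - (1.0 + 2.0 * n)))
    return RayleighResult(r=r, z=z, p=float(np.clip(p, 0.0, 1.0)))


@dataclass(frozen=True)
class IndividualVector:
    """One individual's mean flight direction and directedness in one phase.

    ``mean_dir`` is the circular mean heading in compass degrees (``nan``
    when undefined), ``r`` the mean resultant length (0 = uniform headings,
    1 = constant heading), and ``rayleigh_z``/``rayleigh_p`` the Rayleigh
    uniformity statistics over the ``n_samples`` encoder samples.
    """

    individual_id: str
    phase_id: str
    mean_dir: float
    r: float
    n_samples: int
    rayleigh_z: float
    rayleigh_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"IndividualVector: r={self.r} outside [0, 1]")


def individual_vector_from_angles(
    angles_deg: Sequence[float] | np.ndarray,
    individual_id: str,
    phase_id: str,
) -> IndividualVector:
    """Build an :class:`IndividualVector` from raw headings (>= 2 samples)."""
    ang = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if ang.size < 2:
        raise ValueError("individual_vector: need at least 2 samples")
    mean_dir, r = mean_vector(ang)
    ray = rayleigh_test(ang)
    return IndividualVector(
        individual_id=str(individual_id),
        phase_id=str(phase_id),
        mean_dir=mean_dir,
        r=r,
        n_samples=int(ang.size),
        rayleigh_z=ray.z,
        rayleigh_p=ray.p,
    )


def moore_rstar_max(n: int) -> float:
    """Upper bound of Moore's R*: ``(n + 1) / (2 sqrt(n))``, attained when
    all individual directions coincide."""
    return (n + 1) / (2.0 * np.sqrt(n))


def rank_weighted_resultant(
    mean_dirs_deg: np.ndarray, r_values: np.ndarray
) -> tuple[float, float]:
    """Rank-weighted mean direction and Moore's R* for one cohort.

    Individuals are ranked by ``r`` ascending (ties get average ranks);
    with ranks ``i`` and directions ``theta_i`` the components are
    ``C = sum i*cos(theta_i)``, ``S = sum i*sin(theta_i)`` and
    ``R* = sqrt(C^2 + S^2) / n^{3/2}``.  Returns ``(mv_dir, rstar)``;
    ``mv_dir`` is ``nan`` when the weighted vectors cancel exactly.
    """
    dirs = np.asarray(mean_dirs_deg, dtype=float)
    rs = np.asarray(r_values, dtype=float)
    if dirs.size == 0:
        raise ValueError("rank_weighted_resultant: empty cohort")
    if dirs.shape != rs.shape:
        raise ValueError("rank_weighted_resultant: direction/r length mismatch")
    if np.any(np.isnan(dirs)):
        raise ValueError("rank_weighted_resultant: undefined mean direction in cohort")
    n = dirs.size
    ranks = stats.rankdata(rs)  # average ranks on ties
    north, east = _components(dirs)
    c = float(np.sum(ranks * north))
    s = float(np.sum(ranks * east))
    resultant = float(np.hypot(c, s))
    rstar = resultant / n**1.5
    if resultant < _ZERO_RESULTANT_TOL:
        return float("nan"), rstar
    mv_dir = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    return mv_dir, rstar


def group_moore(vectors: Sequence[IndividualVector]) -> tuple[float, float]:
    """Moore's modified Rayleigh statistic for a cohort of individuals.

    Returns ``(mv_dir, rstar)`` — the rank-weighted mean direction of the
    group and the modified Rayleigh statistic R*.  A single-individual
    cohort is degenerate (R* is 1 by construction) and triggers a warning.
    """
    vectors = list(vectors)
    if len(vectors) == 0:
        raise ValueError("group_moore: empty cohort")
    if len(vectors) == 1:
        warnings.warn(
            "group_moore: single-individual cohort is degenerate (R* = 1)",
            stacklevel=2,
        )
    dirs = np.array([v.mean_dir for v in vectors], dtype=float)
    rs = np.array([v.r for v in vectors], dtype=float)
    return rank_weighted_resultant(dirs, rs)


def moore_null(n: int, n_mc: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample the null distribution of Moore's R* for cohort size ``n``.

    Under H0 the ``n`` directions are i.i.d. uniform and independent of the
    r-ranks, so the ranks can be held fixed at ``1..n``.  Returns ``n_mc``
    null R* values; reproducible given the seed.
    """
    if n < 2:
        raise ValueError("moore_null: need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranks = np.arange(1, n + 1, dtype=float)
    # chunk to bound memory at large n_mc
    out = np.empty(n_mc, dtype=float)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    for lo in range(0, n_mc, chunk):
        hi = min(lo + chunk, n_mc)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(hi - lo, n))
        c = np.cos(theta) @ ranks
        s = np.sin(theta) @ ranks
        out[lo:hi] = np.hypot(c, s)
    out /= n**1.5
    return out


class MoorePValue(NamedTuple):
    p_mc: float
    crit_05: float
    crit_01: float


def moore_pvalue(
    rstar: float,
    n: int,
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
    null: np.ndarray | None = None,
) -> MoorePValue:
    """Monte-Carlo significance of Moore's R*.

    ``p_mc = (1 + #{null >= rstar}) / (1 + n_mc)`` over ``n_mc`` uniform
    null cohorts of size ``n``; ``crit_05``/``crit_01`` are the empirical
    95th/99th null percentiles.  A precomputed ``null`` sample (from
    :func:`moore_null`, which depends only on ``n``) may be passed to
    amortize the null across many cohorts of the same size.
    """
    if n < 2:
        raise ValueError("moore_pvalue: need n >= 2")
    if null is None:
        if n_mc < 1000:
            raise ValueError("moore_pvalue: n_mc must be >= 1000")
        null = moore_null(n, n_mc, seed)
    null = np.asarray(null, dtype=float)
    m = null.size
    p = (1.0 + int(np.count_nonzero(null >= rstar))) / (1.0 + m)
    crit_05, crit_01 = np.quantile(null, [0.95, 0.99])
    return MoorePValue(p_mc=float(p), crit_05=float(crit_05), crit_01=float(crit_01))


@dataclass(frozen=True)
class ConfidenceArc:
    """Bootstrap confidence arc for the rank-weighted mean direction.

    The arc runs clockwise from ``ci_low`` to ``ci_high`` (compass
    degrees) and always contains the point-estimate MV.  ``n_redrawn``
    counts degenerate resamples (cancelling resultant) that were redrawn.
    """

    ci_low: float
    ci_high: float
    n_redrawn: int = 0

    def __iter__(self):
        return iter((self.ci_low, self.ci_high))

    def contains(self, angle_deg: float) -> bool:
        """Whether ``angle_deg`` lies on the clockwise arc low -> high."""
        span = (self.ci_high - self.ci_low) % 360.0
        off = (angle_deg - self.ci_low) % 360.0
        return off <= span + 1e-9

    @property
    def width(self) -> float:
        return (self.ci_high - self.ci_low) % 360.0


def bootstrap_ci(
    vectors: Sequence[IndividualVector],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> ConfidenceArc:
    """Percentile bootstrap confidence arc for the group MV direction.

    Individuals are resampled with replacement ``n_boot`` times; each
    resample's rank-weighted MV is reduced to its signed deviation from the
    point-estimate MV, and the arc spans the central ``level`` fraction of
    those deviations (clamped so the point estimate always lies on the
    arc).  Degenerate resamples with an undefined MV are redrawn and
    counted in the result.
    """
    vectors = list(vectors)
    n = len(vectors)
    if n < 2:
        raise ValueError("bootstrap_ci: need at least 2 individuals")
    if n_boot < 200:
        raise ValueError("bootstrap_ci: n_boot must be >= 200")
    if not (0.0 < level < 1.0):
        raise ValueError("bootstrap_ci: level must be in (0, 1)")
    dirs = np.array([v.mean_dir for v in vectors], dtype=float)
    rs = np.array([v.r for v in vectors], dtype=float)
    mv_hat, _ = rank_weighted_resultant(dirs, rs)
    if np.isnan(mv_hat):
        raise ValueError("bootstrap_ci: point-estimate MV is undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    north, east = _components(dirs)
    boot_dirs = np.empty(n_boot, dtype=float)
    filled = 0
    n_redrawn = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        ranks = stats.rankdata(rs[idx], axis=1)
        c = np.sum(ranks * north[idx], axis=1)
        s = np.sum(ranks * east[idx], axis=1)
        resultant = np.hypot(c, s)
        ok = resultant >= _ZERO_RESULTANT_TOL
        n_redrawn += int(np.count_nonzero(~ok))
        k = int(np.count_nonzero(ok))
        boot_dirs[filled : filled + k] = np.rad2deg(np.arctan2(s[ok], c[ok])) % 360.0
        filled += k
    dev = signed_angle_diff(boot_dirs, mv_hat)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(dev, [alpha / 2.0, 1.0 - alpha / 2.0])
    q_lo = min(float(q_lo), 0.0)  # keep the point estimate on the arc
    q_hi = max(float(q_hi), 0.0)
    return ConfidenceArc(
        ci_low=wrap_degrees(mv_hat + q_lo),
        ci_high=wrap_degrees(mv_hat + q_hi),
        n_redrawn=n_redrawn,
    )


@dataclass(frozen=True)
class GroupOrientation:
    """Group-level orientation summary for one phase.

    ``mv_dir`` is the rank-weighted mean direction, ``rstar`` Moore's
    modified Rayleigh statistic, ``p_mc`` its Monte-Carlo p-value, and
    ``ci_low``/``ci_high`` the bounds of the ``level`` confidence arc
    (clockwise from low to high).
    """

    phase_id: str
    n: int
    mv_dir: float
    rstar: float
    p_mc: float
    crit_05: float
    crit_01: float
    ci_low: float
    ci_high: float

    @property
    def sig_05(self) -> bool:
        return self.p_mc < 0.05

    @property
    def sig_01(self) -> bool:
        return self.p_mc < 0.01
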