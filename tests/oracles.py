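"""Independent brute-force oracles and small builders shared by tests.

The oracle implementations deliberately share no code with the package:
explicit loops, sort-based ranking, and a literal step-up evaluation.
"""

from __future__ import annotations

import numpy as np

from tetherflight import IndividualVector


def make_vectors(dirs, rs, phase="I"):
    return [
        IndividualVector(f"m{i}", phase, float(d), float(r), 100, 100 * r * r, 0.5)
        for i, (d, r) in enumerate(zip(dirs, rs))
    ]


def brute_force_moore(dirs_deg, rs):
    """Rank-weighted resultant via explicit loops and average ranks."""
    n = len(dirs_deg)
    order = sorted(range(n), key=lambda i: rs[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and rs[order[j + 1]] == rs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    c = s = 0.0
    for i in range(n):
        c += ranks[i] * np.cos(np.deg2rad(dirs_deg[i]))
        s += ranks[i] * np.sin(np.deg2rad(dirs_deg[i]))
    rstar = np.sqrt(c * c + s * s) / n**1.5
    mv = np.rad2deg(np.arctan2(s, c)) % 360.0
    return mv, rstar


def brute_force_bh(p):
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
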