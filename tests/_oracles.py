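"""Independent brute-force oracles used by several test modules.

These deliberately re-derive expected values by enumeration rather than
calling the implementation paths they check.
"""

from itertools import combinations as subsets

import numpy as np
from scipy import stats


def enumeration_pvalue(a: int, b: int, lib_a: float, lib_b: float) -> float:
    """Two-sided conditional binomial p by full outcome enumeration."""
    n = a + b
    if n == 0:
        return 1.0
    q = lib_b / (lib_a + lib_b)
    pmf = stats.binom.pmf(np.arange(n + 1), n, q)
    return float(min(1.0, pmf[pmf <= pmf[b] * (1 + 1e-7)].sum()))


def brute_force_scores(lists, combos=None, n_grid=None):
    """Explicit top-n set intersections for every combination and cutoff.

    Mirrors the documented tie-breaking (fewest lists, then lexicographic
    ids, then smallest cutoff) but computes observed sets by enumeration.
    Returns gene_id -> (score, k, combination tuple, cutoff).
    """
    g = lists[0].universe_size
    by_id = {l.experiment_id: l for l in lists}
    if combos is None:
        ids = sorted(by_id)
        combos = [c for size in range(2, len(ids) + 1)
                  for c in subsets(ids, size)]
    best = {gid: (0.0, 0, (), 0) for l in lists for gid in l.gene_ids}
    for combo in sorted(combos, key=lambda c: (len(c), c)):
        members = [by_id[i] for i in combo]
        shortest = min(len(m) for m in members)
        grid = (
            range(1, shortest + 1)
            if n_grid is None
            else sorted({n for n in n_grid if 1 <= n <= shortest})
        )
        k = len(members)
        for n in grid:
            inter = set(members[0].gene_ids[:n])
            for m in members[1:]:
                inter &= set(m.gene_ids[:n])
            if not inter:
                continue
            enr = len(inter) / (g * (n / g) ** k)
            for gid in inter:
                if enr > best[gid][0]:
                    best[gid] = (enr, k, combo, n)
    return best
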