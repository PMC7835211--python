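"""Independent brute-force oracles used by the test suite.

Each oracle is written from the textbook definition of the quantity it
checks, never from the package's implementation, so the two routes stay
independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def bh_stepup_bruteforce(p):
    """Benjamini-Hochberg step-up by literal definition.

    Sort p ascending; q at sorted position i (1-based) is
    ``min_{j >= i} min(1, m * p_(j) / j)``; undo the sort.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, m * p_sorted[j] / (j + 1)) for j in range(i, m)
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def running_es_bruteforce(ranked, members):
    """Classic KS-style enrichment score by walking the full list.

    Steps +1/Nh at members, -1/(N-Nh) otherwise; returns the running-sum
    value of largest magnitude, taking the first on a magnitude tie,
    together with its walk index.
    """
    members = set(members)
    n = len(ranked)
    nh = sum(1 for g in ranked if g in members)
    assert 0 < nh < n
    run = 0.0
    best = 0.0
    best_idx = -1
    walk = []
    for i, g in enumerate(ranked):
        run += 1.0 / nh if g in members else -1.0 / (n - nh)
        walk.append(run)
        if abs(run) > abs(best) + 1e-12:  # same tie convention: first extremum wins
            best = run
            best_idx = i
    return best, best_idx, walk


def manova_pillai_p_reference(joint: pd.DataFrame, members) -> float:
    """Two-group MANOVA p-value from statsmodels (reference implementation)."""
    from statsmodels.multivariate.manova import MANOVA

    data = joint[["r1", "r2"]].copy()
    data["member"] = joint["gene_id"].isin(set(members)).astype(int)
    fit = MANOVA.from_formula("r1 + r2 ~ member", data=data)
    stats = fit.mv_test().results["member"]["stat"]
    return float(stats.loc["Pillai's trace", "Pr > F"])
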