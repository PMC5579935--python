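"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive algorithms (full enumeration, quadratic
scans) and share no code paths with the package internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


# -- Dollo parsimony ---------------------------------------------------------

def count_losses(node, present: set) -> int:
    """Minimum number of loss events for a gain at ``node``.

    Each maximal all-absent subtree below the gain node costs one loss.
    """

    def rec(n):
        if n.is_leaf():
            return 0, n.taxon.label not in present
        results = [rec(c) for c in n.child_nodes()]
        if all(absent for _, absent in results):
            return 0, True
        cost = sum(1 if absent else c for c, absent in results)
        return cost, False

    cost, absent = rec(node)
    assert not absent, "gain node must cover at least one present leaf"
    return cost


def dollo_brute_force(tree, present):
    """Enumerate every node as the single gain point; return the
    minimum-loss placement (ties broken toward the most recent node)."""
    present = set(present)
    best = None
    for node in tree.nodes():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if not present <= leaves:
            continue
        losses = count_losses(node, present)
        key = (losses, node.age_my)
        if best is None or key < best[0]:
            best = (key, node)
    assert best is not None
    return best[1], best[0][0]


# -- rank statistics ---------------------------------------------------------

def rank_pearson(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def exact_mwu_two_sided_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data).

    Two-sided p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    n1 = x.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(pooled.size), n1):
        r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        us.append(r)
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def exact_pairing_p(ages, target_age_sets) -> tuple[float, float]:
    """Exact permutation p for the mean fraction-of-targets-older statistic.

    Enumerates all m! pairings of miRNA ages with target-age sets.
    Returns (observed statistic, P(null >= observed) including the
    identity pairing).
    """
    m = len(ages)

    def frac(age, t):
        t = np.asarray(t, dtype=float)
        return float(np.mean(t > age))

    observed = np.mean([frac(ages[i], target_age_sets[i]) for i in range(m)])
    stats_all = []
    for perm in itertools.permutations(range(m)):
        stats_all.append(np.mean([frac(ages[i], target_age_sets[perm[i]]) for i in range(m)]))
    stats_all = np.array(stats_all)
    return float(observed), float(np.mean(stats_all >= observed - 1e-12))


def van_elteren_exact(values, group, stratum) -> tuple[float, float, float]:
    """Exact restricted-permutation reference for the stratified rank test.

    Recomputes the weighted centered rank-sum statistic T and its
    standardization, then enumerates all within-stratum group-label
    assignments to get the exact two-sided p of |z|.
    Returns (z_obs, p_lo, p_hi): exact P(|z| > |z_obs|) and
    P(|z| >= |z_obs|), bracketing the discrete point mass.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=bool)
    stratum = np.asarray(stratum)
    strata = [s for s in dict.fromkeys(stratum.tolist())]
    per = []
    var = 0.0
    for s in strata:
        mask = stratum == s
        g = group[mask]
        if g.all() or not g.any():
            continue
        v = values[mask]
        ranks = stats.rankdata(v)
        n = v.size
        n1 = int(g.sum())
        mean = n1 * (n + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie = float(np.sum(counts**3 - counts))
        v_s = n1 * (n - n1) / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        w = 1.0 / (n + 1.0)
        var += w**2 * v_s
        obs = w * (float(ranks[g].sum()) - mean)
        contribs = []
        for combo in itertools.combinations(range(n), n1):
            contribs.append(w * (float(ranks[list(combo)].sum()) - mean))
        per.append((obs, contribs))
    sd = math.sqrt(var)
    t_obs = sum(o for o, _ in per)
    z_obs = t_obs / sd if sd > 0 else 0.0
    totals = [0.0]
    for _, contribs in per:
        totals = [t + c for t in totals for c in contribs]
    zs = np.array(totals) / sd if sd > 0 else np.zeros(len(totals))
    p_hi = float(np.mean(np.abs(zs) >= abs(z_obs) - 1e-9))
    p_lo = float(np.mean(np.abs(zs) > abs(z_obs) + 1e-9))
    return float(z_obs), p_lo, p_hi


# -- intervals ---------------------------------------------------------------

def quadratic_overlap(query, subjects, min_frac=0.0):
    """O(n*m) reference for half-open interval overlap detection."""
    out = []
    qlen = query.end - query.start
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        ol = min(query.end, s.end) - max(query.start, s.start)
        if ol > 0 and ol >= min_frac * qlen:
            out.append(s)
    return sorted(out, key=lambda iv: (iv.start, iv.end))
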