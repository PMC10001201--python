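"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: brute-force grid
search for median-effect fitting, naive O(n^3) agglomeration for average
linkage, a permutation test for group separation, and the textbook
sum-of-squares ANOVA formulas.
"""

from __future__ import annotations

import numpy as np


def grid_search_median_effect(doses, fa, m_center, dm_center, span=2.0, n_grid=561):
    """Exhaustive search minimizing the linearized squared error in (m, Dm)."""
    x = np.log10(np.asarray(doses, float))
    y = np.log10(np.asarray(fa, float) / (1.0 - np.asarray(fa, float)))
    ms = m_center * np.exp(np.linspace(np.log(1 / span), np.log(span), n_grid))
    dms = dm_center * np.exp(np.linspace(np.log(1 / span), np.log(span), n_grid))
    M, D = np.meshgrid(ms, dms, indexing="ij")
    pred = M[..., None] * (x[None, None, :] - np.log10(D)[..., None])
    sse = ((y[None, None, :] - pred) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(ms[i]), float(dms[j])


def naive_average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration; cluster distance = mean of original pairwise
    distances (UPGMA).  Returns [(leafset_a, leafset_b, height), ...]."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    active = list(range(n))
    next_id = n
    merges = []
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                h = float(np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        merges.append((clusters[a], clusters[b], h))
        clusters[next_id] = clusters[a] | clusters[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return merges


def linkage_to_merges(linkage_matrix: np.ndarray):
    """Convert a scipy linkage matrix to [(leafset_a, leafset_b, height), ...]."""
    n = linkage_matrix.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, h, _) in enumerate(linkage_matrix):
        sa, sb = members[int(a)], members[int(b)]
        merges.append((sa, sb, float(h)))
        members[n + k] = sa | sb
    return merges


def same_merge_sequence(merges_x, merges_y, atol=1e-9):
    """Do two agglomerations perform identical merges at identical heights?"""
    if len(merges_x) != len(merges_y):
        return False
    for (a1, b1, h1), (a2, b2, h2) in zip(merges_x, merges_y):
        if {a1, b1} != {a2, b2} or abs(h1 - h2) > atol:
            return False
    return True


def permutation_test_two_groups(x, y, n_perm=2000, seed=0):
    """Two-sided permutation p-value for a difference in group means."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    observed = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[: len(x)].mean() - perm[len(x):].mean()) >= observed
    return (count + 1) / (n_perm + 1)


def anova_f_and_p(groups):
    """One-way fixed-effects ANOVA from the sum-of-squares formulas."""
    from scipy.stats import f as f_dist

    groups = [np.asarray(g, float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    return f_stat, float(f_dist.sf(f_stat, df_between, df_within))
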