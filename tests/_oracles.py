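"""Brute-force reference implementations used only as test oracles.

These deliberately avoid numpy set algebra and the package's own code
paths: masks become Python sets of voxel-coordinate tuples and statistics
are computed by explicit enumeration, so agreement with the library is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def voxel_set(mask_data: np.ndarray) -> set[tuple[int, int, int]]:
    return {tuple(int(v) for v in idx) for idx in np.argwhere(mask_data)}


def brute_uncertainty_voxels(mask_arrays) -> int:
    sets = [voxel_set(m) for m in mask_arrays]
    union = set().union(*sets)
    inter = sets[0].intersection(*sets[1:])
    return len(union - inter)


def _brute_dice_pct(a: set, b: set) -> float:
    if not a and not b:
        return 100.0
    if not a or not b:
        return 0.0
    return 100.0 * len(a & b) / ((len(a) + len(b)) / 2.0)


def brute_pairwise_dsi(mask_arrays) -> float:
    sets = [voxel_set(m) for m in mask_arrays]
    terms = [
        _brute_dice_pct(sets[i], sets[j])
        for i, j in itertools.combinations(range(len(sets)), 2)
    ]
    return sum(terms) / len(terms)


def brute_agreement(algo_arrays, ref_arrays) -> tuple[float, float]:
    algo = [voxel_set(m) for m in algo_arrays]
    refs = [voxel_set(m) for m in ref_arrays]
    inter = refs[0].intersection(*refs[1:])
    union = set().union(*refs)
    vs_inter = sum(_brute_dice_pct(a, inter) for a in algo) / len(algo)
    vs_union = sum(_brute_dice_pct(a, union) for a in algo) / len(algo)
    return vs_inter, vs_union


def brute_wilcoxon_p(diffs) -> float:
    """Two-sided signed-rank p by full enumeration of all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product([False, True], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_spearman_rho(x, y) -> float:
    """Pearson correlation of midranks, ranks assigned by direct enumeration."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx = midranks(x)
    ry = midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def brute_kruskal_h(groups) -> float:
    """Tie-corrected H from the rank-sum formula, evaluated directly."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = rankdata(pooled)
    n_total = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g)
        r_g = ranks[start : start + g.size]
        start += g.size
        h += g.size * (r_g.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction
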