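"""Statistical comparisons and score consolidation for the nodule study.

Covers the four pieces of statistical machinery the evaluation uses:

* consolidation of four raters' ordinal characteristic scores into one
  score per nodule (majority, then population-frequency tie-break);
* the two-sided Wilcoxon signed-rank test comparing paired robustness
  metrics between methods (exact enumeration for small n, tie-corrected
  normal approximation otherwise);
* Spearman rank correlation with a t-test on the coefficient, for
  characteristics on a continuous ordinal scale;
* the Kruskal-Wallis H test for purely categorical characteristics.

Raw two-sided p-values are reported per category with no multiplicity
correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SCORE_RANGES",
    "CATEGORICAL_CATEGORIES",
    "CharacteristicScores",
    "ConsolidatedScore",
    "WilcoxonResult",
    "consolidate_scores",
    "wilcoxon_signed_rank",
    "spearman_with_ttest",
    "kruskal_wallis",
]

# Legal score ranges for the nine nodule characteristics (standard
# radiological annotation scales: most run 1-5; internal structure 1-4,
# calcification 1-6).
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "subtlety": (1, 5),
    "internal_structure": (1, 4),
    "calcification": (1, 6),
    "sphericity": (1, 5),
    "margin": (1, 5),
    "lobulation": (1, 5),
    "spiculation": (1, 5),
    "texture": (1, 5),
    "malignancy": (1, 5),
}

# Categories whose scale is a set of distinct appearances rather than an
# ordered continuum; these get Kruskal-Wallis instead of Spearman + t.
CATEGORICAL_CATEGORIES = frozenset({"internal_structure", "calcification"})


@dataclass
class CharacteristicScores:
    """Scores of one nodule: category -> four raters' integer scores."""

    scores: dict[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        for cat, ratings in self.scores.items():
            if cat not in SCORE_RANGES:
                raise ValueError(f"unknown characteristic category {cat!r}")
            lo, hi = SCORE_RANGES[cat]
            ratings = tuple(int(r) for r in ratings)
            if len(ratings) != 4:
                raise ValueError(f"{cat}: expected 4 ratings, got {len(ratings)}")
            if any(r < lo or r > hi for r in ratings):
                raise ValueError(f"{cat}: ratings {ratings} outside legal range {lo}-{hi}")
            self.scores[cat] = ratings


@dataclass(frozen=True)
class ConsolidatedScore:
    score: int
    rule_used: str  # "majority" or "population_tie_break"
    flagged: bool = False  # True when the lowest-score fallback decided
    category: str | None = None


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n: int  # pairs after dropping zero differences
    method: str  # "exact" or "normal"
    flagged: bool = False  # True when all differences were zero


def consolidate_scores(
    ratings,
    population_frequency: dict[int, int],
    category: str | None = None,
) -> ConsolidatedScore:
    """One score from four raters' scores.

    A unique modal score (which includes any >= 3-of-4 majority) wins
    outright.  When the mode is tied — e.g. ratings (4,4,2,2), or four
    distinct scores — the tied candidate assigned most frequently across
    the whole study population wins.  Should the population frequencies tie
    as well, the lowest score is returned and the result is flagged; this
    final fallback is a documented extension chosen for determinism.
    """
    ratings = tuple(int(r) for r in ratings)
    if len(ratings) != 4:
        raise ValueError(f"expected 4 ratings, got {len(ratings)}")
    if category is not None:
        lo, hi = SCORE_RANGES[category]
        if any(r < lo or r > hi for r in ratings):
            raise ValueError(f"ratings {ratings} outside legal range {lo}-{hi} for {category}")
    counts = Counter(ratings)
    top = max(counts.values())
    modes = sorted(s for s, c in counts.items() if c == top)
    if len(modes) == 1:
        return ConsolidatedScore(modes[0], "majority", False, category)
    missing = [s for s in modes if s not in population_frequency]
    if missing:
        raise ValueError(f"population_frequency lacks counts for candidate scores {missing}")
    best_freq = max(population_frequency[s] for s in modes)
    winners = [s for s in modes if population_frequency[s] == best_freq]
    return ConsolidatedScore(
        min(winners), "population_tie_break", len(winners) > 1, category
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n equiprobable sign assignments.

    Dynamic programming over doubled midranks (always integers), so tied
    absolute differences are handled exactly — equivalent to full sign
    enumeration without the 2^n cost.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    # dist[s] = number of sign assignments with doubled W+ == s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  For n <= 25 the exact null distribution
    of W+ is enumerated (ties included); for larger n a normal
    approximation with tie-corrected variance is used.  If every
    difference is zero the test is vacuous: p = 1, flagged.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must share one length, got {a.shape} vs {b.shape}")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", flagged=True)
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX:
        p = _signed_rank_exact_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:  # all differences tied at one magnitude and sign-balanced edge case
        return WilcoxonResult(w_plus, 1.0, n, "normal", flagged=True)
    z = (w_plus - mu) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n, "normal")


def spearman_with_ttest(x, y) -> tuple[float, float]:
    """Spearman rho (midranks) with a t-test for rho != 0.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom,
    the conventional significance test for a rank correlation on a
    continuous ordinal scale.  Perfect correlations give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation is undefined for a constant variable")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-squared p (k - 1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # Identical values across all groups: H is 0 by definition
        # (scipy raises here instead).
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)
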