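"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different route from the library code:
naive pairwise-max agglomeration instead of scipy's NN-chain linkage, a
dense symmetric eigendecomposition instead of SVD, exhaustive enumeration
of the within-day permutation group instead of Monte-Carlo sampling, and a
quadratic scan over every (gene, peak) pair instead of interval trees.
"""

from __future__ import annotations

import itertools

import numpy as np


def complete_linkage_partition(D: np.ndarray, cut_height: float) -> set[frozenset]:
    """Naive complete-linkage agglomeration, cut at a fixed height.

    Maintains the inter-cluster distance matrix explicitly and merges the
    closest pair (lexicographically smallest on exact ties) while the
    minimum inter-cluster distance stays <= cut_height. Complete linkage is
    monotone, so stopping at the first merge above the cut equals cutting
    the full tree there.
    """
    n = len(D)
    D = D.astype(float).copy()
    members: list[list[int] | None] = [[i] for i in range(n)]
    active = list(range(n))
    np.fill_diagonal(D, np.inf)
    while len(active) > 1:
        best = (np.inf, -1, -1)
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                d = D[a, b]
                if d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        if d > cut_height:
            break
        # complete linkage: distance to the union is the pairwise max
        D[a, :] = np.maximum(D[a, :], D[b, :])
        D[:, a] = D[a, :]
        D[a, a] = np.inf
        members[a] = members[a] + members[b]  # type: ignore[operator]
        members[b] = None
        active.remove(b)
    return {frozenset(members[a]) for a in active}  # type: ignore[arg-type]


def pc1_scores(X: np.ndarray) -> np.ndarray:
    """First principal-component scores of row-standardized X via eigh."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    Z = (X - mu) / sd
    gram = Z.T @ Z
    w, V = np.linalg.eigh(gram)
    return V[:, -1]


def exact_within_day_permutation_p(
    eigengene: np.ndarray,
    genotype: np.ndarray,
    day: np.ndarray,
    early_days: tuple[float, ...],
    knockout: str = "knockout",
    control: str = "control",
) -> float:
    """Exact one-sided p over all within-day genotype relabellings."""
    early = np.isin(day, np.asarray(early_days, dtype=float))

    def stat(g: np.ndarray) -> float:
        ko = early & (g == knockout)
        ct = early & (g == control)
        return eigengene[ko].mean() - eigengene[ct].mean()

    observed = stat(genotype)
    day_groups = [np.flatnonzero(day == d) for d in np.unique(day)]
    per_day_options = []
    for idx in day_groups:
        labels = genotype[idx]
        opts = sorted({p for p in itertools.permutations(labels)})
        per_day_options.append((idx, opts))
    count = total = 0
    for combo in itertools.product(*(opts for _, opts in per_day_options)):
        g = genotype.copy()
        for (idx, _), labs in zip(per_day_options, combo):
            g[idx] = labs
        total += 1
        if stat(g) >= observed - 1e-12:
            count += 1
    return count / total


def brute_force_marked(
    tss_pos: np.ndarray,
    tss_chrom: np.ndarray,
    peaks: list[tuple[str, int, int]],
    window_bp: int,
) -> np.ndarray:
    """Quadratic (gene x peak) half-open overlap scan."""
    out = np.zeros(len(tss_pos), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(tss_chrom, tss_pos)):
        lo, hi = max(0, int(pos) - window_bp), int(pos) + window_bp
        for pchrom, start, end in peaks:
            if pchrom == chrom and start < hi and end > lo:
                out[i] = True
                break
    return out
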