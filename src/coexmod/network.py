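"""Co-expression module detection: correlation network, complete-linkage
dendrogram with a static cut, eigengene summaries, eigengene-similarity
merging, and kME-based module membership.

The procedure has four steps. (1) Pearson correlations are computed for
all probe pairs across all retained samples. (2) Probes are clustered by
complete-linkage agglomeration using 1 - cor as the distance. (3) The
dendrogram is cut at a static height — by default the height corresponding
to the top 2% of pairwise correlations — and clusters of at least
``min_size`` (default 10) members are summarized by their first principal
component ("eigengene"). (4) Modules whose eigengenes correlate above a
merge threshold (default 0.85, strict) are merged greedily in order of
highest correlation, recomputing eigengenes after every merge.

Finally, every probe's module membership strength (kME) is its Pearson
correlation with each module eigengene; a probe is assigned to the module
of its strongest *positive* kME provided the correlation is significant
after Bonferroni correction over (number of probes x number of modules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .datasets import ExpressionDataset, ModuleSet


@dataclass
class CorrelationModel:
    """All-pairs probe Pearson correlations and the derived distance."""

    correlation: pd.DataFrame

    @property
    def distance(self) -> pd.DataFrame:
        return 1.0 - self.correlation

    @property
    def probe_ids(self) -> pd.Index:
        return self.correlation.index


def correlation_model(
    data: ExpressionDataset, on_zero_variance: str = "error"
) -> CorrelationModel:
    """Pearson correlation of every probe pair across all samples.

    Zero-variance probes have no defined correlation; they are either
    rejected (``on_zero_variance="error"``) or dropped (``"drop"``).
    """
    if data.n_samples < 3:
        raise ValueError("correlation model needs >= 3 samples")
    X = data.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = data.probe_ids[sd < 1e-12].tolist()
    if flat:
        if on_zero_variance == "drop":
            keep = sd >= 1e-12
            X = X[keep]
            index = data.probe_ids[keep]
        else:
            raise ValueError(f"zero-variance probes: {flat}")
    else:
        index = data.probe_ids
    C = np.corrcoef(X)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2
    return CorrelationModel(pd.DataFrame(C, index=index, columns=index))


def static_cut_height(model: CorrelationModel, top_fraction: float = 0.02) -> float:
    """Dendrogram height keeping the top fraction of pairwise correlations.

    Returns ``1 - q`` where q is the (1 - top_fraction) quantile (linear
    interpolation between order statistics) of the upper-triangle
    off-diagonal correlations, signed — negative correlations count as
    small, not large.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    C = model.correlation.to_numpy()
    iu = np.triu_indices_from(C, k=1)
    pairs = C[iu]
    if np.ptp(pairs) < 1e-12:
        warnings.warn("all pairwise correlations are equal; cut height is degenerate")
        return float(1.0 - pairs[0])
    q = np.quantile(pairs, 1.0 - top_fraction, method="linear")
    return float(1.0 - q)


def cluster_and_cut(
    model: CorrelationModel, cut_height: float, min_size: int = 10
) -> ModuleSet:
    """Complete-linkage agglomeration on 1 - cor, cut at a fixed height.

    A cluster is a maximal dendrogram subtree whose internal merge heights
    are all <= ``cut_height``. Clusters below ``min_size`` members are left
    unassigned. Modules are named M1, M2, ... in decreasing size order
    (ties broken by first probe position for determinism).
    """
    if not 0.0 <= cut_height <= 2.0:
        raise ValueError("cut_height must lie in [0, 2] (1 - cor distances)")
    D = model.distance.to_numpy()
    np.fill_diagonal(D, 0.0)
    condensed = squareform(np.maximum(D, 0.0), checks=False)
    Z = linkage(condensed, method="complete")
    flat = fcluster(Z, t=cut_height, criterion="distance")

    probe_ids = model.probe_ids
    labels = pd.Series([pd.NA] * len(probe_ids), index=probe_ids, dtype="object")
    clusters: dict[int, np.ndarray] = {
        c: np.flatnonzero(flat == c) for c in np.unique(flat)
    }
    big = [c for c, idx in clusters.items() if len(idx) >= min_size]
    big.sort(key=lambda c: (-len(clusters[c]), clusters[c][0]))
    for rank, c in enumerate(big, start=1):
        labels.iloc[clusters[c]] = f"M{rank}"
    return ModuleSet(labels=labels, cut_height=float(cut_height), min_size=min_size)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (X - mu) / sd


def compute_eigengene(
    data: ExpressionDataset, member_probes: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized submatrix.

    Probes are standardized (zero mean, unit variance) before the
    decomposition; the per-sample PC1 scores are rescaled to unit variance.
    The sign is fixed so the eigengene correlates non-negatively with the
    mean standardized member profile; on an exact tie the sign making the
    first nonzero probe loading positive is used. Also returns the fraction
    of standardized variance the component explains.
    """
    if len(member_probes) < 2:
        raise ValueError("eigengene needs >= 2 member probes")
    if data.n_samples < 3:
        raise ValueError("eigengene needs >= 3 samples")
    X = _standardize_rows(data.values.loc[member_probes].to_numpy(dtype=float))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = Vt[0]
    var_explained = float(S[0] ** 2 / np.sum(S**2))

    mean_profile = X.mean(axis=0)
    align = float(np.dot(scores, mean_profile))
    if abs(align) > 1e-12:
        sign = np.sign(align)
    else:
        loadings = U[:, 0]
        nz = loadings[np.abs(loadings) > 1e-12]
        sign = np.sign(nz[0]) if len(nz) else 1.0
    scores = sign * scores
    sd = scores.std(ddof=1)
    if sd > 1e-12:
        scores = scores / sd
    return pd.Series(scores, index=data.sample_ids), var_explained


def attach_eigengenes(data: ExpressionDataset, modules: ModuleSet) -> ModuleSet:
    """Compute and store the eigengene of every labelled module."""
    names = sorted(
        {m for m in modules.labels.dropna().unique()},
        key=lambda n: int(n[1:]) if n[1:].isdigit() else n,
    )
    rows, ve = {}, {}
    for name in names:
        eig, var = compute_eigengene(data, modules.members(name))
        rows[name] = eig
        ve[name] = var
    modules.eigengenes = pd.DataFrame(rows).T.reindex(names)
    modules.eigengenes.index.name = "module"
    modules.var_explained = ve
    return modules


def merge_modules(
    data: ExpressionDataset, modules: ModuleSet, threshold: float = 0.85
) -> ModuleSet:
    """Greedily merge modules whose eigengenes correlate above threshold.

    Repeatedly find the module pair with the highest eigengene correlation;
    if it strictly exceeds ``threshold`` merge the pair (into the
    lower-numbered label), recompute that eigengene, and continue until no
    pair exceeds the threshold. Every merge is appended to ``merge_log``.
    """
    if modules.eigengenes is None:
        modules = attach_eigengenes(data, modules)
    labels = modules.labels.copy()
    eig = {m: modules.eigengenes.loc[m] for m in modules.eigengenes.index}
    ve = dict(modules.var_explained)
    log: list[dict] = []

    while len(eig) > 1:
        names = sorted(eig, key=lambda n: int(n[1:]) if n[1:].isdigit() else n)
        E = np.vstack([eig[n].to_numpy() for n in names])
        C = np.corrcoef(E)
        iu = np.triu_indices(len(names), k=1)
        best = np.argmax(C[iu])
        best_cor = float(C[iu][best])
        if best_cor <= threshold:
            break
        a, b = names[iu[0][best]], names[iu[1][best]]
        keep, drop = sorted([a, b], key=lambda n: int(n[1:]) if n[1:].isdigit() else n)
        labels[labels == drop] = keep
        members = list(labels.index[labels == keep])
        eig[keep], ve[keep] = compute_eigengene(data, members)
        del eig[drop], ve[drop]
        log.append({"merged": [keep, drop], "into": keep, "correlation": best_cor})

    names = sorted(eig, key=lambda n: int(n[1:]) if n[1:].isdigit() else n)
    out = ModuleSet(
        labels=labels,
        cut_height=modules.cut_height,
        min_size=modules.min_size,
        eigengenes=pd.DataFrame({n: eig[n] for n in names}).T.reindex(names),
        var_explained={n: ve[n] for n in names},
        merge_log=modules.merge_log + log,
    )
    out.eigengenes.index.name = "module"
    return out


@dataclass
class MembershipTable:
    """kME correlations, p-values, and Bonferroni-gated assignments.

    ``kme``/``p_value`` are probe x module DataFrames; ``assigned`` maps a
    probe to its module (or NA). ``bonferroni_alpha`` is the effective
    per-test threshold alpha / (n_probes * n_modules).
    """

    kme: pd.DataFrame
    p_value: pd.DataFrame
    assigned: pd.Series
    bonferroni_alpha: float

    def to_frame(self) -> pd.DataFrame:
        best = self.kme.idxmax(axis=1)
        rows = pd.DataFrame(
            {
                "module": self.assigned,
                "best_module": best,
                "kME": self.kme.to_numpy()[
                    np.arange(len(self.kme)), self.kme.columns.get_indexer(best)
                ],
                "p_value": self.p_value.to_numpy()[
                    np.arange(len(self.p_value)), self.p_value.columns.get_indexer(best)
                ],
            }
        )
        rows.index.name = "probe_id"
        return rows


def correlation_p_value(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t transform (n-2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return np.minimum(p, 1.0)


def assign_membership(
    data: ExpressionDataset, modules: ModuleSet, alpha: float = 0.05
) -> MembershipTable:
    """Assign every probe by its strongest positive, Bonferroni-significant kME.

    All probes — including those never clustered or in sub-min_size
    clusters — receive kME against every eigengene. A probe is assigned to
    the module of its largest kME iff that kME is positive and its
    two-sided p-value beats alpha / (n_probes * n_modules); otherwise it is
    left unassigned.
    """
    if modules.eigengenes is None or modules.eigengenes.empty:
        raise ValueError("modules must carry eigengenes (none were computed)")
    n = data.n_samples
    if n <= 2:
        raise ValueError("membership requires > 2 samples")
    X = _standardize_rows(data.values.to_numpy(dtype=float))
    E = _standardize_rows(modules.eigengenes.to_numpy(dtype=float))
    kme = (X @ E.T) / (n - 1)
    kme = np.clip(kme, -1.0, 1.0)
    p = correlation_p_value(kme, n)

    names = list(modules.eigengenes.index)
    threshold = alpha / (data.n_probes * len(names))
    best_idx = np.argmax(kme, axis=1)
    rows = np.arange(len(best_idx))
    ok = (kme[rows, best_idx] > 0) & (p[rows, best_idx] < threshold)
    assigned = pd.Series(
        [names[i] if keep else pd.NA for i, keep in zip(best_idx, ok)],
        index=data.probe_ids,
        dtype="object",
    )
    return MembershipTable(
        kme=pd.DataFrame(kme, index=data.probe_ids, columns=names),
        p_value=pd.DataFrame(p, index=data.probe_ids, columns=names),
        assigned=assigned,
        bonferroni_alpha=threshold,
    )
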