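"""Knockout-derepression screen over module eigengenes.

A module "requires the repressor" if its eigengene is elevated in knockout
samples relative to controls early in the differentiation time course. The
screen formalizes that as a per-module contrast statistic —

    mean eigengene (knockout, early days) - mean eigengene (control, early days)

— with a one-sided permutation p-value in which genotype labels are
shuffled *within each day*, preserving the time-course blocking. A module
is flagged when its statistic is positive and p < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MembershipTable

EARLY_DAYS_DEFAULT = (0, 1, 2)


@dataclass
class DerepressionScreenResult:
    """Per-module contrast statistics, permutation p-values and flags."""

    table: pd.DataFrame  # index module; columns statistic, p_value, flagged
    early_days: tuple[float, ...]
    n_permutations: int
    seed: int
    alpha: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def _contrast(
    E: np.ndarray, genotype: np.ndarray, early: np.ndarray, knockout: str, control: str
) -> np.ndarray:
    ko = early & (genotype == knockout)
    ct = early & (genotype == control)
    return E[:, ko].mean(axis=1) - E[:, ct].mean(axis=1)


def derepression_screen(
    eigengenes: pd.DataFrame,
    sample_meta: pd.DataFrame,
    early_days: tuple[float, ...] = EARLY_DAYS_DEFAULT,
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    knockout: str = "knockout",
    control: str = "control",
) -> DerepressionScreenResult:
    """Screen eigengenes for knockout-specific early elevation.

    ``eigengenes`` is module x sample; ``sample_meta`` must give each
    sample's genotype and day. Both genotypes must be present at every
    early day. The p-value uses the add-one estimator
    (1 + #{permuted >= observed}) / (1 + n_permutations), so it is never 0.
    """
    meta = sample_meta.loc[eigengenes.columns]
    genotype = meta["genotype"].to_numpy()
    day = meta["day"].to_numpy(dtype=float)
    early = np.isin(day, np.asarray(early_days, dtype=float))
    if not early.any():
        raise ValueError(f"no samples at early days {early_days}")
    for d in early_days:
        present = set(genotype[day == d])
        if d in day and not {knockout, control} <= present:
            raise ValueError(
                f"day {d}: need both genotypes at every early day, found {sorted(present)}"
            )

    E = eigengenes.to_numpy(dtype=float)
    observed = _contrast(E, genotype, early, knockout, control)

    rng = np.random.default_rng(seed)
    day_groups = [np.flatnonzero(day == d) for d in np.unique(day)]
    exceed = np.zeros(len(E), dtype=int)
    perm_geno = genotype.copy()
    for _ in range(n_permutations):
        for idx in day_groups:
            perm_geno[idx] = genotype[idx][rng.permutation(len(idx))]
        stat = _contrast(E, perm_geno, early, knockout, control)
        exceed += stat >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)

    table = pd.DataFrame(
        {
            "statistic": observed,
            "p_value": p,
            "flagged": (observed > 0) & (p < alpha),
        },
        index=eigengenes.index,
    )
    return DerepressionScreenResult(
        table=table,
        early_days=tuple(early_days),
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
    )


def top_members(
    membership: MembershipTable, module: str, k: int = 15
) -> pd.DataFrame:
    """The k assigned members of a module with the highest kME, descending.

    Ties in kME are broken by probe ID so the ranking is deterministic. If
    the module has fewer than k assigned members the whole module is
    returned with a warning.
    """
    if module not in membership.kme.columns:
        raise KeyError(f"unknown module {module!r}")
    members = membership.assigned.index[membership.assigned == module]
    if len(members) == 0:
        raise ValueError(f"module {module!r} has no assigned members")
    if k > len(members):
        warnings.warn(
            f"requested top {k} of module {module!r} but only "
            f"{len(members)} members are assigned; returning all"
        )
    kme = membership.kme.loc[members, module]
    # stable sort after ordering by probe ID => kME ties break deterministically
    ranked = pd.DataFrame({"kME": kme}).sort_index().sort_values(
        "kME", ascending=False, kind="mergesort"
    )
    ranked.index.name = "probe_id"
    return ranked.head(k)
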