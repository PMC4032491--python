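"""Expression loading, quantile normalization and sample-outlier QC.

Quantile normalization forces every sample onto the common reference
distribution (the across-sample mean of sorted values); ties within a
sample receive the mean of the reference values at their tied ranks.
Outlier detection implements the standardized-connectivity rule: a
sample's connectivity is the sum of its inter-sample Pearson correlations,
and samples whose connectivity z-score falls below ``z_cut`` (default -2)
are removed, iterating until no sample falls below the cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

log = logging.getLogger(__name__)


def read_expression(matrix_path, meta_path) -> ExpressionDataset:
    """Load a probe x sample TSV matrix and its sample metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    data = ExpressionDataset(values, meta)
    log.info("loaded expression matrix: %d probes x %d samples", *values.shape)
    return data


def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Map every sample onto the mean-of-sorted-vectors reference.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; the transform is idempotent and
    preserves within-sample rank order. Tied values get the mean of the
    reference entries at their tied ranks.
    """
    X = data.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        return ExpressionDataset(data.values.copy(), data.sample_meta.copy())

    reference = np.sort(X, axis=0).mean(axis=1)
    # prefix sums of the reference let a tied run of values take the mean of
    # the reference entries over exactly its occupied sorted positions
    out = np.empty_like(X)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(n_samples):
        vals = X[:, j]
        sorted_vals = np.sort(vals)
        run_start = np.searchsorted(sorted_vals, vals, side="left") + 1  # 1-based
        run_end = np.searchsorted(sorted_vals, vals, side="right")
        out[:, j] = (ref_cum[run_end] - ref_cum[run_start - 1]) / (run_end - run_start + 1)

    return ExpressionDataset(
        pd.DataFrame(out, index=data.probe_ids, columns=data.sample_ids),
        data.sample_meta.copy(),
    )


@dataclass
class QCReport:
    """Outcome of iterative standardized-connectivity outlier removal.

    ``rounds`` holds, per iteration, each retained sample's connectivity
    K_i = sum_{j != i} cor(sample_i, sample_j) and its z-score, plus the
    samples removed that round. ``excluded`` collects removals in order with
    a reason string.
    """

    z_cut: float
    rounds: list[dict] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [s for s, _ in self.excluded]

    def to_dict(self) -> dict:
        return {
            "z_cut": self.z_cut,
            "rounds": self.rounds,
            "excluded": [{"sample_id": s, "reason": r} for s, r in self.excluded],
        }


def detect_sample_outliers(
    data: ExpressionDataset,
    z_cut: float = -2.0,
    max_rounds: int = 5,
    exclude_samples: list[str] | None = None,
) -> QCReport:
    """Iteratively flag low-connectivity sample outliers.

    An explicit ``exclude_samples`` list is honoured first (mirroring
    removal of samples for known technical reasons, e.g. hybridized on a
    different day), then rounds of z-score exclusion run on the remainder.
    If all samples within a round have identical profiles (sd of K is 0),
    every z is defined as 0 and nothing is removed.
    """
    if data.n_samples < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    report = QCReport(z_cut=z_cut)
    kept = list(data.sample_ids)
    for s in exclude_samples or []:
        if s not in kept:
            raise ValueError(f"exclude_samples: unknown sample ID {s!r}")
        kept.remove(s)
        report.excluded.append((s, "user-specified exclusion"))

    for rnd in range(1, max_rounds + 1):
        if len(kept) < 3:
            break
        X = data.values[kept].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X, rowvar=False)
        C = np.nan_to_num(C, nan=0.0)
        K = C.sum(axis=0) - np.diag(C)
        sd = K.std(ddof=1)
        z = np.zeros_like(K) if sd < 1e-12 else (K - K.mean()) / sd
        removed = [kept[i] for i in np.flatnonzero(z < z_cut)]
        report.rounds.append(
            {
                "round": rnd,
                "connectivity": dict(zip(kept, K.round(6).tolist())),
                "z": dict(zip(kept, z.round(6).tolist())),
                "removed": removed,
            }
        )
        if not removed:
            break
        if len(removed) == len(kept):
            raise ValueError("outlier removal would exclude every sample")
        for s in removed:
            kept.remove(s)
            report.excluded.append((s, f"connectivity z < {z_cut} (round {rnd})"))
    if not kept:
        raise ValueError("outlier removal excluded every sample")
    return report


def apply_qc(
    data: ExpressionDataset, report: QCReport, renormalize: bool = True
) -> ExpressionDataset:
    """Drop excluded samples; optionally re-quantile-normalize the remainder."""
    kept = [s for s in data.sample_ids if s not in set(report.excluded_ids)]
    out = data.subset_samples(kept)
    if renormalize and report.excluded_ids:
        out = quantile_normalize(out)
    return out
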