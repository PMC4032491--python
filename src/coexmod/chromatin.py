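"""Promoter chromatin-state classification and gene-set enrichment.

A gene is "marked" for a histone modification if any peak of that mark
overlaps the symmetric half-open window [tss - window_bp, tss + window_bp)
around its transcription start site (default window 1,000 bp, strand does
not alter the window). The two marks H3K27me3 (repressive) and H3K4me3
(active) combine into four promoter states: bivalent (both), k27_only,
k4_only, unmarked. Enrichment of marking in a gene set against a universe
is summarized by counts, fractions, and a one-sided hypergeometric
over-representation p-value.

All coordinates are BED-dialect: 0-based, half-open. GFF input (1-based,
inclusive) is converted on read, taking the strand-aware feature start as
the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")
STATES = ("bivalent", "k27_only", "k4_only", "unmarked")


class BedFormatError(ValueError):
    """Malformed BED/GFF content, reported with a line number."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a >= 3 column BED file into a (chrom, start, end, ...) frame."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            if not chrom:
                raise BedFormatError(f"{path}:{lineno}: empty chromosome")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: start {start} >= end {end} (half-open intervals)"
                )
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            score = parts[4] if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=list(BED_COLUMNS))


def read_tss(path: str | Path) -> pd.DataFrame:
    """Read TSS positions from BED (single-base features) or GFF/GTF.

    Returns a frame indexed by gene ID with columns chrom, pos (0-based
    base position of the TSS) and strand. For GFF, the TSS is the
    strand-aware 5' end of each feature (start on '+', end on '-'),
    converted from 1-based inclusive to 0-based.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        return _read_tss_gff(path)
    bed = read_bed(path)
    wide = bed[bed["end"] - bed["start"] != 1]
    if len(wide):
        raise BedFormatError(
            f"{path}: TSS BED must contain single-base features; "
            f"{len(wide)} wider records found"
        )
    tss = pd.DataFrame(
        {"chrom": bed["chrom"], "pos": bed["start"], "strand": bed["strand"]},
    )
    tss.index = pd.Index(bed["name"], name="gene_id")
    _check_unique_genes(tss, path)
    return tss


def _read_tss_gff(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise BedFormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, _, start_s, end_s, _, strand, _, attrs = parts[:9]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise BedFormatError(f"{path}:{lineno}: start > end")
            gene_id = _gff_gene_id(attrs) or f"feature_{lineno}"
            # GFF is 1-based inclusive; 5' end depends on strand
            pos = (start - 1) if strand != "-" else (end - 1)
            rows.append((gene_id, chrom, pos, strand))
    tss = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"]).set_index(
        "gene_id"
    )
    _check_unique_genes(tss, path)
    return tss


def _gff_gene_id(attrs: str) -> str | None:
    for field in attrs.replace("; ", ";").split(";"):
        field = field.strip()
        for key in ("ID=", "gene_id=", "Name="):
            if field.startswith(key):
                return field[len(key):].strip('"')
        if field.startswith("gene_id "):  # GTF dialect
            return field.split(" ", 1)[1].strip('"')
    return None


def _check_unique_genes(tss: pd.DataFrame, path) -> None:
    if tss.index.duplicated().any():
        dup = tss.index[tss.index.duplicated()].unique().tolist()
        raise BedFormatError(f"{path}: duplicated gene IDs: {dup}")


def _build_trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    return trees


def classify_promoters(
    tss: pd.DataFrame,
    k27_peaks: pd.DataFrame,
    k4_peaks: pd.DataFrame,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Per-gene promoter state from peak overlap with the TSS window.

    A gene is marked for a histone mark iff >= 1 base of any peak of that
    mark falls inside [pos - window_bp, pos + window_bp) (clipped at 0).
    Chromosomes present in the TSS table but absent from a peak set simply
    yield unmarked genes for that mark (logged once per chromosome).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    marked = {}
    for mark, peaks in (("k27", k27_peaks), ("k4", k4_peaks)):
        trees = _build_trees(peaks)
        missing = sorted(set(tss["chrom"]) - set(trees))
        for chrom in missing:
            log.warning("chromosome %s absent from %s peaks; genes left unmarked", chrom, mark)
        hits = np.zeros(len(tss), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(tss["chrom"], tss["pos"])):
            tree = trees.get(chrom)
            if tree is None:
                continue
            lo = max(0, int(pos) - window_bp)
            hi = int(pos) + window_bp
            hits[i] = bool(tree.overlap(lo, hi))
        marked[mark] = hits

    state = np.select(
        [marked["k27"] & marked["k4"], marked["k27"], marked["k4"]],
        ["bivalent", "k27_only", "k4_only"],
        default="unmarked",
    )
    out = pd.DataFrame(
        {"k27_marked": marked["k27"], "k4_marked": marked["k4"], "state": state},
        index=tss.index,
    )
    return out


@dataclass
class EnrichmentResult:
    """Marking counts in a gene set vs its universe, with hypergeometric p."""

    marked_in_set: int
    set_size: int
    marked_in_universe: int
    universe_size: int
    p_value: float

    @property
    def set_fraction(self) -> float:
        return self.marked_in_set / self.set_size

    @property
    def universe_fraction(self) -> float:
        return self.marked_in_universe / self.universe_size

    def to_dict(self) -> dict:
        return {
            "marked_in_set": self.marked_in_set,
            "set_size": self.set_size,
            "set_fraction": self.set_fraction,
            "marked_in_universe": self.marked_in_universe,
            "universe_size": self.universe_size,
            "universe_fraction": self.universe_fraction,
            "p_value": self.p_value,
        }


def set_enrichment(
    states: pd.DataFrame,
    gene_set: list[str],
    universe: list[str] | None = None,
    mark: str = "k27",
) -> EnrichmentResult:
    """Over-representation of a mark in a gene set versus a universe.

    ``mark`` is "k27", "k4" or "bivalent". The p-value is the upper
    hypergeometric tail: probability of drawing at least the observed
    number of marked genes in a set of this size from the universe.
    """
    universe = list(universe) if universe is not None else list(states.index)
    gene_set = list(gene_set)
    if not gene_set or not universe:
        raise ValueError("gene set and universe must be non-empty")
    missing = [g for g in universe if g not in states.index]
    if missing:
        raise ValueError(f"universe genes missing from classification: {missing[:5]}...")
    if not set(gene_set) <= set(universe):
        raise ValueError("gene_set must be a subset of the universe")

    if mark == "bivalent":
        flags = states["state"] == "bivalent"
    elif mark in ("k27", "k4"):
        flags = states[f"{mark}_marked"]
    else:
        raise ValueError(f"unknown mark {mark!r}; use 'k27', 'k4' or 'bivalent'")

    marked_universe = int(flags.loc[universe].sum())
    marked_set = int(flags.loc[gene_set].sum())
    M, K, N = len(universe), marked_universe, len(gene_set)
    p = float(hypergeom.sf(marked_set - 1, M, K, N))
    return EnrichmentResult(
        marked_in_set=marked_set,
        set_size=N,
        marked_in_universe=marked_universe,
        universe_size=M,
        p_value=min(p, 1.0),
    )
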