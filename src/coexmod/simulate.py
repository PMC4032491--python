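"""Synthetic genotype x differentiation-time expression data with planted
co-expression modules, plus matched promoter interval fixtures.

The generator emulates a two-genotype (control vs knockout of a chromatin
repressor) differentiation time course sampled at days 0, 1, 2, 4 and 7.
Planted modules are groups of probes that share a smooth latent time
profile; a configurable subset of modules is "derepressed" — their members
gain a constant expression offset in knockout samples at early days,
mimicking genes that need the repressor to stay off. The remaining probes
are independent Gaussian background.

``simulate_intervals`` builds a matching single-chromosome genome: one TSS
per gene, and H3K27me3 / H3K4me3 peaks placed inside (or decoys outside)
a +/- window around each TSS according to per-gene planted promoter states,
so the downstream window-overlap classifier can be checked against known
marking probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

CONTROL = "control"
KNOCKOUT = "knockout"


class DesignError(ValueError):
    """A simulation design violates one of its invariants."""


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic expression study.

    Defaults mirror the planted-module recovery benchmark: five modules of
    20-60 probes among ~2,000 total, two genotypes x five days x three
    replicates (30 samples), and a within-module noise level giving a
    population within-module correlation of ~0.6
    (``1 / (1 + within_module_noise_sd**2)`` for unit-variance latents).
    """

    n_background_probes: int = 1800
    module_sizes: tuple[int, ...] = (20, 30, 40, 50, 60)
    n_replicates: int = 3
    genotypes: tuple[str, str] = (CONTROL, KNOCKOUT)
    days: tuple[float, ...] = (0, 1, 2, 4, 7)
    derepressed_modules: tuple[int, ...] = (0,)
    derepression_effect: float = 2.0
    early_day_max: float = 2.0
    within_module_noise_sd: float = 0.8165
    background_noise_sd: float = 1.0
    latent_basis_degree: int = 3
    max_latent_correlation: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_background_probes < 0:
            raise DesignError("n_background_probes must be >= 0")
        if any(s < 10 for s in self.module_sizes):
            raise DesignError(
                "module_sizes: every planted module needs >= 10 members "
                f"(got {self.module_sizes}); smaller clusters are below the "
                "pipeline's minimum detectable size"
            )
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if len(self.genotypes) != 2 or len(set(self.genotypes)) != 2:
            raise DesignError("genotypes must be two distinct labels")
        if len(self.days) < 2 or list(self.days) != sorted(self.days):
            raise DesignError("days must be an increasing list of >= 2 timepoints")
        bad = [i for i in self.derepressed_modules if not 0 <= i < len(self.module_sizes)]
        if bad:
            raise DesignError(f"derepressed_modules: indices {bad} out of range")
        if self.within_module_noise_sd < 0:
            raise DesignError("within_module_noise_sd must be >= 0")
        if self.background_noise_sd < 0:
            raise DesignError("background_noise_sd must be >= 0")
        if not 0 < self.max_latent_correlation <= 1:
            raise DesignError("max_latent_correlation must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.days) * self.n_replicates

    @property
    def n_probes(self) -> int:
        return self.n_background_probes + sum(self.module_sizes)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``assignment`` maps every probe to its planted module name or "background".
    ``latent_profiles`` (module x sample) are the zero-mean, unit-variance
    latent time profiles before noise and derepression offsets.
    ``promoter_states`` is filled in by :func:`simulate_intervals`.
    """

    assignment: pd.Series
    latent_profiles: pd.DataFrame | None = None
    derepressed_modules: tuple[str, ...] = ()
    promoter_states: pd.DataFrame | None = None

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.assignment.unique() if m != "background"]

    def module_members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment.to_dict(),
            "latent_profiles": None
            if self.latent_profiles is None
            else {m: row.to_dict() for m, row in self.latent_profiles.iterrows()},
            "derepressed_modules": list(self.derepressed_modules),
            "promoter_states": None
            if self.promoter_states is None
            else self.promoter_states.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def planted_assignment(
    module_sizes: tuple[int, ...] | list[int], n_background: int
) -> SyntheticTruth:
    """Truth object carrying only a probe -> module map (no expression).

    Useful when only interval fixtures are needed, e.g. to study promoter
    marking of a gene set of known size against a background universe.
    """
    labels: list[str] = []
    ids: list[str] = []
    for m, size in enumerate(module_sizes):
        name = f"M{m + 1}"
        for j in range(size):
            ids.append(f"{name}_g{j:04d}")
            labels.append(name)
    for j in range(n_background):
        ids.append(f"bg_g{j:05d}")
        labels.append("background")
    return SyntheticTruth(assignment=pd.Series(labels, index=pd.Index(ids, name="probe_id")))


def _sample_table(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for genotype in design.genotypes:
        for day in design.days:
            for rep in range(1, design.n_replicates + 1):
                day_txt = f"{day:g}"
                rows.append(
                    {
                        "sample_id": f"{genotype}_d{day_txt}_r{rep}",
                        "genotype": genotype,
                        "day": day,
                        "replicate": rep,
                        "batch": "b1",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _draw_latent_profiles(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Smooth random day-profiles, standardized over samples.

    Each profile is a random polynomial of ``latent_basis_degree`` in the
    day variable (rescaled to [-1, 1]), evaluated per sample and then
    centred / scaled to unit variance. Profiles are drawn sequentially with
    rejection so that no two planted latents correlate above
    ``max_latent_correlation`` — planted modules are distinct by design.
    """
    days = np.asarray(design.days, dtype=float)
    x = 2 * (days - days.min()) / (days.max() - days.min()) - 1
    meta = _sample_table(design)
    day_idx = np.searchsorted(days, meta["day"].to_numpy())

    profiles: list[np.ndarray] = []
    for _ in design.module_sizes:
        for _attempt in range(1000):
            coef = rng.normal(size=design.latent_basis_degree + 1)
            day_values = np.polynomial.polynomial.polyval(x, coef)
            prof = day_values[day_idx]
            sd = prof.std(ddof=1)
            if sd < 1e-9:
                continue
            prof = (prof - prof.mean()) / sd
            if all(
                abs(np.corrcoef(prof, q)[0, 1]) <= design.max_latent_correlation
                for q in profiles
            ):
                profiles.append(prof)
                break
        else:  # pragma: no cover - would need pathological settings
            raise DesignError(
                "max_latent_correlation: could not draw sufficiently distinct "
                "latent profiles; relax the bound or reduce module count"
            )
    return np.asarray(profiles)


def simulate_expression(design: SimulationDesign) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate an expression matrix and its ground truth from a design.

    Module member expression is ``latent(module, sample) + N(0, within_sd)``;
    members of derepressed modules additionally get ``+derepression_effect``
    in knockout samples at days <= ``early_day_max``. Background probes are
    i.i.d. ``N(0, background_sd)``. Bit-reproducible from ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    meta = _sample_table(design)
    n_samples = len(meta)

    profiles = _draw_latent_profiles(design, rng)
    truth = planted_assignment(design.module_sizes, design.n_background_probes)
    assignment = truth.assignment
    module_names = [f"M{m + 1}" for m in range(len(design.module_sizes))]

    early_ko = (
        (meta["genotype"] == design.genotypes[1]) & (meta["day"] <= design.early_day_max)
    ).to_numpy()

    values = np.empty((len(assignment), n_samples))
    row = 0
    for m, size in enumerate(design.module_sizes):
        signal = profiles[m].copy()
        if m in design.derepressed_modules:
            signal = signal + design.derepression_effect * early_ko
        noise = rng.normal(0.0, design.within_module_noise_sd, size=(size, n_samples))
        values[row : row + size] = signal[None, :] + noise
        row += size
    if design.n_background_probes:
        values[row:] = rng.normal(
            0.0, design.background_noise_sd, size=(design.n_background_probes, n_samples)
        )

    data = ExpressionDataset(
        pd.DataFrame(values, index=assignment.index, columns=meta.index), meta
    )
    truth.latent_profiles = pd.DataFrame(
        profiles, index=pd.Index(module_names, name="module"), columns=meta.index
    )
    truth.derepressed_modules = tuple(module_names[i] for i in design.derepressed_modules)
    return data, truth


# ---------------------------------------------------------------------------
# Matched interval fixtures
# ---------------------------------------------------------------------------

STATES = ("bivalent", "k27_only", "k4_only", "unmarked")


@dataclass(frozen=True)
class MarkingProbabilities:
    """Per-gene Bernoulli marking rates for the two histone marks.

    Defaults plant H3K27me3 at 74% of module genes versus 7% of background
    genes — the proportions reported for repressor-dependent modules versus
    all-module genes — and give module genes a higher H3K4me3 rate so that
    bivalent (both-marked, "poised") promoters concentrate in modules.
    """

    k27_module: float = 0.74
    k27_background: float = 0.07
    k4_module: float = 0.70
    k4_background: float = 0.50

    def validate(self) -> None:
        for name, p in asdict(self).items():
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"{name}: probability {p} outside [0, 1]")


@dataclass
class SyntheticIntervals:
    """Peak and TSS fixtures on a single synthetic chromosome."""

    k27_peaks: pd.DataFrame
    k4_peaks: pd.DataFrame
    tss: pd.DataFrame
    planted_states: pd.DataFrame  # per gene: k27_marked, k4_marked, state

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "k27": outdir / "h3k27me3_peaks.bed",
            "k4": outdir / "h3k4me3_peaks.bed",
            "tss": outdir / "tss.bed",
            "states": outdir / "planted_promoter_states.tsv",
        }
        _write_bed(self.k27_peaks, paths["k27"])
        _write_bed(self.k4_peaks, paths["k4"])
        tss_bed = pd.DataFrame(
            {
                "chrom": self.tss["chrom"],
                "start": self.tss["pos"],
                "end": self.tss["pos"] + 1,
                "name": self.tss.index,
                "score": 0,
                "strand": self.tss["strand"],
            }
        )
        _write_bed(tss_bed, paths["tss"])
        self.planted_states.to_csv(paths["states"], sep="\t", index_label="gene_id")
        return paths


def _write_bed(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def simulate_intervals(
    truth: SyntheticTruth,
    window_bp: int = 1000,
    probs: MarkingProbabilities | None = None,
    seed: int = 0,
    chrom: str = "chrS",
    decoy_prob: float = 0.3,
    marked_modules: tuple[str, ...] | list[str] | None = None,
) -> SyntheticIntervals:
    """Place TSSs and histone-mark peaks consistent with planted states.

    One TSS per gene on a single chromosome, spaced 10x ``window_bp`` apart
    so promoter windows never overlap. For each gene and mark, a peak is
    drawn inside the +/- ``window_bp`` TSS window with the probability for
    the gene's class (module member vs background); unmarked genes may get
    a decoy peak well outside the window so non-overlap is exercised too.

    ``marked_modules`` restricts the high-probability "module" class to the
    named modules (e.g. ``truth.derepressed_modules`` to emulate repressor
    targets being preferentially marked); the default treats every planted
    module gene as the module class.
    """
    probs = probs or MarkingProbabilities()
    probs.validate()
    if window_bp <= 0:
        raise DesignError("window_bp must be positive")
    if marked_modules is not None:
        unknown = set(marked_modules) - set(truth.module_names)
        if unknown:
            raise DesignError(f"marked_modules: unknown modules {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    genes = truth.assignment.index
    if marked_modules is None:
        is_module = (truth.assignment != "background").to_numpy()
    else:
        is_module = truth.assignment.isin(list(marked_modules)).to_numpy()
    spacing = 10 * window_bp
    pos = spacing + spacing * np.arange(len(genes))
    strand = np.where(rng.random(len(genes)) < 0.5, "+", "-")

    p_k27 = np.where(is_module, probs.k27_module, probs.k27_background)
    p_k4 = np.where(is_module, probs.k4_module, probs.k4_background)
    k27_marked = rng.random(len(genes)) < p_k27
    k4_marked = rng.random(len(genes)) < p_k4

    def _peaks(marked: np.ndarray, mark: str) -> pd.DataFrame:
        rows = []
        for i, gene in enumerate(genes):
            if marked[i]:
                width = int(rng.integers(200, 800))
                # centre inside the window => guaranteed >=1 bp overlap
                centre = int(pos[i] + rng.integers(-window_bp + 1, window_bp))
                start = max(0, centre - width // 2)
                rows.append((chrom, start, start + width, f"{mark}_{gene}", 0, "."))
            elif rng.random() < decoy_prob:
                # decoy strictly outside every promoter window
                width = int(rng.integers(200, 800))
                offset = int(rng.integers(2 * window_bp, 4 * window_bp))
                start = int(pos[i]) + offset
                rows.append((chrom, start, start + width, f"{mark}_decoy_{gene}", 0, "."))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    state = np.select(
        [k27_marked & k4_marked, k27_marked, k4_marked],
        ["bivalent", "k27_only", "k4_only"],
        default="unmarked",
    )
    planted = pd.DataFrame(
        {"k27_marked": k27_marked, "k4_marked": k4_marked, "state": state},
        index=genes.rename("gene_id"),
    )
    tss = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": strand}, index=genes.rename("gene_id")
    )
    result = SyntheticIntervals(
        k27_peaks=_peaks(k27_marked, "k27"),
        k4_peaks=_peaks(k4_marked, "k4"),
        tss=tss,
        planted_states=planted,
    )
    truth.promoter_states = planted
    return result
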