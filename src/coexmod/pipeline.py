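"""End-to-end pipeline runner with declarative configuration.

A run executes preprocess -> module detection -> derepression screen ->
promoter enrichment on either user-supplied files or the built-in
synthetic generator, writing every intermediate table plus a JSON manifest
(parameters, seeds, package/library versions, input checksums) so the run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .datasets import ExpressionDataset
from .preprocess import apply_qc, detect_sample_outliers, quantile_normalize, read_expression
from .network import (
    assign_membership,
    attach_eigengenes,
    cluster_and_cut,
    correlation_model,
    merge_modules,
    static_cut_height,
)
from .screen import derepression_screen, top_members
from .chromatin import classify_promoters, read_bed, read_tss, set_enrichment
from .simulate import MarkingProbabilities, SimulationDesign, simulate_expression, simulate_intervals

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """All thresholds, paths, toggles and seeds of one pipeline run."""

    # inputs (ignored when simulate=True)
    matrix: str | None = None
    meta: str | None = None
    k27_peaks: str | None = None
    k4_peaks: str | None = None
    tss: str | None = None
    # stage toggles
    simulate: bool = False
    run_preprocess: bool = True
    run_screen: bool = True
    run_enrichment: bool = True
    # preprocess
    z_cut: float = -2.0
    max_qc_rounds: int = 5
    exclude_samples: list[str] = field(default_factory=list)
    renormalize_after_qc: bool = True
    log2: bool = False
    # module detection
    top_fraction: float = 0.02
    cut_height: float | None = None  # explicit override of the percentile-derived height
    min_size: int = 10
    merge_threshold: float = 0.85
    alpha: float = 0.05
    # screen
    early_days: list[float] = field(default_factory=lambda: [0, 1, 2])
    n_permutations: int = 10_000
    screen_alpha: float = 0.05
    top_k: int = 15
    # chromatin
    window_bp: int = 1000
    # seeds
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ConfigError("top_fraction must be in (0, 1)")
        if self.cut_height is not None and not 0 <= self.cut_height <= 2:
            raise ConfigError("cut_height must be in [0, 2]")
        if self.min_size < 2:
            raise ConfigError("min_size must be >= 2")
        if not 0 < self.merge_threshold <= 1:
            raise ConfigError("merge_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1 or not 0 < self.screen_alpha < 1:
            raise ConfigError("alpha levels must be in (0, 1)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")
        if not self.simulate:
            if self.matrix is None or self.meta is None:
                raise ConfigError("matrix and meta paths are required unless simulate=True")
            for name in ("matrix", "meta"):
                p = getattr(self, name)
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
            if self.run_enrichment:
                for name in ("k27_peaks", "k4_peaks", "tss"):
                    p = getattr(self, name)
                    if p is None or not Path(p).exists():
                        raise ConfigError(
                            f"enrichment enabled but {name} path missing: {p}"
                        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the configured stages, writing artifacts and a manifest.

    Returns the run directory. On stage failure the manifest still records
    the stages completed so far together with the failure point.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "coexmod": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {},
        "stages": [],
        "status": "running",
    }

    def _done(stage: str) -> None:
        manifest["stages"].append(stage)
        _write_manifest()

    def _write_manifest() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("coexmod")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        # ---- inputs ------------------------------------------------------
        if config.simulate:
            design = SimulationDesign(seed=config.seed)
            data, truth = simulate_expression(design)
            intervals = simulate_intervals(
                truth, window_bp=config.window_bp, seed=config.seed + 1
            )
            data.to_tsv(outdir / "simulated_matrix.tsv", outdir / "simulated_meta.tsv")
            truth.to_json(outdir / "truth.json")
            paths = intervals.write(outdir)
            k27, k4 = intervals.k27_peaks, intervals.k4_peaks
            tss = intervals.tss
            manifest["inputs"]["simulation_design"] = dataclasses.asdict(design)
        else:
            for name in ("matrix", "meta", "k27_peaks", "k4_peaks", "tss"):
                p = getattr(config, name)
                if p:
                    manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
            data = read_expression(config.matrix, config.meta)
            k27 = read_bed(config.k27_peaks) if config.k27_peaks else None
            k4 = read_bed(config.k4_peaks) if config.k4_peaks else None
            tss = read_tss(config.tss) if config.tss else None
        _done("load")

        # ---- preprocess --------------------------------------------------
        if config.run_preprocess:
            if config.log2:
                data = ExpressionDataset(
                    np.log2(data.values + 1.0), data.sample_meta.copy()
                )
            data = quantile_normalize(data)
            qc = detect_sample_outliers(
                data,
                z_cut=config.z_cut,
                max_rounds=config.max_qc_rounds,
                exclude_samples=config.exclude_samples or None,
            )
            (outdir / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=1))
            data = apply_qc(data, qc, renormalize=config.renormalize_after_qc)
            data.to_tsv(outdir / "normalized_matrix.tsv", outdir / "retained_meta.tsv")
        _done("preprocess")

        # ---- module detection -------------------------------------------
        model = correlation_model(data, on_zero_variance="drop")
        height = (
            config.cut_height
            if config.cut_height is not None
            else static_cut_height(model, config.top_fraction)
        )
        modules = cluster_and_cut(model, height, min_size=config.min_size)
        modules = attach_eigengenes(data, modules)
        modules = merge_modules(data, modules, threshold=config.merge_threshold)
        membership = assign_membership(data, modules, alpha=config.alpha)
        manifest["cut_height"] = float(height)
        manifest["n_modules"] = len(modules.eigengenes)
        modules.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        membership.to_frame().to_csv(outdir / "membership.tsv", sep="\t")
        (outdir / "merge_log.json").write_text(json.dumps(modules.merge_log, indent=1))
        _done("modules")

        # ---- derepression screen ----------------------------------------
        screen_result = None
        if config.run_screen:
            screen_result = derepression_screen(
                modules.eigengenes,
                data.sample_meta,
                early_days=tuple(config.early_days),
                n_permutations=config.n_permutations,
                seed=config.seed + 2,
                alpha=config.screen_alpha,
            )
            screen_result.table.to_csv(outdir / "screen.tsv", sep="\t", index_label="module")
            tops = []
            for module in screen_result.flagged:
                if (membership.assigned == module).any():
                    t = top_members(membership, module, k=config.top_k)
                    t.insert(0, "module", module)
                    tops.append(t)
            if tops:
                pd.concat(tops).to_csv(outdir / "top_members.tsv", sep="\t")
        _done("screen")

        # ---- promoter enrichment ----------------------------------------
        if config.run_enrichment and tss is not None:
            states = classify_promoters(tss, k27, k4, window_bp=config.window_bp)
            states.to_csv(outdir / "promoter_states.tsv", sep="\t", index_label="gene_id")
            assigned = membership.assigned.dropna()
            classified = assigned.index.intersection(states.index)
            universe = list(classified)
            flagged = screen_result.flagged if screen_result is not None else []
            gene_set = [
                g for g in universe if assigned.get(g) in flagged
            ] or None
            if universe and gene_set:
                enr = set_enrichment(states, gene_set, universe, mark="k27")
                (outdir / "enrichment.json").write_text(
                    json.dumps(enr.to_dict(), indent=1)
                )
        _done("enrichment")

        manifest["status"] = "ok"
        _write_manifest()
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest()
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
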