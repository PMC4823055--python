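"""Top-level pipeline: simulate → classify → select, driven by one config.

The pipeline ties the stages together on a shared synthetic universe: a
breast cohort is classified into molecular subtypes by the iterative
ensemble; differential expression of cancer subtypes against normal-tissue
panels, localization rules and mean-rank ordering assemble the balanced
target list; epithelial/mesenchymal markers from a replicated cell-line
panel flag EMT-linked targets. Every artifact is stamped with the config
hash and seed, and a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as aio
from .ensemble import ExpertGrid, iterative_ensemble_label
from .synthetic import (CohortConfig, PanelConfig, generate_breast_cohort,
                        generate_cell_line_panel, generate_target_universe)
from .targets import (FilterThresholds, balanced_top_n, de_filter, emt_markers,
                      intersect_targets_emt, localization_flags,
                      mean_rank_order)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("adcscreen")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; fully determines the outputs."""

    seed: int = 0
    out_dir: str = "adcscreen_out"
    stages: tuple = ("simulate", "classify", "select")
    # synthetic inputs
    cohort: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    universe: dict = field(default_factory=dict)
    # ensemble
    grid: dict = field(default_factory=lambda: {
        "fs_methods": ("modt", "ovl"), "classifiers": ("svm", "knn"),
        "k_values": (5, 6, 7)})
    feedback_threshold: float = 0.95
    final_threshold: float = 0.75
    max_iter: int = 25
    stable_window: int = 3
    # target selection
    thresholds: dict = field(default_factory=dict)
    top_n: int = 50
    localization: str = "membrane"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load YAML (JSON is valid YAML) into a config."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(out: Path, cfg: PipelineConfig) -> None:
    manifest = {"config_hash": cfg.digest(), "seed": cfg.seed,
                "config": asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages; returns paths of the written artifacts.

    Raises if a stage's inputs are missing (e.g. ``classify`` without a
    prior ``simulate`` in the same run or on disk).
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    _stamp(out, cfg)
    artifacts["manifest"] = out / "manifest.json"

    t0 = time.perf_counter()
    if "simulate" in cfg.stages:
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        cohort_cfg = CohortConfig(**{"seed": cfg.seed, **cfg.cohort})
        matrix, table, truth = generate_breast_cohort(cohort_cfg)
        aio.write_expression_tsv(matrix, sim_dir / "cohort_expression.tsv")
        aio.write_table_tsv(table, sim_dir / "cohort_samples.tsv")
        aio.write_table_tsv(truth.to_frame(), sim_dir / "cohort_truth.tsv")

        uni = generate_target_universe(seed=cfg.seed + 1,
                                       target_localization=cfg.localization,
                                       **cfg.universe)
        aio.write_expression_tsv(uni["matrix"], sim_dir / "universe_expression.tsv")
        aio.write_table_tsv(uni["sample_table"], sim_dir / "universe_samples.tsv")
        aio.write_table_tsv(uni["annotations"], sim_dir / "gene_annotations.tsv")

        panel_cfg = PanelConfig(**{"seed": cfg.seed + 2,
                                   "n_genes": len(uni["matrix"].index),
                                   **cfg.panel})
        pmatrix, ptable, ptruth = generate_cell_line_panel(panel_cfg)
        aio.write_expression_tsv(pmatrix, sim_dir / "panel_expression.tsv")
        aio.write_table_tsv(ptable, sim_dir / "panel_samples.tsv")
        artifacts["simulate"] = sim_dir
        log.info("simulate stage done in %.1fs", time.perf_counter() - t0)

    if "classify" in cfg.stages:
        t1 = time.perf_counter()
        sim_dir = out / "simulate"
        need = sim_dir / "cohort_expression.tsv"
        if not need.exists():
            raise FileNotFoundError(
                f"classify stage needs {need}; run the simulate stage first")
        matrix = aio.read_expression_tsv(need)
        table = aio.read_table_tsv(sim_dir / "cohort_samples.tsv")
        grid = ExpertGrid(**cfg.grid)
        labels, trace = iterative_ensemble_label(
            matrix, table["seed_label"], grid,
            feedback_threshold=cfg.feedback_threshold,
            final_threshold=cfg.final_threshold, max_iter=cfg.max_iter,
            stable_window=cfg.stable_window, seed=cfg.seed)
        cls_dir = out / "classify"
        cls_dir.mkdir(exist_ok=True)
        aio.write_table_tsv(labels, cls_dir / "labels.tsv")
        aio.write_table_tsv(trace.to_frame(), cls_dir / "trace.tsv")
        for it, counts in enumerate(trace.tiers):
            log.info("iteration %d tier counts: %s", it, counts)
        artifacts["classify"] = cls_dir
        log.info("classify stage done in %.1fs (converged_at=%s)",
                 time.perf_counter() - t1, trace.converged_at)

    if "select" in cfg.stages:
        t2 = time.perf_counter()
        sim_dir = out / "simulate"
        need = sim_dir / "universe_expression.tsv"
        if not need.exists():
            raise FileNotFoundError(
                f"select stage needs {need}; run the simulate stage first")
        matrix = aio.read_expression_tsv(need)
        stable = aio.read_table_tsv(sim_dir / "universe_samples.tsv")
        ann = aio.read_table_tsv(sim_dir / "gene_annotations.tsv")
        th = FilterThresholds(**{"top_n": cfg.top_n, **cfg.thresholds})

        normals_by_tissue = {
            t: list(ids.index)
            for t, ids in stable[stable["seed_label"] == "normal"].groupby("tissue")
        }
        flags = localization_flags(ann)
        wanted = flags["membrane"] if cfg.localization == "membrane" \
            else flags["extracellular"]
        ordered = {}
        records = {}
        for sub in ("luminal", "HER2+", "triple-negative"):
            cancer = list(stable.index[stable["seed_label"] == sub])
            rec = de_filter(matrix, cancer, normals_by_tissue, th)
            rec = mean_rank_order(rec)
            records[sub] = rec
            keep = rec.index[rec["passed_filter"]
                             & wanted.reindex(rec.index, fill_value=False)]
            ordered[sub] = list(keep)
        top = balanced_top_n(ordered, n=th.top_n)
        top["localization"] = cfg.localization.upper()

        pmatrix = aio.read_expression_tsv(sim_dir / "panel_expression.tsv")
        ptable = aio.read_table_tsv(sim_dir / "panel_samples.tsv")
        lines = {cls: {ln: list(grp.index) for ln, grp in sub.groupby("line")}
                 for cls, sub in ptable.groupby("seed_label")}
        emt = emt_markers(pmatrix, lines["epithelial"], lines["mesenchymal"])
        annotated, counts = intersect_targets_emt(top, emt)

        sel_dir = out / "select"
        sel_dir.mkdir(exist_ok=True)
        for sub, rec in records.items():
            tag = sub.replace("+", "pos").replace("-", "_")
            aio.write_table_tsv(rec, sel_dir / f"de_filter_{tag}.tsv")
        aio.write_table_tsv(annotated, sel_dir / "targets.tsv")
        counts.rename("n").to_csv(sel_dir / "emt_counts.tsv", sep="\t")
        artifacts["select"] = sel_dir
        artifacts["targets"] = sel_dir / "targets.tsv"
        log.info("select stage done in %.1fs (%d targets)",
                 time.perf_counter() - t2, len(annotated))
    return artifacts
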