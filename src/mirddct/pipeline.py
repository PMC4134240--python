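"""End-to-end orchestration: censor -> annotate -> normalize -> ddCt ->
prune -> directional tests -> BH -> fold changes -> clustering, with a JSON
run manifest recording seeds, stage counts and the realized BH cutoff.

Two entry points: :func:`run_full` starts from a long-form Ct table;
:func:`run_from_ddct` starts from an already-computed assay x pair ddCt
matrix (e.g. a published supplementary matrix) and skips normalization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster as hcluster
from . import io as qio
from . import normalization, pruning
from .diffexpr import run_differential_expression

__all__ = ["PipelineConfig", "run_full", "run_from_ddct"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, with the study thresholds as
    defaults: 40-cycle detection limit, 9-of-18 minimum paired detection,
    3 endogenous controls, 2-fold (1 log2 unit) shifted null, BH at 5%.
    """

    detection_limit: float = 40.0
    total_pairs: Optional[int] = None  # None: infer from the data
    min_detected_pairs: Optional[int] = None  # None: 9-of-18 rule / ceil(n/2)
    endogenous_candidates: Optional[list[str]] = None  # None: assays named ctrl-*
    n_controls: int = 3
    alpha: float = 0.05
    delta0_log2: float = 1.0
    normality_alpha: float = 0.05
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_restarts: int = 20
    max_iter: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        sections = {"pruning", "normalization", "diffexpr", "cluster", "simulation"}
        for key, value in raw.items():
            if key in sections and isinstance(value, dict):
                if key == "simulation":
                    continue  # consumed by the simulate subcommand
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in flat:
            flat["k_range"] = tuple(flat["k_range"])
        return cls(**flat)

    def pruning_config(self, total_pairs: int) -> pruning.PruningConfig:
        kwargs: dict = {"ct_detection_limit": self.detection_limit, "total_pairs": total_pairs}
        if self.min_detected_pairs is not None:
            kwargs["min_detected_pairs"] = self.min_detected_pairs
        return pruning.PruningConfig(**kwargs)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _StageError(RuntimeError):
    pass


class _Run:
    """Tracks outputs written in this run so failures leave no partial state."""

    def __init__(self, out_dir) -> None:
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            if p.exists():
                p.unlink()


def _analyse_matrix(matrix: pd.DataFrame, cfg: PipelineConfig, run: _Run, manifest: dict):
    """Shared back half: min-pairs pruning, tests, BH, clustering, report."""
    stage = "min-pairs filter"
    try:
        total = cfg.total_pairs or matrix.shape[1]
        pcfg = cfg.pruning_config(total)
        pruned = pruning.filter_min_pairs(matrix, pcfg)
        manifest["stages"].append(
            {"stage": stage, "assays_in": int(matrix.shape[0]), "assays_out": int(pruned.shape[0])}
        )

        stage = "differential expression"
        results, bh = run_differential_expression(pruned, cfg.alpha, cfg.delta0_log2)
        manifest["stages"].append(
            {"stage": stage, "assays_in": int(pruned.shape[0]), "assays_out": len(results)}
        )
        manifest["bh"] = {
            "alpha": bh.alpha,
            "m_tested": bh.m,
            "n_significant": bh.rank,
            "cutoff": bh.cutoff,
        }
        logger.info("BH corrected cutoff p-value: %.4g (%d significant of %d tested)",
                    bh.cutoff, bh.rank, bh.m)
        qio.write_de_report(results, run.path("de_report.csv"))
        qio.write_ddct_matrix(pruned, run.path("ddct_matrix.csv"))

        flags = pd.DataFrame(
            {
                "assay_id": [r.assay_id for r in results],
                "ks_p": [np.nan if r.ks_p is None else r.ks_p for r in results],
                "normality_flag": [
                    int(r.ks_p is not None and r.ks_p < cfg.normality_alpha) for r in results
                ],
            }
        )
        flags.to_csv(run.path("normality_flags.csv"), index=False)

        stage = "clustering"
        curve = hcluster.elbow_select(
            pruned, cfg.k_range, seed=cfg.seed, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter
        )
        model = hcluster.k_median(
            pruned, curve.chosen_k, seed=cfg.seed, n_restarts=cfg.n_restarts, max_iter=cfg.max_iter
        )
        model.assignments.rename_axis("pair_id").to_csv(run.path("cluster_assignments.csv"))
        sizes = model.assignments.value_counts().sort_index()
        with open(run.path("cluster_model.json"), "w") as fh:
            json.dump(
                {
                    "chosen_k": curve.chosen_k,
                    "k_values": list(curve.k_values),
                    "costs": list(curve.costs),
                    "cost": model.cost,
                    "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
                    "seed": model.seed,
                    "n_restarts": model.n_restarts,
                },
                fh,
                indent=1,
            )
        manifest["cluster"] = {
            "chosen_k": curve.chosen_k,
            "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
            "cost": model.cost,
        }

        row_order, col_order, _, _ = hcluster.hierarchical_order(pruned)
        with open(run.path("heatmap_orders.json"), "w") as fh:
            json.dump({"row_order": list(row_order), "col_order": list(col_order)}, fh)

        sig = [r for r in results if r.bh_significant]
        corr_rows = []
        for i in range(len(sig)):
            for j in range(i + 1, len(sig)):
                try:
                    r, n_used = hcluster.pairwise_correlation(
                        pruned, sig[i].assay_id, sig[j].assay_id
                    )
                except ValueError:
                    continue
                corr_rows.append((sig[i].assay_id, sig[j].assay_id, r, n_used))
        pd.DataFrame(
            corr_rows, columns=["assay_a", "assay_b", "pearson_r", "n_pairs"]
        ).to_csv(run.path("significant_correlations.csv"), index=False)

        return results, bh, model, curve
    except _StageError:
        raise
    except Exception as exc:
        raise _StageError(f"stage {stage!r} failed: {exc}") from exc


def run_full(
    ct_path,
    annotation_path,
    out_dir,
    cfg: Optional[PipelineConfig] = None,
) -> dict:
    """Run the whole pipeline from a long-form Ct table file.

    Returns the manifest dict (also written to ``manifest.json`` in
    ``out_dir``). Any stage failure removes the partial outputs of this
    run and re-raises with the stage name.
    """
    cfg = cfg or PipelineConfig()
    run = _Run(out_dir)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "inputs": {"ct_table": str(ct_path), "annotation_map": str(annotation_path)},
        "stages": [],
    }
    stage = "read"
    try:
        table = qio.read_ct_table(ct_path)
        if table.empty:
            raise ValueError(f"empty Ct table: {ct_path}")
        amap = qio.read_annotation_map(annotation_path)
        n_assays0 = table["assay_id"].nunique()
        manifest["stages"].append(
            {"stage": stage, "records": int(len(table)), "assays_out": int(n_assays0)}
        )

        stage = "detection-limit censoring"
        table = pruning.censor_detection_limit(table, cfg.detection_limit)
        manifest["stages"].append(
            {
                "stage": stage,
                "assays_in": int(n_assays0),
                "assays_out": int(n_assays0),
                "detected_wells": int(table["ct"].notna().sum()),
            }
        )

        stage = "annotation filter"
        table = pruning.filter_annotation(table, amap)
        n_assays1 = table["assay_id"].nunique()
        manifest["stages"].append(
            {"stage": stage, "assays_in": int(n_assays0), "assays_out": int(n_assays1)}
        )

        stage = "endogenous-control selection"
        candidates = cfg.endogenous_candidates
        if candidates is None:
            candidates = sorted(
                a for a in table["assay_id"].unique() if a.startswith("ctrl-")
            )
        selection = normalization.select_endogenous_controls(
            table, candidates, cfg.n_controls
        )
        manifest["controls"] = {
            "candidates": list(selection.candidate_ids),
            "chosen": list(selection.chosen_ids),
            "stability_sd": selection.stability_scores,
        }

        stage = "normalization"
        dct = normalization.compute_dct(table, selection)
        matrix = normalization.compute_ddct(dct)
        manifest["stages"].append(
            {"stage": stage, "assays_in": int(n_assays1), "assays_out": int(matrix.shape[0])}
        )
    except _StageError:
        run.cleanup()
        raise
    except Exception as exc:
        run.cleanup()
        raise _StageError(f"stage {stage!r} failed: {exc}") from exc

    try:
        _analyse_matrix(matrix, cfg, run, manifest)
    except _StageError:
        run.cleanup()
        raise
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def run_from_ddct(matrix_path, out_dir, cfg: Optional[PipelineConfig] = None) -> dict:
    """Re-analyze an existing assay x pair ddCt matrix (normalization skipped)."""
    cfg = cfg or PipelineConfig()
    run = _Run(out_dir)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "inputs": {"ddct_matrix": str(matrix_path)},
        "stages": [],
    }
    try:
        matrix = qio.read_ddct_matrix(matrix_path)
        manifest["stages"].append(
            {"stage": "read", "assays_out": int(matrix.shape[0]), "pairs": int(matrix.shape[1])}
        )
    except Exception as exc:
        run.cleanup()
        raise _StageError(f"stage 'read' failed: {exc}") from exc
    try:
        _analyse_matrix(matrix, cfg, run, manifest)
    except _StageError:
        run.cleanup()
        raise
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
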