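"""End-to-end orchestration of the leachate-response analysis.

``run_pipeline`` reads an experiment directory (count/taxonomy/copy
number/design/flow/covariate TSVs, optionally a micrograph directory),
runs every stage in order and writes the result surfaces of the study:
alpha diversity after rarefaction averaging, copy-number corrected
composition, the two-factor PERMANOVA, Kruskal–Wallis/Dunn treatment
contrasts, the richness-vs-protein-like-DOM correlation, responder
clusters with absolute abundance scaling, and (when images are present)
the single-cell activity tables. Every output table carries the config
hash and seed in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amplicon, clustering, image_quant, stats_core

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    image_dir: str | None = None  # None => amplicon-only run
    seed: int = 0
    depth: int | None = None  # None => minimum sample total
    n_reps: int = 100
    k: int = 7
    linkage: str = "complete"
    pseudocount: float | None = None  # None => half the smallest nonzero
    abundance_threshold: float = 0.01
    n_permutations: int = 1000
    boncat_k: float = 3.0
    fish_k: float = 3.0
    min_area_px: int = 5
    bit_depth: int = 8
    order_level_overrides: tuple = (
        "Bacteroidota", "Alphaproteobacteria", "Gammaproteobacteria",
    )
    probe_panel: dict | None = None  # None => built-in six-probe panel

    def hash(self) -> str:
        """Digest of the analysis parameters (paths excluded, so the same
        analysis on the same data hashes identically wherever it runs)."""
        payload = {
            k: v for k, v in asdict(self).items()
            if k not in ("input_dir", "output_dir", "image_dir")
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_KNOWN_KEYS = set(PipelineConfig().__dict__)


def load_config(path: Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.order_level_overrides, list):
        cfg.order_level_overrides = tuple(cfg.order_level_overrides)
    return cfg


_REQUIRED_FILES = (
    "counts.tsv", "taxonomy.tsv", "copy_numbers.tsv", "design.tsv",
)


def validate_config(cfg: PipelineConfig) -> list:
    """Schema and cross-reference checks; returns a list of problems."""
    problems = []
    root = Path(cfg.input_dir)
    for name in _REQUIRED_FILES:
        if not (root / name).exists():
            problems.append(f"missing input file: {root / name}")
    if cfg.seed is None:
        problems.append("seed must be set explicitly")
    if cfg.n_reps < 1 or cfg.n_permutations < 1 or cfg.k < 1:
        problems.append("n_reps, n_permutations and k must be >= 1")
    if (root / "counts.tsv").exists() and cfg.depth is not None:
        counts = pd.read_csv(root / "counts.tsv", sep="\t", index_col=0)
        min_total = int(counts.sum(axis=0).min())
        if cfg.depth > min_total:
            problems.append(
                f"depth {cfg.depth} exceeds the minimum sample total {min_total}"
            )
    if cfg.image_dir is not None:
        img = Path(cfg.image_dir)
        if not img.is_dir():
            problems.append(f"image directory not found: {img}")
        else:
            panel = _panel_from_config(cfg)
            probes = set()
            for p in img.glob("*.tif"):
                m = image_quant._FNAME.match(p.name)
                if m:
                    probes.add(m["probe"])
            unknown = probes - set(panel.targets)
            if unknown:
                problems.append(f"images reference probes not in panel: {sorted(unknown)}")
    return problems


def _panel_from_config(cfg: PipelineConfig) -> image_quant.ProbePanel:
    if cfg.probe_panel is None:
        return image_quant.default_probe_panel()
    return image_quant.ProbePanel(**cfg.probe_panel)


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _log(stage: str, message: str) -> None:
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t[{stage}]\t{message}"
    logger.info(line)
    _RUN_LOG.append(line)


_RUN_LOG: list = []


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory. Any stage failure
    aborts with a stage-tagged error message."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    _RUN_LOG.clear()
    root = Path(cfg.input_dir)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)

    try:
        stage = "load"
        counts = pd.read_csv(root / "counts.tsv", sep="\t", index_col=0)
        taxonomy = pd.read_csv(root / "taxonomy.tsv", sep="\t", index_col=0).fillna("")
        cn = amplicon.CopyNumberTable(pd.read_csv(root / "copy_numbers.tsv", sep="\t"))
        design = pd.read_csv(root / "design.tsv", sep="\t", index_col=0)
        flow = covariates = None
        if (root / "flow_totals.tsv").exists():
            flow = pd.read_csv(root / "flow_totals.tsv", sep="\t", index_col=0)["cells_per_mL"]
        if (root / "covariates.tsv").exists():
            covariates = pd.read_csv(root / "covariates.tsv", sep="\t", index_col=0)
        _log(stage, f"{counts.shape[0]} ASVs x {counts.shape[1]} samples")

        stage = "rarefaction"
        rarefied = amplicon.rarefy_mean(
            counts, depth=cfg.depth, n_reps=cfg.n_reps, seed=rng_seed
        )
        div = amplicon.diversity(rarefied)
        div = div.join(design, how="left")
        _write(div, out / "diversity.tsv", cfg)
        _log(stage, f"depth={cfg.depth or int(counts.sum(0).min())} n_reps={cfg.n_reps}")

        stage = "copy-number"
        rel = amplicon.copy_number_correct(counts, taxonomy, cn)
        _write(rel.rename_axis("asv_id"), out / "rel_abund.tsv", cfg)

        stage = "composition"
        comp = amplicon.aggregate_taxa(
            rel, taxonomy, level="phylum",
            order_level_overrides=cfg.order_level_overrides,
        )
        _write(comp, out / "composition.tsv", cfg)

        stage = "permanova"
        treat = design[design["plastic"].isin(["control", "LDPE", "aged"])]
        dm = stats_core.bray_curtis(rel[treat.index].T)
        perm = stats_core.permanova(
            dm, treat, n_perm=cfg.n_permutations, seed=rng_seed
        )
        _write(perm.table.rename_axis("term"), out / "permanova.tsv", cfg)
        _log(stage, f"plastic R2={perm.r2('plastic'):.3f} p={perm.p('plastic'):.4g}")

        stage = "treatment-contrasts"
        rich = div.loc[treat.index]
        kw = stats_core.kruskal_wallis(
            stats_core.GroupedValues(
                rich["richness"].to_numpy(float), treat["plastic"].to_numpy()
            )
        )
        dunn = stats_core.dunn_posthoc(
            stats_core.GroupedValues(
                rich["richness"].to_numpy(float), treat["plastic"].to_numpy()
            )
        )
        contrasts = dunn.pairwise.copy()
        contrasts.insert(0, "kw_H", kw.statistic)
        contrasts.insert(1, "kw_p", kw.p_value)
        _write(contrasts, out / "richness_contrasts.tsv", cfg, index=False)

        stage = "correlations"
        corr_rows = []
        if covariates is not None:
            common = rich.index.intersection(covariates.index)
            protein_prop = (
                covariates.loc[common, "fdom_protein_like"]
                / covariates.loc[common, "doc_umol_L"]
            )
            sp = stats_core.spearman(
                rich.loc[common, "richness"].to_numpy(float),
                protein_prop.to_numpy(float),
                n_perm=9999,
                seed=rng_seed,
            )
            corr_rows.append(
                {"pair": "richness~protein_like_DOM_proportion",
                 "spearman_rho": sp.statistic, "p_perm": sp.p_value, "n": len(common)}
            )
            _write(pd.DataFrame(corr_rows), out / "correlations.tsv", cfg, index=False)
            _log(stage, f"rho={sp.statistic:.3f}")

        stage = "clustering"
        abundant = amplicon.abundant_asv_filter(rel, cfg.abundance_threshold)
        clr = clustering.clr_transform(rel.loc[abundant], cfg.pseudocount)
        assignment = clustering.cluster_responders(clr, k=cfg.k, linkage=cfg.linkage)
        _write(assignment.to_frame().rename_axis("asv_id"), out / "clusters.tsv", cfg)
        _write(clr.rename_axis("asv_id"), out / "clr_matrix.tsv", cfg)
        sil = clustering.silhouette_profile(clr, linkage=cfg.linkage)
        _write(sil, out / "silhouette.tsv", cfg, index=False)
        _log(stage, f"{len(abundant)} abundant ASVs -> k={cfg.k} clusters")

        stage = "cluster-abundance"
        contrib = clustering.cluster_contribution(assignment, rel)
        _write(contrib.rename_axis("cluster"), out / "cluster_summary.tsv", cfg)
        if flow is not None:
            absolute = clustering.cluster_cell_abundance(
                contrib[treat.index.intersection(contrib.columns)],
                flow, design=design,
            )
            _write(absolute["cells_per_sample"].rename_axis("cluster"),
                   out / "cluster_cells_per_mL.tsv", cfg)
            _write(absolute["treatment_mean"].rename_axis("cluster"),
                   out / "cluster_cells_treatment_mean.tsv", cfg)

        if cfg.image_dir is not None:
            stage = "image-quant"
            cells = image_quant.quantify_fov_directory(
                Path(cfg.image_dir), min_area_px=cfg.min_area_px,
                boncat_k=cfg.boncat_k, fish_k=cfg.fish_k, bit_depth=cfg.bit_depth,
            )
            _write(cells, out / "cells.tsv", cfg, index=False)
            panel = _panel_from_config(cfg)
            per_probe_rows = []
            for (sample, probe), sub in cells.groupby(["sample_id", "probe_id"]):
                n_fov = sub["fov_id"].nunique()
                row = {
                    "sample_id": sample, "probe_id": probe, "n_fov": n_fov,
                    "total_activity": image_quant.sample_activity(sub, n_fov),
                    "boncat_per_fov": image_quant.boncat_positive_density(sub, n_fov)["per_fov"],
                    "contribution_abundance": image_quant.group_abundance_contribution(sub),
                }
                try:
                    row["contribution_activity"] = image_quant.group_activity_contribution(sub)
                except ZeroDivisionError:
                    row["contribution_activity"] = np.nan
                per_probe_rows.append(row)
            per_probe = pd.DataFrame(per_probe_rows)
            _write(per_probe, out / "per_probe.tsv", cfg, index=False)
            activity = image_quant.resolve_nested_groups(per_probe, panel)
            _write(activity, out / "activity_table.tsv", cfg, index=False)
            versus = image_quant.abundance_vs_activity(activity)
            _write(versus, out / "abundance_vs_activity.tsv", cfg, index=False)
            _log(stage, f"{len(cells)} cells quantified")

            stage = "cardfish-vs-16s"
            agree = clustering.cardfish_vs_16s_agreement(
                per_probe, rel, taxonomy, seed=rng_seed
            )
            _write(agree["paired"], out / "cardfish_vs_16s.tsv", cfg, index=False)

        stage = "log"
        (out / "run_log.txt").write_text("\n".join(_RUN_LOG) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage [{stage}] failed: {exc}") from exc
    return out
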