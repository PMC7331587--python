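"""Configuration and the end-to-end analysis runner.

The runner chains the stages of the workflow: count normalization and log
transform -> co-expression network (correlation, soft threshold, TOM) ->
dynamic tree cut into modules with hub (eigen) proteins -> module-trait
correlation -> per-protein ANOVA with post-hoc pattern classification ->
module x pattern-group over-representation screen -> optional enrichment and
PPI mapping.  Runs are deterministic for a fixed config and inputs; a
manifest records the config hash and seeds.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import __version__
from .io import AbundanceMatrix, TraitDesign, write_table
from .network import adjacency, pearson_matrix, scan_soft_threshold, tom, tom_dissimilarity
from .modules import (
    ModulePartition,
    assign_eigen_proteins,
    dynamic_tree_cut,
    grow_modules_by_membership,
    hierarchical_cluster,
    module_trait_correlation,
)
from .preprocess import filter_low_detection, log_transform, normalize
from .screen import classify_patterns, differential_result, overlap_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the reference workflow.

    A soft-threshold power of 10 (with an optional scan at r2 >= 0.90), a
    minimum module size of 5, a tree-cut sensitivity (deep split) of 4 and a
    significance level alpha = 0.05 throughout.
    """

    normalization: str = "total_count"
    min_detect_fraction: float = 0.0
    power: int = 10
    scan_powers: bool = True
    power_min: int = 1
    power_max: int = 30
    kme_threshold: float = 0.5
    r2_threshold: float = 0.90
    network_type: str = "unsigned"
    linkage: str = "average"
    min_module_size: int = 5
    deep_split: int = 4
    alpha: float = 0.05
    posthoc_adjust: str = "holm"
    bh_family: str = "all_cells"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.normalization not in ("total_count", "quantile", "none"):
            problems.append(f"normalization {self.normalization!r}")
        if not 0.0 <= self.min_detect_fraction <= 1.0:
            problems.append("min_detect_fraction must be in [0, 1]")
        if self.power < 1:
            problems.append("power must be >= 1")
        if not 0 <= self.deep_split <= 4:
            problems.append("deep_split must be in 0..4")
        if not 0 < self.alpha < 1:
            problems.append("alpha must be in (0, 1)")
        if self.min_module_size < 2:
            problems.append("min_module_size must be >= 2")
        if self.network_type not in ("unsigned", "signed"):
            problems.append(f"network_type {self.network_type!r}")
        if self.linkage not in ("complete", "average"):
            problems.append(f"linkage {self.linkage!r}")
        if self.posthoc_adjust not in ("holm", "bh"):
            problems.append(f"posthoc_adjust {self.posthoc_adjust!r}")
        if self.bh_family not in ("all_cells", "per_group"):
            problems.append(f"bh_family {self.bh_family!r}")
        if not 0 < self.r2_threshold <= 1:
            problems.append("r2_threshold must be in (0, 1]")
        if not 0 < self.kme_threshold < 1:
            problems.append("kme_threshold must be in (0, 1)")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file into a typed PipelineConfig.

    Unknown keys are rejected with a closest-match suggestion; domain
    violations are reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        msgs = []
        for key in sorted(unknown):
            close = difflib.get_close_matches(key, known, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            msgs.append(f"unknown config key {key!r}{hint}")
        raise ValueError("; ".join(msgs))
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    normalized: AbundanceMatrix
    scan: object | None
    partition: ModulePartition
    module_trait: object
    differential: object
    patterns: object
    screen: object
    manifest: dict


def run_pipeline(
    cfg: PipelineConfig,
    counts: AbundanceMatrix,
    design: TraitDesign,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full workflow on a count matrix and trait design."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    m = counts
    if cfg.min_detect_fraction > 0:
        m = stage("filter", filter_low_detection, m, cfg.min_detect_fraction)
    if m.value_kind == "counts" and cfg.normalization != "none":
        m = stage("normalize", normalize, m, cfg.normalization)
    logm = stage("log_transform", log_transform, m)

    scan = None
    power = cfg.power
    if cfg.scan_powers:
        scan = stage(
            "soft_threshold_scan",
            scan_soft_threshold,
            logm,
            list(range(cfg.power_min, cfg.power_max + 1)),
            cfg.r2_threshold,
            cfg.network_type,
        )
        power = scan.selected_power

    corr = stage("correlation", pearson_matrix, logm)
    adj = stage("adjacency", adjacency, corr, power, cfg.network_type)
    dis = stage("tom", lambda a: tom_dissimilarity(tom(a)), adj)
    dend = stage("clustering", hierarchical_cluster, dis, adj.protein_ids, cfg.linkage)
    part = stage(
        "tree_cut", dynamic_tree_cut, dend, dis, cfg.min_module_size, cfg.deep_split
    )
    part = stage(
        "membership_growth",
        grow_modules_by_membership,
        part,
        logm.subset_proteins(adj.protein_ids),
        cfg.kme_threshold,
    )
    part = stage("eigen_proteins", assign_eigen_proteins, part, adj)
    # trait correlation and ANOVA run on the same normalized log matrix,
    # restricted to the proteins that entered the network
    logm_net = logm.subset_proteins(adj.protein_ids)
    mt = stage("module_trait", module_trait_correlation, part, logm_net, design)
    diff = stage("differential", differential_result, logm_net, design, cfg.posthoc_adjust)
    pats = stage("patterns", classify_patterns, diff, cfg.alpha)
    scr = stage(
        "overlap_screen",
        overlap_screen,
        part,
        pats,
        set(adj.protein_ids),
        cfg.alpha,
        cfg.bh_family,
    )

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_proteins_input": counts.n_proteins,
        "n_proteins_network": len(adj.protein_ids),
        "n_samples": counts.n_samples,
        "power_used": int(power),
        "n_modules": len(part.module_labels),
    }
    result = PipelineResult(cfg, logm, scan, part, mt, diff, pats, scr, manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(part.to_frame().set_index("protein_id"), out / "modules.tsv")
        write_table(mt.set_index("module"), out / "module_trait.tsv")
        write_table(diff.join(pats), out / "differential.tsv")
        if len(scr):
            write_table(scr.set_index("module"), out / "overlap_screen.tsv")
        if scan is not None:
            write_table(scan.to_frame().set_index("power"), out / "soft_threshold_scan.tsv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
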