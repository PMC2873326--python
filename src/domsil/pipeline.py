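"""End-to-end orchestration: expression -> domains -> features -> trees.

Stages can run individually (see :mod:`domsil.cli`) or end-to-end via
:func:`run_pipeline`; both paths produce byte-identical tables.  Every
run writes its intermediate tables, per-Mb gene count tracks, fitted
trees (JSON + plain-text rules) and a manifest recording the config,
seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import citree, de, domains as dom, features as feat, io
from .models import GeneModel, L1Domain, ProbeMatrix, RepeatElement

logger = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_STAGE = 3


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    genes: str
    probe_map: str
    matrix: str
    design: str
    repeats: str
    chrom: str
    chrom_len: int
    transgene_site: int
    silent_probes: str | None = None
    domains_bed: str | None = None
    manifest_tsv: str | None = None
    alpha: float = 0.05
    window: int = dom.DEFAULT_WINDOW
    hl1_threshold: float | None = None
    min_domain_size: int = dom.DEFAULT_MIN_DOMAIN_SIZE
    fl_min_fraction: float = 0.9
    deciles: tuple = (10, 20, 30, 40, 50)
    tree: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "deciles" in raw:
            raw["deciles"] = tuple(raw["deciles"])
        return cls(**raw)

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for key in ("genes", "probe_map", "matrix", "design", "repeats",
                    "silent_probes", "domains_bed", "manifest_tsv"):
            value = getattr(self, key)
            if value is not None and not (base / value).exists():
                raise FileNotFoundError(f"config key {key!r}: no such file {value}")
        if not (0 <= self.transgene_site < self.chrom_len):
            raise ValueError("transgene_site must lie on the chromosome")

    def tree_params(self) -> citree.TreeParams:
        return citree.TreeParams(seed=self.seed, **self.tree)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_de(
    matrix: ProbeMatrix,
    genes: list[GeneModel],
    silent_probe_ids: list[str] | None,
    alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame, de.ModeratedTParams, float]:
    """Probe- and gene-level differential expression."""
    if silent_probe_ids:
        baseline = de.estimate_silent_baseline(matrix, silent_probe_ids)
    else:
        baseline = -math.inf  # no silent-gene list: skip the filter
    params, probe_de = de.run_probe_de(matrix, baseline=baseline, alpha=alpha)
    gene_de = de.aggregate_gene_status(genes, probe_de)
    n_status = gene_de["status"].value_counts().to_dict()
    logger.info("gene status counts: %s (baseline %.3g)", n_status, baseline)
    return probe_de, gene_de, params, baseline


def stage_domains(
    repeats: list[RepeatElement],
    config: RunConfig,
) -> tuple[list[L1Domain], dom.DensityTrack]:
    """L1 coverage track and HL1/LL1 segmentation (or pass-through BED)."""
    track = dom.coverage_track(
        repeats, config.chrom, config.chrom_len, config.window, class_filter="L1"
    )
    if config.domains_bed is not None:
        domains = io.read_domains_bed(config.domains_bed)
        logger.info("segmentation bypassed: %d domains read from %s",
                    len(domains), config.domains_bed)
    else:
        domains = dom.segment_domains(track, config.hl1_threshold, config.min_domain_size)
    dom.check_tiling(domains, config.chrom_len)
    return domains, track


def stage_features(
    genes: list[GeneModel],
    repeats: list[RepeatElement],
    domains: list[L1Domain],
    config: RunConfig,
) -> pd.DataFrame:
    manifest = (
        feat.read_manifest(config.manifest_tsv)
        if config.manifest_tsv is not None else feat.default_manifest()
    )
    return feat.build_feature_table(
        genes, repeats, domains, config.chrom_len, config.transgene_site, manifest
    )


def stage_trees(
    table: pd.DataFrame,
    gene_de: pd.DataFrame,
    config: RunConfig,
) -> dict[str, citree.TreeModel]:
    """Classification trees per decile plus one regression tree."""
    X = table.drop(columns=["gene_id"])
    params = config.tree_params()
    trees: dict[str, citree.TreeModel] = {}
    for q in config.deciles:
        labels = de.decile_labels(gene_de, q)
        trees[f"classification_top{q}"] = citree.grow_tree(X, labels, params, kind="binary")
    response = de.regression_response(gene_de)
    trees["regression"] = citree.grow_tree(X, response, params, kind="continuous")
    return trees


def gene_count_track(
    genes: list[GeneModel], gene_de: pd.DataFrame, chrom_len: int, status: str | None = None
) -> np.ndarray:
    """Genes per Mb (optionally restricted to one DE status), by gene midpoint."""
    n = -(-chrom_len // 1_000_000)
    counts = np.zeros(n)
    wanted = None
    if status is not None:
        wanted = set(gene_de.loc[gene_de["status"] == status, "gene_id"])
    for g in genes:
        if wanted is not None and g.gene_id not in wanted:
            continue
        mid = (g.interval.start + g.interval.end) // 2
        counts[mid // 1_000_000] += 1
    return counts


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """Execute every stage and write all declared outputs under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = io.read_gene_models(config.genes, config.probe_map)
    repeats = io.read_repeats(config.repeats, config.fl_min_fraction)
    matrix = io.read_probe_matrix(config.matrix, config.design)
    silent = io.read_id_list(config.silent_probes) if config.silent_probes else None

    probe_de, gene_de, mt_params, baseline = stage_de(matrix, genes, silent, config.alpha)
    domains, track = stage_domains(repeats, config)
    table = stage_features(genes, repeats, domains, config)
    trees = stage_trees(table, gene_de, config)

    paths: dict[str, Path] = {}

    def save(name: str, path: Path) -> Path:
        paths[name] = path
        return path

    io.write_table(probe_de, save("probe_de", out / "probe_de.tsv"))
    io.write_table(gene_de, save("gene_de", out / "gene_de.tsv"))
    io.write_domains_bed(domains, save("domains", out / "domains.bed"))
    io.write_bedgraph(config.chrom, config.window, track.values,
                      save("l1_track", out / "l1_density.bedgraph"), config.chrom_len)
    table_out = table.copy()
    io.write_table(table_out, save("features", out / "features.tsv"))
    for status, fname in (("down", "down_genes_per_mb.bedgraph"),
                          ("up", "up_genes_per_mb.bedgraph"),
                          (None, "genes_per_mb.bedgraph")):
        counts = gene_count_track(genes, gene_de, config.chrom_len, status)
        io.write_bedgraph(config.chrom, 1_000_000, counts,
                          save(fname.split(".")[0], out / fname), config.chrom_len)
    for name, tree in trees.items():
        p = save(f"tree_{name}", out / f"tree_{name}.json")
        p.write_text(tree.to_json())
        r = save(f"rules_{name}", out / f"tree_{name}.rules.txt")
        r.write_text("\n".join(citree.tree_rules(tree)) + "\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "baseline": None if math.isinf(baseline) else baseline,
        "moderated_t": {"d0": mt_params.d0 if math.isfinite(mt_params.d0) else "inf",
                        "s0_sq": mt_params.s0_sq},
        "counts": {
            "probes": len(probe_de),
            "genes": len(genes),
            "gene_status": gene_de["status"].value_counts().to_dict(),
            "severity": gene_de["severity"].value_counts().to_dict(),
            "domains": {t: sum(d.domain_type == t for d in domains) for t in ("HL1", "LL1")},
        },
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = mpath
    return paths
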