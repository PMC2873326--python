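"""Synthetic chromosomes and expression data with a planted silencing effect.

The generator emulates the study conditions the pipeline is built for:
a mouse autosome partitioned into alternating gene-poor, L1-dense (HL1)
and gene-rich, L1-depleted (LL1) domains of a few hundred kb to several
Mb; genes measured by 1-4 probe sets each; control and treated
replicate groups with Gaussian log2 noise; and a planted silencing
effect capped at a 50% reduction per gene — the biological maximum when
only one of two alleles responds to the Xist transgene.

Silencing is modelled phenomenologically as a per-gene Bernoulli draw
whose probability depends on domain context (a boost inside HL1
domains, protection deep inside large LL1 domains), with the reduction
fraction drawn uniformly up to the 50% cap.  Alternative effect models
plant a SINE-density effect (the reciprocal signal seen on chromosomes
whose L1 domain structure is weak), a single hard rule on associated
LL1 domain size (for split-recovery tests), or no effect at all (null
calibration).  Every run is deterministic given its seed, and ground
truth is returned alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._intervals import IntervalUnion
from .features import associated_domain
from .io import (
    write_domains_bed, write_id_list, write_probe_matrix, write_repeats_bed, write_table,
)
from .models import GeneModel, GenomicInterval, L1Domain, ProbeMatrix, RepeatElement

EFFECT_MODELS = ("domain", "sine", "ll1_size_rule", "none")

#: L1 subfamilies drawn for simulated elements (matches the feature panel)
from .features import L1_SUBFAMILIES  # noqa: E402


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator (all sizes in bp)."""

    chrom: str = "chrS"
    chrom_len: int = 100_000_000
    # domain architecture
    hl1_size_range: tuple = (600_000, 3_000_000)
    ll1_size_range: tuple = (800_000, 6_000_000)
    # gene content
    gene_per_mb_hl1: float = 2.0
    gene_per_mb_ll1: float = 18.0
    gene_size_range: tuple = (2_000, 30_000)
    # repeat content (coverage fractions / rates)
    l1_cov_hl1: float = 0.45
    l1_cov_ll1: float = 0.05
    fl_per_mb_hl1: float = 3.0
    fl_per_mb_ll1: float = 0.1
    sine_cov_hl1: float = 0.05
    sine_cov_ll1: float = 0.25
    ltr_cov: float = 0.08
    # expression design
    probes_per_gene: tuple = (1, 4)
    replicates: int = 3
    noise_sd: float = 0.25
    control_mean_range: tuple = (6.0, 12.0)
    n_silent_probes: int = 100
    silent_range: tuple = (3.0, 4.5)
    n_unexpressed_probes: int = 50
    unexpressed_range: tuple = (2.5, 3.5)
    # planted effect
    effect_model: str = "domain"
    base_p: float = 0.50
    hl1_boost: float = 0.40
    ll1_core_protection: float = 0.30
    ll1_size_threshold: int = 1_300_000
    core_trunc: int = 500_000
    sine_density_threshold: float = 14.5  # percent, for the 'sine' model
    min_reduction: float = 0.1
    max_reduction: float = 0.5
    transgene_site_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if not (0 < self.max_reduction <= 0.5):
            raise ValueError("max_reduction must lie in (0, 0.5]: only one allele silences")
        for p in (self.base_p, self.hl1_boost, self.ll1_core_protection):
            if not (0 <= p <= 1):
                raise ValueError("effect probabilities must lie in [0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")

    @property
    def transgene_site(self) -> int:
        return int(self.transgene_site_frac * self.chrom_len)


@dataclass
class SimulatedBundle:
    config: SimConfig
    genes: list[GeneModel]
    repeats: list[RepeatElement]
    domains: list[L1Domain]
    matrix: ProbeMatrix
    silent_probes: list[str]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# chromosome
# ---------------------------------------------------------------------------

def _plant_domains(config: SimConfig, rng: np.random.Generator) -> list[L1Domain]:
    domains = []
    pos = 0
    dtype = "LL1" if rng.random() < 0.5 else "HL1"
    while pos < config.chrom_len:
        lo, hi = config.hl1_size_range if dtype == "HL1" else config.ll1_size_range
        size = int(rng.uniform(lo, hi))
        end = min(pos + size, config.chrom_len)
        if config.chrom_len - end < min(config.hl1_size_range[0], config.ll1_size_range[0]):
            end = config.chrom_len  # avoid a trailing sliver
        domains.append(L1Domain(dtype, GenomicInterval(config.chrom, pos, end)))
        pos = end
        dtype = "HL1" if dtype == "LL1" else "LL1"
    return domains


def _place_repeat_mass(
    rng: np.random.Generator,
    domain: L1Domain,
    coverage: float,
    length_range: tuple,
    clump_block: int = 500_000,
    clump_shape: float = 4.0,
    clump_bounds: tuple = (0.8, 1.8),
) -> list[tuple[int, int]]:
    """Place fragments with locally clumped intensity around a coverage target.

    Repeat landscapes are clumpy: local insertion density varies well
    beyond Poisson.  Placement is doubly stochastic — each ~500 kb block
    gets a Gamma-modulated intensity (mean = the domain target) and
    fragments are placed uniformly within it until the expected union,
    by the Poisson-coverage law 1 - exp(-placed/size), hits the block's
    modulated target.  The modulation is truncated so a block keeps its
    domain's density character (an LL1 block never reaches HL1-level
    coverage and vice versa); domain-mean coverage stays on target while
    local window densities fluctuate as in real annotation.
    """
    if coverage <= 0:
        return []
    if coverage >= 1:
        raise ValueError("coverage target must be < 1")
    out = []
    pos = domain.interval.start
    while pos < domain.interval.end:
        block_end = min(pos + clump_block, domain.interval.end)
        size = block_end - pos
        mult = float(np.clip(rng.gamma(clump_shape, 1.0 / clump_shape), *clump_bounds))
        local_cov = min(coverage * mult, 0.95)
        budget = -math.log(1.0 - local_cov) * size
        placed = 0.0
        while placed < budget:
            length = int(rng.uniform(*length_range))
            start = int(rng.uniform(pos, max(pos + 1, block_end - length)))
            end = min(start + length, block_end)
            if end > start:
                out.append((start, end))
                placed += end - start
        pos = block_end
    return out


def _place_genes(
    config: SimConfig, domains: list[L1Domain], rng: np.random.Generator
) -> list[GeneModel]:
    intervals: list[tuple[int, int, str]] = []
    for d in domains:
        per_mb = config.gene_per_mb_hl1 if d.domain_type == "HL1" else config.gene_per_mb_ll1
        n = rng.poisson(per_mb * d.size / 1e6)
        for _ in range(n):
            for _attempt in range(20):
                length = int(rng.uniform(*config.gene_size_range))
                if length >= d.size:
                    length = max(1000, d.size // 2)
                start = int(rng.uniform(d.interval.start, d.interval.end - length))
                end = start + length
                if all(e <= s0 or s >= e0 for s0, e0, _ in intervals for s, e in [(start, end)]):
                    strand = "+" if rng.random() < 0.5 else "-"
                    intervals.append((start, end, strand))
                    break
    intervals.sort()
    genes = []
    for i, (start, end, strand) in enumerate(intervals):
        gene_id = f"g{i:04d}"
        iv = GenomicInterval(config.chrom, start, end, strand)
        genes.append(GeneModel(gene_id, iv, _make_exons(iv, rng)))
    return genes


def _make_exons(iv: GenomicInterval, rng: np.random.Generator) -> list[GenomicInterval]:
    n_ex = int(rng.integers(2, 9))
    # 2*n_ex sorted breakpoints delimit alternating exon/intron blocks
    cuts = np.sort(rng.integers(iv.start, iv.end, size=2 * n_ex - 2))
    bounds = np.concatenate([[iv.start], cuts, [iv.end]])
    exons = []
    for k in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if e > s:
            exons.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    if not exons:
        exons = [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand)]
    return exons


def simulate_chromosome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[RepeatElement], list[L1Domain]]:
    """Generate genes, repeats and the planted domain structure."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    domains = _plant_domains(config, rng)
    repeats: list[RepeatElement] = []
    for d in domains:
        hl1 = d.domain_type == "HL1"
        l1_cov = config.l1_cov_hl1 if hl1 else config.l1_cov_ll1
        sine_cov = config.sine_cov_hl1 if hl1 else config.sine_cov_ll1
        # most genomic L1 copies are short 5'-truncated fragments
        for start, end in _place_repeat_mass(rng, d, l1_cov, (100, 800),
                                             clump_bounds=(0.9, 1.8)):
            sub = str(rng.choice(L1_SUBFAMILIES))
            repeats.append(
                RepeatElement(GenomicInterval(config.chrom, start, end), "L1", sub, False)
            )
        fl_rate = config.fl_per_mb_hl1 if hl1 else config.fl_per_mb_ll1
        for _ in range(rng.poisson(fl_rate * d.size / 1e6)):
            length = int(rng.uniform(5800, 6500))
            start = int(rng.uniform(d.interval.start, max(d.interval.start + 1,
                                                          d.interval.end - length)))
            end = min(start + length, d.interval.end)
            sub = str(rng.choice(L1_SUBFAMILIES))
            if end - start >= 5400:  # full-length only if not clipped short
                repeats.append(
                    RepeatElement(GenomicInterval(config.chrom, start, end), "L1", sub, True)
                )
        for start, end in _place_repeat_mass(rng, d, sine_cov, (100, 300)):
            repeats.append(
                RepeatElement(GenomicInterval(config.chrom, start, end), "SINE", "B1", False)
            )
        for start, end in _place_repeat_mass(rng, d, config.ltr_cov, (300, 1000)):
            repeats.append(
                RepeatElement(GenomicInterval(config.chrom, start, end), "LTR", "MTA", False)
            )
    repeats.sort(key=lambda r: (r.interval.start, r.interval.end))
    genes = _place_genes(config, domains, rng)
    return genes, repeats, domains


# ---------------------------------------------------------------------------
# planted effect and expression
# ---------------------------------------------------------------------------

def _gene_context(
    genes: list[GeneModel],
    repeats: list[RepeatElement],
    domains: list[L1Domain],
    config: SimConfig,
) -> pd.DataFrame:
    from .domains import core_domain
    from .features import _flank_window

    sine_union = IntervalUnion(
        [r.interval.start for r in repeats if r.repeat_class == "SINE"],
        [r.interval.end for r in repeats if r.repeat_class == "SINE"],
    )
    large_cores = [
        c for d in domains
        if d.domain_type == "LL1" and d.size > config.ll1_size_threshold
        and (c := core_domain(d, config.core_trunc)) is not None
    ]
    rows = []
    for g in genes:
        hl1 = any(
            d.domain_type == "HL1" and d.interval.overlaps(g.interval) for d in domains
        )
        assoc_ll1 = associated_domain(g, domains, "LL1")
        in_large_core = any(c.overlaps(g.interval) for c in large_cores)
        lo, hi = _flank_window(g, "upstream", 100_000, config.chrom_len)
        sine_up = 100.0 * sine_union.covered(lo, hi) / (hi - lo) if hi > lo else float("nan")
        rows.append(
            {
                "gene_id": g.gene_id,
                "in_hl1": hl1,
                "ll1_size_mb": assoc_ll1.size / 1e6 if assoc_ll1 else float("nan"),
                "in_large_ll1_core": in_large_core,
                "sine_up_100kb_pct": sine_up,
            }
        )
    return pd.DataFrame(rows)


def _silencing_probability(ctx: pd.DataFrame, config: SimConfig) -> np.ndarray:
    model = config.effect_model
    if model == "none":
        return np.zeros(len(ctx))
    if model == "domain":
        p = (
            config.base_p
            + config.hl1_boost * ctx["in_hl1"].to_numpy(dtype=float)
            - config.ll1_core_protection * ctx["in_large_ll1_core"].to_numpy(dtype=float)
        )
        return np.clip(p, 0.0, 1.0)
    if model == "sine":
        low_sine = (ctx["sine_up_100kb_pct"].to_numpy() <= config.sine_density_threshold)
        return np.clip(config.base_p + config.hl1_boost * low_sine.astype(float), 0.0, 1.0)
    # 'll1_size_rule': a single hard rule on associated LL1 size
    hit = ctx["ll1_size_mb"].to_numpy() * 1e6 <= config.ll1_size_threshold
    return hit.astype(float)


def simulate_expression(
    genes: list[GeneModel],
    context: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeMatrix, list[str], pd.DataFrame]:
    """Probe matrix with a planted effect, silent-probe list and ground truth.

    Probe sets are assigned here (1-4 per gene, recorded on the gene
    models).  Treated means shift by log2(1 - reduction); all values
    get independent Gaussian log2 noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    p_silence = _silencing_probability(context, config)
    silenced = rng.random(len(genes)) < p_silence
    reduction = np.where(
        silenced, rng.uniform(config.min_reduction, config.max_reduction, len(genes)), 0.0
    )
    probe_ids: list[str] = []
    probe_lfc: list[float] = []
    for i, gene in enumerate(genes):
        n_probes = int(rng.integers(config.probes_per_gene[0], config.probes_per_gene[1] + 1))
        gene.probe_sets = [f"{gene.gene_id}_ps{k}" for k in range(n_probes)]
        lfc = math.log2(1.0 - reduction[i]) if silenced[i] else 0.0
        for pid in gene.probe_sets:
            probe_ids.append(pid)
            probe_lfc.append(lfc)
    n_rep = config.replicates
    samples = [f"ctrl_{k + 1}" for k in range(n_rep)] + [f"dox_{k + 1}" for k in range(n_rep)]
    design = pd.Series(["control"] * n_rep + ["treated"] * n_rep, index=samples)
    base = rng.uniform(*config.control_mean_range, size=len(probe_ids))
    means = np.tile(base[:, None], (1, 2 * n_rep))
    means[:, n_rep:] += np.asarray(probe_lfc)[:, None]
    # silent and unexpressed probes sit at the low end of the intensity scale
    silent_ids = [f"silent_{k:03d}" for k in range(config.n_silent_probes)]
    silent_base = rng.uniform(*config.silent_range, size=len(silent_ids))
    unexpr_ids = [f"unexpr_{k:03d}" for k in range(config.n_unexpressed_probes)]
    unexpr_base = rng.uniform(*config.unexpressed_range, size=len(unexpr_ids))
    all_ids = probe_ids + silent_ids + unexpr_ids
    all_means = np.vstack(
        [means, np.tile(silent_base[:, None], (1, 2 * n_rep)),
         np.tile(unexpr_base[:, None], (1, 2 * n_rep))]
    )
    values = all_means + rng.normal(0.0, config.noise_sd, size=all_means.shape)
    matrix = ProbeMatrix(pd.DataFrame(values, index=all_ids, columns=samples), design)
    truth = context.copy()
    truth["silenced"] = silenced
    truth["reduction"] = reduction
    return matrix, silent_ids, truth


def simulate_bundle(config: SimConfig) -> SimulatedBundle:
    """End-to-end simulation: chromosome, expression and ground truth."""
    rng = np.random.default_rng(config.seed)
    genes, repeats, domains = simulate_chromosome(config, rng)
    context = _gene_context(genes, repeats, domains, config)
    matrix, silent_ids, truth = simulate_expression(genes, context, config, rng)
    return SimulatedBundle(config, genes, repeats, domains, matrix, silent_ids, truth)


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------

def write_genes_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = g.exons or [iv]
            sizes = ",".join(str(e.length) for e in exons) + ","
            offsets = ",".join(str(e.start - iv.start) for e in exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}"
                f"\t{iv.start}\t{iv.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def write_probe_map(genes: list[GeneModel], path) -> None:
    rows = [
        {"probe_set_id": pid, "gene_id": g.gene_id} for g in genes for pid in g.probe_sets
    ]
    pd.DataFrame(rows, columns=["probe_set_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def write_fixture_bundle(bundle: SimulatedBundle, out_dir) -> dict[str, Path]:
    """Write a complete, pipeline-consumable input set plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.bed",
        "repeats": out / "repeats.bed",
        "domains": out / "domains_truth.bed",
        "matrix": out / "matrix.tsv",
        "design": out / "design.tsv",
        "probe_map": out / "probe_map.tsv",
        "silent": out / "silent_probes.txt",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_genes_bed12(bundle.genes, paths["genes"])
    write_repeats_bed(bundle.repeats, paths["repeats"])
    write_domains_bed(bundle.domains, paths["domains"])
    write_probe_matrix(bundle.matrix, paths["matrix"], paths["design"])
    write_probe_map(bundle.genes, paths["probe_map"])
    write_id_list(bundle.silent_probes, paths["silent"])
    write_table(bundle.truth, paths["truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=False)
    return paths


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    field_names = set(SimConfig.__dataclass_fields__)
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items() if k in field_names}
    return SimConfig(**kwargs)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)


def weak_domain_config(**overrides) -> SimConfig:
    """Chromosome-12-like conditions: weak L1-domain modularity, SINE effect.

    Some autosomes lack clear-cut L1 modularity: gene-rich regions are
    regularly interrupted by short high-L1 stretches and no large
    L1-depleted domain exists.  This preset shrinks the domains and the
    HL1/LL1 L1-density contrast so domain placement carries little
    signal, and plants the silencing effect on local SINE density
    instead (SINEs distribute reciprocally to L1s): genes whose 100 kb
    upstream SINE coverage is at or below the threshold are boosted.
    """
    base = dict(
        effect_model="sine",
        hl1_size_range=(400_000, 1_200_000),
        ll1_size_range=(600_000, 2_000_000),
        l1_cov_hl1=0.20,
        l1_cov_ll1=0.12,
        sine_cov_hl1=0.12,
        sine_cov_ll1=0.18,
        gene_per_mb_hl1=6.0,
        gene_per_mb_ll1=14.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def chr3_like_rule_config(**overrides) -> SimConfig:
    """Chromosome-3-like conditions for split-point recovery.

    No large L1-depleted domain: LL1 sizes span 0.8-3 Mb so the planted
    hard rule on associated LL1 size (silenced iff <= the 1.3 Mb
    threshold) has cases on both sides.
    """
    base = dict(
        effect_model="ll1_size_rule",
        chrom_len=50_000_000,
        ll1_size_range=(800_000, 2_400_000),
    )
    base.update(overrides)
    return SimConfig(**base)
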