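"""Per-gene genomic feature catalogue.

The default catalogue contains exactly 83 candidate predictors in five
families:

* ``intrinsic`` — gene size, intron size;
* ``transgene_distance`` — distance from the transgene integration site;
* ``local_density`` — percent coverage of L1 / SINE / LTR repeats in
  windows of 10, 100, 500 and 1000 kb up/downstream of the gene
  (strand-relative) plus over the gene body;
* ``domain`` — placement relative to HL1/LL1 domains: overlap flags,
  size (Mb) of the associated domain of each type, overlap with core
  domains (domains truncated by 250 or 500 kb at each boundary),
  distances to the nearest HL1, LL1 and domain boundary;
* ``fl_subfamily`` — distance to, and orientation (1 = upstream,
  -1 = downstream) of, the nearest full-length L1 element of each of
  21 mouse L1 subfamilies.

Feature columns are named ``x<index>_<description>``.  Indices with a
published meaning keep it: x5 (HL1 overlap), x25/x26 (L1/SINE density
100 kb upstream), x30/x31 (associated LL1/HL1 size), x33/x34 (core-LL1
overlap at 250/500 kb truncation), x37 (core-HL1 overlap at 500 kb),
x44 (distance to nearest FL L1_Mus2), x53 (orientation of nearest FL
L1Md_F2), x60 (distance to nearest FL L1VL4), x80 (FL Lx4B), x82
(FL Lx5).  The catalogue itself is data: an editable TSV manifest
shipped with the package.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import IntervalUnion
from .domains import core_domain
from .models import GeneModel, GenomicInterval, L1Domain, RepeatElement

logger = logging.getLogger(__name__)

FAMILIES = ("intrinsic", "transgene_distance", "local_density", "domain", "fl_subfamily")

#: default mouse L1 subfamily panel, in manifest order
L1_SUBFAMILIES = (
    "L1_Mus1", "L1_Mus2", "L1_Mus3", "L1Md_A", "L1Md_T", "L1Md_F2", "L1Md_F",
    "L1Md_F3", "L1Md_Gf", "L1VL4", "L1VL1", "Lx", "Lx2", "Lx3", "Lx3_Mus",
    "Lx4A", "Lx6", "Lx7", "Lx8", "Lx4B", "Lx5",
)

DENSITY_WINDOWS = (10_000, 100_000, 500_000, 1_000_000)


@dataclass(frozen=True)
class FeatureDefinition:
    """One manifest entry: which feature, of which family, with which parameters."""

    index: int
    name: str
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")

    @property
    def column(self) -> str:
        return f"x{self.index}_{self.name}"


# ---------------------------------------------------------------------------
# default manifest
# ---------------------------------------------------------------------------

def _density_def(index: int, cls: str, side: str, window: int) -> FeatureDefinition:
    if side == "body":
        name = f"{cls}_body_density"
        params = {"repeat_class": cls, "side": "body"}
    else:
        kb = window // 1000
        name = f"{cls}_{side}_{kb}kb_density"
        params = {"repeat_class": cls, "side": side, "window": window}
    return FeatureDefinition(index, name, "local_density", params)


def default_manifest() -> list[FeatureDefinition]:
    """Build the default 83-feature catalogue."""
    defs: list[FeatureDefinition] = [
        FeatureDefinition(1, "gene_size", "intrinsic", {"measure": "gene_size"}),
        FeatureDefinition(2, "intron_size", "intrinsic", {"measure": "intron_size"}),
        FeatureDefinition(3, "transgene_distance", "transgene_distance", {}),
        FeatureDefinition(4, "ll1_overlap", "domain", {"stat": "overlap", "domain_type": "LL1"}),
        FeatureDefinition(5, "hl1_overlap", "domain", {"stat": "overlap", "domain_type": "HL1"}),
    ]
    # up/downstream repeat densities; the (upstream, 100 kb) triple sits at
    # x25-x27 so that x25/x26 keep their published meaning
    i = 6
    for side, window in (
        ("upstream", 10_000), ("downstream", 10_000), ("downstream", 100_000),
        ("upstream", 500_000), ("downstream", 500_000), ("upstream", 1_000_000),
    ):
        for cls in ("L1", "SINE", "LTR"):
            defs.append(_density_def(i, cls, side, window))
            i += 1
    defs.append(_density_def(24, "L1", "downstream", 1_000_000))
    defs.append(_density_def(25, "L1", "upstream", 100_000))
    defs.append(_density_def(26, "SINE", "upstream", 100_000))
    defs.append(_density_def(27, "LTR", "upstream", 100_000))
    defs.append(_density_def(28, "SINE", "downstream", 1_000_000))
    defs.append(_density_def(29, "LTR", "downstream", 1_000_000))
    defs += [
        FeatureDefinition(30, "ll1_size_mb", "domain", {"stat": "size", "domain_type": "LL1"}),
        FeatureDefinition(31, "hl1_size_mb", "domain", {"stat": "size", "domain_type": "HL1"}),
        FeatureDefinition(32, "hl1_distance", "domain", {"stat": "distance", "domain_type": "HL1"}),
        FeatureDefinition(
            33, "core_ll1_250kb_overlap", "domain",
            {"stat": "core_overlap", "domain_type": "LL1", "trunc": 250_000},
        ),
        FeatureDefinition(
            34, "core_ll1_500kb_overlap", "domain",
            {"stat": "core_overlap", "domain_type": "LL1", "trunc": 500_000},
        ),
        FeatureDefinition(35, "ll1_distance", "domain", {"stat": "distance", "domain_type": "LL1"}),
        FeatureDefinition(
            36, "core_hl1_250kb_overlap", "domain",
            {"stat": "core_overlap", "domain_type": "HL1", "trunc": 250_000},
        ),
        FeatureDefinition(
            37, "core_hl1_500kb_overlap", "domain",
            {"stat": "core_overlap", "domain_type": "HL1", "trunc": 500_000},
        ),
        FeatureDefinition(38, "boundary_distance", "domain", {"stat": "boundary_distance"}),
        _density_def(39, "L1", "body", 0),
        _density_def(40, "SINE", "body", 0),
        _density_def(41, "LTR", "body", 0),
    ]
    i = 42
    for sub in L1_SUBFAMILIES:
        safe = sub.replace("/", "_")
        defs.append(
            FeatureDefinition(i, f"fl_{safe}_distance", "fl_subfamily",
                              {"subfamily": sub, "stat": "distance", "fl_only": True})
        )
        defs.append(
            FeatureDefinition(i + 1, f"fl_{safe}_orientation", "fl_subfamily",
                              {"subfamily": sub, "stat": "orientation", "fl_only": True})
        )
        i += 2
    indices = [d.index for d in defs]
    assert sorted(indices) == list(range(1, 84)), "default manifest must cover x1..x83"
    return sorted(defs, key=lambda d: d.index)


_MANIFEST_COLS = [
    "index", "name", "family", "repeat_class", "side", "window", "subfamily",
    "fl_only", "stat", "domain_type", "trunc", "measure",
]


def write_manifest(defs: list[FeatureDefinition], path) -> None:
    rows = []
    for d in defs:
        row = {"index": d.index, "name": d.name, "family": d.family}
        row.update(d.params)
        rows.append(row)
    df = pd.DataFrame(rows).reindex(columns=_MANIFEST_COLS)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_manifest(path) -> list[FeatureDefinition]:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    defs = []
    for row in df.to_dict("records"):
        params = {}
        for key in ("repeat_class", "side", "subfamily", "stat", "domain_type", "measure"):
            if key in row and isinstance(row[key], str) and row[key]:
                params[key] = row[key]
        for key in ("window", "trunc"):
            if key in row and pd.notna(row[key]):
                params[key] = int(row[key])
        if "fl_only" in row and pd.notna(row[key := "fl_only"]):
            params["fl_only"] = bool(row[key]) if not isinstance(row[key], str) else row[key] == "True"
        defs.append(FeatureDefinition(int(row["index"]), str(row["name"]), str(row["family"]), params))
    if len({d.index for d in defs}) != len(defs):
        raise ValueError("manifest indices must be unique")
    return defs


def load_default_manifest() -> list[FeatureDefinition]:
    """Load the packaged default manifest TSV."""
    ref = importlib.resources.files("domsil") / "data" / "feature_manifest.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_manifest(path)


# ---------------------------------------------------------------------------
# elementary feature computations
# ---------------------------------------------------------------------------

def intrinsic_features(gene: GeneModel) -> tuple[int, float]:
    """(gene_size, intron_size); intron_size is NaN when no exons are annotated."""
    gene_size = gene.interval.length
    if not gene.exons:
        return gene_size, float("nan")
    exonic = sum(e.length for e in gene.exons)
    return gene_size, float(gene_size - exonic)


def transgene_distance(gene: GeneModel, site: int) -> int:
    """bp between the integration site and the gene (0 if the site is inside)."""
    if gene.interval.start <= site < gene.interval.end:
        return 0
    if site < gene.interval.start:
        return gene.interval.start - site
    return site - gene.interval.end


def _flank_window(gene: GeneModel, side: str, window: int, chrom_len: int) -> tuple[int, int]:
    """Strand-relative window [start, end) clipped to the chromosome."""
    plus = gene.interval.strand != "-"
    before = (side == "upstream") == plus  # window at coordinates below the gene
    if side == "body":
        lo, hi = gene.interval.start, gene.interval.end
    elif before:
        lo, hi = gene.interval.start - window, gene.interval.start
    else:
        lo, hi = gene.interval.end, gene.interval.end + window
    return max(0, lo), min(chrom_len, hi)


def local_density(
    gene: GeneModel,
    union: IntervalUnion,
    window: int,
    side: str,
    chrom_len: int,
) -> float:
    """Percent repeat coverage in a strand-relative window next to the gene."""
    lo, hi = _flank_window(gene, side, window, chrom_len)
    if hi <= lo:
        return float("nan")
    return 100.0 * union.covered(lo, hi) / (hi - lo)


def _nearest_from_arrays(
    gene: GeneModel, starts: np.ndarray, ends: np.ndarray
) -> tuple[float, float]:
    g = gene.interval
    gaps = np.maximum(np.maximum(starts - g.end, g.start - ends), 0)
    # element is "before" the gene when it sits at lower coordinates;
    # for overlaps, compare midpoints (ties count as before)
    before = np.where(
        ends <= g.start, True,
        np.where(starts >= g.end, False, (starts + ends) <= (g.start + g.end)),
    )
    plus = g.strand != "-"
    orient = np.where(before == plus, 1, -1)
    # nearest by edge gap; tie -> upstream (orientation == 1)
    best = int(np.lexsort((-orient, gaps))[0])
    return float(gaps[best]), float(orient[best])


def nearest_subfamily_element(
    gene: GeneModel, repeats: list[RepeatElement], subfamily: str, fl_only: bool = True
) -> tuple[float, float]:
    """(distance, orientation) to the nearest element of an L1 subfamily.

    Orientation is 1 when the element lies upstream of the gene in the
    gene's own orientation, -1 downstream; ties in distance go to the
    upstream element.  (NaN, NaN) when the subfamily is absent.
    """
    cands = [
        r for r in repeats
        if r.subfamily == subfamily and (not fl_only or r.full_length)
        and r.interval.chrom == gene.interval.chrom
    ]
    if not cands:
        return float("nan"), float("nan")
    starts = np.array([r.interval.start for r in cands], dtype=np.int64)
    ends = np.array([r.interval.end for r in cands], dtype=np.int64)
    return _nearest_from_arrays(gene, starts, ends)


def associated_domain(gene: GeneModel, domains: list[L1Domain], domain_type: str) -> L1Domain | None:
    """The domain of the given type associated with a gene.

    Largest-overlap wins when several overlap; when none overlaps, the
    nearest domain of the type (leftmost on tie); None when the type is
    absent from the chromosome.
    """
    typed = [d for d in domains if d.domain_type == domain_type]
    if not typed:
        return None
    overlaps = [(d.interval.overlap_length(gene.interval), d) for d in typed]
    best_ov = max(ov for ov, _ in overlaps)
    if best_ov > 0:
        for ov, d in overlaps:  # first occurrence = leftmost on tie
            if ov == best_ov:
                return d
    return min(typed, key=lambda d: (gene.interval.distance(d.interval), d.interval.start))


def domain_features(
    gene: GeneModel, domains: list[L1Domain]
) -> dict[str, float]:
    """All domain-placement features for one gene."""
    if not domains:
        raise ValueError("empty domain list")
    out: dict[str, float] = {}
    for dtype in ("HL1", "LL1"):
        typed = [d for d in domains if d.domain_type == dtype]
        assoc = associated_domain(gene, domains, dtype)
        key = dtype.lower()
        out[f"{key}_overlap"] = float(
            any(d.interval.overlaps(gene.interval) for d in typed)
        )
        out[f"{key}_size_mb"] = assoc.size / 1e6 if assoc is not None else float("nan")
        out[f"{key}_distance"] = (
            float(min(gene.interval.distance(d.interval) for d in typed))
            if typed else float("nan")
        )
        for trunc in (250_000, 500_000):
            cores = [core_domain(d, trunc) for d in typed]
            out[f"core_{key}_{trunc // 1000}kb_overlap"] = float(
                any(c is not None and c.overlaps(gene.interval) for c in cores)
            )
    internal = [d.interval.end for d in domains[:-1]]
    if internal:
        out["boundary_distance"] = float(
            min(_point_distance(gene.interval, b) for b in internal)
        )
    else:
        out["boundary_distance"] = float("nan")
    return out


def _point_distance(iv: GenomicInterval, point: int) -> int:
    if iv.start <= point < iv.end:
        return 0
    return point - iv.end if point >= iv.end else iv.start - point


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

class FeatureContext:
    """Precomputed indexes over one chromosome's annotation."""

    def __init__(
        self,
        repeats: list[RepeatElement],
        domains: list[L1Domain],
        chrom_len: int,
        transgene_site: int,
    ):
        self.repeats = repeats
        self.domains = domains
        self.chrom_len = chrom_len
        self.transgene_site = transgene_site
        self.class_unions = {
            cls: IntervalUnion(
                [r.interval.start for r in repeats if r.repeat_class == cls],
                [r.interval.end for r in repeats if r.repeat_class == cls],
            )
            for cls in ("L1", "SINE", "LTR")
        }
        self._subfamily_arrays: dict[tuple[str, bool], tuple[np.ndarray, np.ndarray]] = {}

    def subfamily_arrays(self, subfamily: str, fl_only: bool) -> tuple[np.ndarray, np.ndarray]:
        key = (subfamily, fl_only)
        if key not in self._subfamily_arrays:
            cands = [
                r for r in self.repeats
                if r.subfamily == subfamily and (not fl_only or r.full_length)
            ]
            self._subfamily_arrays[key] = (
                np.array([r.interval.start for r in cands], dtype=np.int64),
                np.array([r.interval.end for r in cands], dtype=np.int64),
            )
        return self._subfamily_arrays[key]


def build_feature_table(
    genes: list[GeneModel],
    repeats: list[RepeatElement],
    domains: list[L1Domain],
    chrom_len: int,
    transgene_site: int,
    manifest: list[FeatureDefinition] | None = None,
) -> pd.DataFrame:
    """One row per gene, one named column per manifest entry."""
    if manifest is None:
        manifest = default_manifest()
    if len({d.index for d in manifest}) != len(manifest):
        raise ValueError("manifest indices must be unique")
    ctx = FeatureContext(repeats, domains, chrom_len, transgene_site)
    columns: dict[str, list[float]] = {d.column: [] for d in manifest}
    warned: set[str] = set()
    dom_cache: dict[str, dict[str, float]] = {}
    sub_cache: dict[tuple[str, str, bool], tuple[float, float]] = {}
    for gene in genes:
        dom = dom_cache.get(gene.gene_id)
        if dom is None and domains:
            dom = domain_features(gene, domains)
            dom_cache[gene.gene_id] = dom
        for d in manifest:
            columns[d.column].append(
                _compute_one(gene, d, ctx, dom, sub_cache, warned)
            )
    table = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})
    for d in manifest:
        table[d.column] = columns[d.column]
    return table


def _compute_one(gene, d: FeatureDefinition, ctx: FeatureContext, dom, sub_cache, warned):
    p = d.params
    if d.family == "intrinsic":
        gene_size, intron = intrinsic_features(gene)
        return float(gene_size) if p.get("measure") == "gene_size" else intron
    if d.family == "transgene_distance":
        return float(transgene_distance(gene, ctx.transgene_site))
    if d.family == "local_density":
        union = ctx.class_unions.get(p["repeat_class"])
        if union is None:
            return float("nan")
        return local_density(gene, union, p.get("window", 0), p["side"], ctx.chrom_len)
    if d.family == "domain":
        if dom is None:
            raise ValueError("domain features requested but no domains supplied")
        stat, dtype = p["stat"], p.get("domain_type", "")
        key = dtype.lower()
        if stat == "overlap":
            return dom[f"{key}_overlap"]
        if stat == "size":
            return dom[f"{key}_size_mb"]
        if stat == "distance":
            return dom[f"{key}_distance"]
        if stat == "core_overlap":
            return dom[f"core_{key}_{p['trunc'] // 1000}kb_overlap"]
        if stat == "boundary_distance":
            return dom["boundary_distance"]
        raise ValueError(f"unknown domain stat {stat!r}")
    if d.family == "fl_subfamily":
        sub = p["subfamily"]
        fl_only = bool(p.get("fl_only", True))
        cache_key = (gene.gene_id, sub, fl_only)
        if cache_key not in sub_cache:
            starts, ends = ctx.subfamily_arrays(sub, fl_only)
            if starts.size == 0:
                sub_cache[cache_key] = (float("nan"), float("nan"))
                if sub not in warned:
                    warned.add(sub)
                    logger.warning("no %selement of subfamily %s on this chromosome",
                                   "full-length " if fl_only else "", sub)
            else:
                sub_cache[cache_key] = _nearest_from_arrays(gene, starts, ends)
        dist, orient = sub_cache[cache_key]
        return dist if p["stat"] == "distance" else orient
    raise ValueError(f"unknown feature family {d.family!r}")
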