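"""Readers and writers for the pipeline's standard file formats.

Supported inputs: gene models as GFF3 (parsed with ``gffutils``) or
BED12; repeat annotation as RepeatMasker ``.out`` or BED6+; the probe
expression matrix, sample design and probe-set -> gene mapping as TSV.
Outputs are BED (domains), bedGraph (density tracks) and TSV tables.
All written coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted on read.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .models import GeneModel, GenomicInterval, L1Domain, ProbeMatrix, RepeatElement

logger = logging.getLogger(__name__)

#: canonical full-length L1 element size in bp
CANONICAL_L1_LENGTH = 6000

MISSING = "."


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------

def read_probe_map(path) -> dict[str, list[str]]:
    """Read a probe-set -> gene mapping TSV (columns probe_set_id, gene_id).

    Probe sets mapped to more than one gene are excluded entirely (only
    uniquely mapping probe sets are informative about a single locus);
    each exclusion is logged.
    Returns gene_id -> ordered list of probe-set ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_set_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"probe map {path} lacks required column {col!r}")
    counts = df.groupby("probe_set_id")["gene_id"].nunique()
    ambiguous = set(counts.index[counts > 1])
    if ambiguous:
        logger.warning(
            "excluding %d probe set(s) mapped to more than one gene: %s",
            len(ambiguous), sorted(ambiguous)[:10],
        )
    df = df[~df["probe_set_id"].isin(ambiguous)].drop_duplicates()
    mapping: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.gene_id, []).append(row.probe_set_id)
    return mapping


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _genes_from_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("ID", [g.id])[0]
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
        exons = []
        for ex in db.children(g, featuretype="exon"):
            exons.append(GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or "."))
        exons = _dedupe_exons(exons)
        genes.append(GeneModel(gene_id, interval, exons))
    return genes


def _dedupe_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping exon records (e.g. shared across transcripts)."""
    if not exons:
        return []
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    merged = [exons[0]]
    for ex in exons[1:]:
        last = merged[-1]
        if ex.start <= last.end:
            if ex.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, ex.end, last.strand)
        else:
            merged.append(ex)
    return merged


def _genes_from_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 line has {len(parts)} fields")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line ({exc})") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            interval = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
            exons = [
                GenomicInterval(chrom, start + off, start + off + sz, interval.strand)
                for off, sz in zip(offsets, sizes)
            ]
            genes.append(GeneModel(name, interval, exons))
    return genes


def read_gene_models(path, probe_map_path=None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 and attach probe-set mappings.

    The dialect is chosen from the file suffix (``.gff``/``.gff3`` vs
    ``.bed``).  Genes with no mapped probe set are retained with an
    empty ``probe_sets`` list (they are simply unscorable downstream).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _genes_from_gff3(path)
    elif path.suffix.lower() == ".bed":
        genes = _genes_from_bed12(path)
    else:
        raise ValueError(f"cannot infer gene-model dialect from suffix of {path}")
    if probe_map_path is not None:
        mapping = read_probe_map(probe_map_path)
        for g in genes:
            g.probe_sets = mapping.get(g.gene_id, [])
    return genes


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

_CLASS_MAP = {"LINE/L1": "L1", "L1": "L1", "SINE": "SINE", "LTR": "LTR"}


def _map_repeat_class(raw: str) -> str:
    if raw in _CLASS_MAP:
        return _CLASS_MAP[raw]
    head = raw.split("/")[0]
    if head == "LINE" and raw.startswith("LINE/L1"):
        return "L1"
    if head in ("SINE", "LTR"):
        return head
    return "other"


def _repeats_from_rm_out(path, fl_min_fraction, canonical_length) -> list[RepeatElement]:
    elements = []
    unknown: Counter = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            # header lines start with 'SW'/'score' or are blank
            if not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: RepeatMasker line has {len(parts)} fields")
            try:
                chrom = parts[4]
                start = int(parts[5]) - 1  # .out is 1-based inclusive
                end = int(parts[6])
                strand = "+" if parts[8] == "+" else "-"
                subfamily = parts[9]
                raw_class = parts[10]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line ({exc})") from None
            cls = _map_repeat_class(raw_class)
            if cls == "other":
                unknown[raw_class] += 1
            full = cls == "L1" and (end - start) >= fl_min_fraction * canonical_length
            elements.append(
                RepeatElement(GenomicInterval(chrom, start, end, strand), cls, subfamily, full)
            )
    if unknown:
        logger.info("repeat classes mapped to 'other': %s", dict(unknown))
    return elements


def _repeats_from_bed(path, fl_min_fraction, canonical_length) -> list[RepeatElement]:
    """BED6+ repeats: chrom start end subfamily score strand [class [full_length]]."""
    elements = []
    unknown: Counter = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: repeat BED needs >= 6 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from None
            subfamily = parts[3]
            strand = parts[5] if parts[5] in "+-" else "."
            raw_class = parts[6] if len(parts) > 6 else subfamily
            cls = _map_repeat_class(raw_class)
            if cls == "other":
                unknown[raw_class] += 1
            if len(parts) > 7 and parts[7] != MISSING:
                full = cls == "L1" and parts[7] not in ("0", "false", "False")
            else:
                full = cls == "L1" and (end - start) >= fl_min_fraction * canonical_length
            elements.append(
                RepeatElement(GenomicInterval(chrom, start, end, strand), cls, subfamily, full)
            )
    if unknown:
        logger.info("repeat classes mapped to 'other': %s", dict(unknown))
    return elements


def read_repeats(path, fl_min_fraction: float = 0.9,
                 canonical_length: int = CANONICAL_L1_LENGTH) -> list[RepeatElement]:
    """Read repeat annotation from RepeatMasker ``.out`` or BED6+.

    An L1 element is flagged full-length when its aligned span is at
    least ``fl_min_fraction`` of the canonical ~6 kb element, unless the
    BED input states the flag explicitly in column 8.
    """
    path = Path(path)
    if path.suffix.lower() == ".out":
        return _repeats_from_rm_out(path, fl_min_fraction, canonical_length)
    return _repeats_from_bed(path, fl_min_fraction, canonical_length)


def write_repeats_bed(elements: list[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            cls = "LINE/L1" if el.repeat_class == "L1" else el.repeat_class
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.subfamily}\t0\t{iv.strand}"
                f"\t{cls}\t{int(el.full_length)}\n"
            )


# ---------------------------------------------------------------------------
# domains / tracks
# ---------------------------------------------------------------------------

def write_domains_bed(domains: list[L1Domain], path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            iv = d.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.domain_type}\n")


def read_domains_bed(path) -> list[L1Domain]:
    domains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: domain BED needs 4 columns")
            domains.append(
                L1Domain(parts[3], GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            )
    return domains


def write_bedgraph(chrom: str, window: int, values, path, chrom_len: int | None = None) -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            start = i * window
            end = (i + 1) * window
            if chrom_len is not None:
                end = min(end, chrom_len)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_probe_matrix(matrix_path, design_path) -> ProbeMatrix:
    """Read a log2 probe-set matrix TSV and a design TSV (sample_id, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise ValueError(f"design {design_path} lacks required column {col!r}")
    return ProbeMatrix(values, pd.Series(design["group"].values, index=design["sample_id"]))


def write_probe_matrix(matrix: ProbeMatrix, matrix_path, design_path) -> None:
    matrix.values.rename_axis("probe_set_id").to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.design.values}).to_csv(
        design_path, sep="\t", index=False
    )


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with '.' for missing values (full float precision)."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
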