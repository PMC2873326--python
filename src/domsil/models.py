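"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open ([start, end)), the BED
convention.  GFF3 input (1-based inclusive) is converted at the I/O
boundary; nothing downstream of :mod:`domsil.io` ever sees 1-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

REPEAT_CLASSES = ("L1", "SINE", "LTR", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``'+'``, ``'-'``, ``'.'``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the intervals overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class RepeatElement:
    """A located repeat annotation.

    ``full_length`` marks L1 elements retaining most of the ~6 kb
    canonical element structure (relatively young insertions); it is
    only meaningful for ``repeat_class == 'L1'``.
    """

    interval: GenomicInterval
    repeat_class: str
    subfamily: str = ""
    full_length: bool = False

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if self.full_length and self.repeat_class != "L1":
            raise ValueError("full_length is only permitted for L1 elements")


@dataclass
class GeneModel:
    """A gene with its exon structure and mapped probe sets."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    probe_sets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene interval for {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
            prev_end = ex.end


class ProbeMatrix:
    """A log2 probe-set expression matrix with a two-group design.

    Wraps a :class:`pandas.DataFrame` (rows = probe sets, columns =
    samples) plus a per-sample group label, ``'control'`` or
    ``'treated'``.  This is the contract of an upstream normalisation
    step (for example RMA): values are already on the log2 scale.
    """

    GROUPS = ("control", "treated")

    def __init__(self, values: pd.DataFrame, design: pd.Series | dict):
        if isinstance(design, dict):
            design = pd.Series(design)
        design = design.reindex(values.columns)
        if design.isna().any():
            missing = list(values.columns[design.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(design.unique()) - set(self.GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        self.values = values.astype(float)
        self.design = design.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.design.index[self.design == group])

    def group_values(self, group: str) -> np.ndarray:
        return self.values[self.group_samples(group)].to_numpy()

    def require_replicates(self, min_per_group: int = 2) -> None:
        for g in self.GROUPS:
            n = len(self.group_samples(g))
            if n < min_per_group:
                raise ValueError(f"group {g!r} has {n} samples; need >= {min_per_group}")

    def subset_probes(self, probe_ids: Sequence[str]) -> "ProbeMatrix":
        return ProbeMatrix(self.values.loc[list(probe_ids)], self.design)

    def __repr__(self) -> str:  # pragma: no cover
        n_c = len(self.group_samples("control"))
        n_t = len(self.group_samples("treated"))
        return f"ProbeMatrix({len(self.values)} probes, {n_c} control + {n_t} treated samples)"


@dataclass(frozen=True)
class L1Domain:
    """A typed chromosomal segment: HL1 (high L1 density) or LL1 (low)."""

    domain_type: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.domain_type not in ("HL1", "LL1"):
            raise ValueError(f"domain_type must be HL1 or LL1, got {self.domain_type!r}")

    @property
    def size(self) -> int:
        return self.interval.length
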