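"""HL1/LL1 domain segmentation from windowed L1 coverage.

Mouse autosomes are organised into alternating segments of high L1
density (HL1, typically gene-poor, enriched for full-length L1s) and
low L1 density (LL1, gene-rich, carrying only fragmented elements),
spanning a few hundred kb to several Mb and broadly matching G/R
cytogenetic bands.  Segmentation here is deliberately simple: windowed
coverage is thresholded, runs of equal label are merged, and segments
shorter than a minimum size are absorbed into their longer flanking
neighbour.  Users with an authoritative domain list can bypass this and
supply a domain BED directly.

Defaults: 100 kb windows; threshold = chromosome-wide mean L1 coverage;
minimum domain size 500 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._intervals import IntervalUnion
from .models import GenomicInterval, L1Domain, RepeatElement

DEFAULT_WINDOW = 100_000
DEFAULT_MIN_DOMAIN_SIZE = 500_000


@dataclass
class DensityTrack:
    """Windowed coverage fractions tiling one chromosome."""

    chrom: str
    chrom_len: int
    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = -(-self.chrom_len // self.window)
        if len(self.values) != n:
            raise ValueError(f"expected {n} windows for {self.chrom_len} bp, got {len(self.values)}")


def coverage_track(
    elements: list[RepeatElement],
    chrom: str,
    chrom_len: int,
    window: int = DEFAULT_WINDOW,
    class_filter: str | None = "L1",
    fl_only: bool = False,
) -> DensityTrack:
    """Fraction of bases covered by the union of selected repeats, per window."""
    if window <= 0:
        raise ValueError("window must be positive")
    chosen = [
        el for el in elements
        if el.interval.chrom == chrom
        and (class_filter is None or el.repeat_class == class_filter)
        and (not fl_only or el.full_length)
    ]
    for el in chosen:
        if el.interval.end > chrom_len:
            raise ValueError(f"element {el.interval} extends beyond chromosome end {chrom_len}")
    union = IntervalUnion(
        [el.interval.start for el in chosen], [el.interval.end for el in chosen]
    )
    n = -(-chrom_len // window)
    starts = np.arange(n, dtype=np.int64) * window
    ends = np.minimum(starts + window, chrom_len)
    covered = union.covered(starts, ends)
    values = covered / (ends - starts)
    return DensityTrack(chrom, chrom_len, window, values)


def segment_domains(
    track: DensityTrack,
    hl1_threshold: float | None = None,
    min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE,
) -> list[L1Domain]:
    """Partition a chromosome into alternating HL1/LL1 domains.

    Windows at or above the threshold are HL1, the rest LL1; maximal
    runs become candidate domains and any domain shorter than
    ``min_domain_size`` is absorbed into the longer flanking neighbour
    (left on tie), smallest offender first.  The default threshold is
    the chromosome-wide mean coverage of the track.

    The result tiles [0, chrom_len) exactly with strictly alternating
    domain types.
    """
    if len(track.values) == 0:
        raise ValueError("empty density track")
    if hl1_threshold is None:
        hl1_threshold = float(track.values.mean())
    labels = np.where(track.values >= hl1_threshold, "HL1", "LL1")
    # collapse windows into labelled runs with bp coordinates
    bounds = [i * track.window for i in range(len(labels))] + [track.chrom_len]
    runs: list[list] = []  # [type, start, end]
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = bounds[i + 1]
        else:
            runs.append([lab, bounds[i], bounds[i + 1]])
    # absorb undersized runs; interior runs first (edge runs have a single
    # flank and are handled once no interior offender remains), smallest
    # then leftmost
    while len(runs) > 1:
        sizes = [r[2] - r[1] for r in runs]
        small = [i for i, s in enumerate(sizes) if s < min_domain_size]
        if not small:
            break
        i = min(small, key=lambda j: (j in (0, len(runs) - 1), sizes[j], j))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            left_size, right_size = sizes[i - 1], sizes[i + 1]
            j = i - 1 if left_size >= right_size else i + 1
        lo, hi = min(i, j), max(i, j)
        runs[lo] = [runs[j][0], runs[lo][1], runs[hi][2]]
        del runs[hi]
        # merging may create adjacent runs of equal type
        k = 1
        while k < len(runs):
            if runs[k][0] == runs[k - 1][0]:
                runs[k - 1][2] = runs[k][2]
                del runs[k]
            else:
                k += 1
    return [
        L1Domain(lab, GenomicInterval(track.chrom, start, end)) for lab, start, end in runs
    ]


def core_domain(domain: L1Domain, trunc: int) -> GenomicInterval | None:
    """Domain truncated by ``trunc`` bp at both boundaries; None if nothing remains.

    Core domains capture a gene's position deep inside a domain, away
    from the transition zones at the boundaries.
    """
    if trunc < 0:
        raise ValueError("trunc must be >= 0")
    start = domain.interval.start + trunc
    end = domain.interval.end - trunc
    if start >= end:
        return None
    return GenomicInterval(domain.interval.chrom, start, end)


def check_tiling(domains: list[L1Domain], chrom_len: int) -> None:
    """Validate that domains tile [0, chrom_len) with alternating types."""
    if not domains:
        raise ValueError("empty domain list")
    if domains[0].interval.start != 0 or domains[-1].interval.end != chrom_len:
        raise ValueError("domains do not span the chromosome")
    for a, b in zip(domains, domains[1:]):
        if a.interval.end != b.interval.start:
            raise ValueError(f"gap/overlap between {a} and {b}")
        if a.domain_type == b.domain_type:
            raise ValueError("adjacent domains share a type")
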