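"""Nuclear and mitochondrial coverage summaries and mtDNA copy number.

Mean nuclear coverage is estimated from alignment flag statistics rather than
a per-base pileup: duplicate reads, singletons and reads with a discordant
mate are subtracted from the mapped-read count before converting to fold
coverage.  mtDNA copy number (mtCN) is then the coverage ratio scaled to a
diploid nuclear genome:

    mtCN = 2 * (mean or median mtDNA coverage) / (mean nucDNA coverage)

The nuclear read counts are conventionally computed over autosomes only;
callers are responsible for supplying counts and a genome length on the same
footing (``genome_length`` defaults to the autosome span of GRCh38).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentStats",
    "CoverageTrack",
    "mean_nuc_coverage",
    "mt_coverage_summary",
    "compute_mtcn",
    "region_median",
    "AUTOSOME_LENGTH_GRCH38",
]

#: Total autosome span of GRCh38 (chr1-22), bases.
AUTOSOME_LENGTH_GRCH38 = 2_875_001_522


@dataclass(frozen=True)
class AlignmentStats:
    """samtools idxstats/flagstat-style summary counts for one sample."""

    total_mapped_reads: int
    singletons: int
    discordant_mate_reads: int
    duplicates: int
    read_length: float
    genome_length: int = AUTOSOME_LENGTH_GRCH38

    def __post_init__(self) -> None:
        counts = (self.total_mapped_reads, self.singletons,
                  self.discordant_mate_reads, self.duplicates)
        if any(c < 0 for c in counts):
            raise ValueError("alignment counts must be non-negative")
        if self.singletons + self.discordant_mate_reads + self.duplicates \
                > self.total_mapped_reads:
            raise ValueError("excluded read classes exceed total mapped reads")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class CoverageTrack:
    """Per-base coverage over one contig; ``start`` is the 1-based origin."""

    contig: str
    values: np.ndarray
    start: int = 1
    circular: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be 1-D")
        if self.values.size and self.values.min() < 0:
            raise ValueError("coverage must be non-negative")


def mean_nuc_coverage(stats: AlignmentStats) -> float:
    """Mean nuclear fold coverage from alignment summary counts."""
    usable = (stats.total_mapped_reads - stats.singletons
              - stats.discordant_mate_reads - stats.duplicates)
    return usable * stats.read_length / stats.genome_length


def mt_coverage_summary(track: CoverageTrack) -> tuple[float, float]:
    """(mean, median) of per-base mtDNA coverage."""
    if track.values.size == 0:
        raise ValueError("empty coverage track")
    return float(np.mean(track.values)), float(np.median(track.values))


def compute_mtcn(mt_stat: float, nuc_cov: float) -> float:
    """mtDNA copies per diploid nuclear genome: ``2 * mt_stat / nuc_cov``.

    ``mt_stat`` is the mean (default convention) or median mtDNA coverage.
    """
    if nuc_cov <= 0:
        raise ValueError(f"nuclear coverage must be positive, got {nuc_cov}")
    return 2.0 * mt_stat / nuc_cov


def region_median(track: CoverageTrack, interval: tuple[int, int]) -> float:
    """Median coverage over a 1-based inclusive interval.

    On a circular track an interval with ``start > end`` wraps through the
    origin (e.g. the 7S DNA span of the mtDNA control region).
    """
    lo, hi = interval
    n = track.values.size
    lo0, hi0 = lo - track.start, hi - track.start
    if lo0 < 0 or hi0 >= n:
        raise ValueError(f"interval {interval} outside track span")
    if lo0 <= hi0:
        segment = track.values[lo0:hi0 + 1]
    else:
        if not track.circular:
            raise ValueError("wrap-around interval on a non-circular track")
        segment = np.concatenate([track.values[lo0:], track.values[:hi0 + 1]])
    if segment.size == 0:
        raise ValueError("empty interval")
    return float(np.median(segment))
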