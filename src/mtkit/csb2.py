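"""chrM:302 length-heteroplasmy composition, bulk and single-cell.

The poly-C tract at the CSBII G-quadruplex (chrM:302 region, structure
G_m A G_n on the light strand / C-tracts with an intervening T as sequenced
here) varies in length within individuals.  Bulk composition is assembled
from caller output at chrM:302 as a simplex over {reference, +C, +CC, +CCC,
Other}; single-cell composition classifies individual reads spanning
chrM:300-318 with the anchored regular expression ``AA(CCC+[CT]CC+)GC`` and
aggregates per cell barcode, with pseudo-bulk obtained by pooling counts
(not by averaging per-cell fractions).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CompositionProfile",
    "Csb2Allele",
    "individual_composition",
    "classify_read",
    "cell_composition",
    "pseudobulk",
    "CSB2_READ_REGEX",
    "TOP_BULK_ALLELES",
]

#: Anchored motif: two constant bases either side of the two C-tracts with an
#: optional single interrupting T.
CSB2_READ_REGEX = re.compile(r"AA(CCC+[CT]CC+)GC")

#: The three most common length alleles in wild-type blood (reference first).
TOP_BULK_ALLELES = ("G6AG8", "G6AG9", "G6AG10")

MIN_CSB2_DEPTH = 100
MIN_NAMED_FRACTION = 0.05
MIN_CELL_READS = 20

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class CompositionProfile:
    """Simplex of allele fractions at chrM:302."""

    reference: float
    plus_c: float      # chrM:302:A,AC
    plus_cc: float     # chrM:302:A,ACC
    plus_ccc: float    # chrM:302:A,ACCC
    other: float       # everything else, incl. QC-fail mass and <0.05 relabels

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < -_SIMPLEX_TOL or v > 1 + _SIMPLEX_TOL for v in vals):
            raise ValueError(f"fractions outside [0, 1]: {vals}")
        if abs(sum(vals) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"fractions sum to {sum(vals)}, not 1")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.reference, self.plus_c, self.plus_cc, self.plus_ccc,
                self.other)


@dataclass(frozen=True)
class Csb2Allele:
    """One read-level length allele: two C-tract lengths and whether the
    interrupting base was present."""

    tract1: int
    tract2: int
    interrupted: bool

    @property
    def label(self) -> str:
        if self.interrupted:
            return f"G{self.tract1}AG{self.tract2}"
        return f"C{self.tract1 + self.tract2}"


_NAMED = {"AC": "plus_c", "ACC": "plus_cc", "ACCC": "plus_ccc"}


def individual_composition(calls: list[dict], depth: int,
                           min_depth: int = MIN_CSB2_DEPTH,
                           min_frac: float = MIN_NAMED_FRACTION
                           ) -> CompositionProfile | None:
    """Bulk chrM:302 composition for one individual.

    ``calls`` carry ``alt`` (e.g. "AC") and ``heteroplasmy`` for QC-pass
    alleles at chrM:302, plus optional QC-fail entries marked ``qc_fail=True``
    whose summed heteroplasmy lands in Other.  The reference fraction is one
    minus the total allele mass; named alleles below ``min_frac`` are
    relabelled Other (the NUMT-artefact guard used throughout); absent named
    alleles are 0.  Samples with post-realignment ``depth < min_depth`` are
    excluded (returns None).
    """
    if depth < min_depth:
        return None
    named = {"plus_c": 0.0, "plus_cc": 0.0, "plus_ccc": 0.0}
    other = 0.0
    total = 0.0
    for call in calls:
        h = float(call["heteroplasmy"])
        total += h
        if call.get("qc_fail", False):
            other += h
        else:
            slot = _NAMED.get(call["alt"])
            if slot is None:
                other += h
            elif h < min_frac:
                other += h
            else:
                named[slot] += h
    if total > 1.0 + _SIMPLEX_TOL:
        raise ValueError(f"allele fractions at chrM:302 sum to {total} > 1")
    reference = 1.0 - total
    return CompositionProfile(reference=reference, other=other, **named)


def classify_read(sequence: str) -> Csb2Allele | None:
    """Classify one read spanning chrM:300-318 by its poly-C tract lengths.

    The first (leftmost) regex match wins.  If the captured group contains a
    T, the two flanking C-runs are the tracts (interrupted allele, label
    ``G{m}AG{n}`` in light-strand notation); a pure-C capture is an
    uninterrupted allele labelled by total C length.  Reads without the motif
    are unclassifiable (None).  Reads must be on the stored/sequenced strand;
    reverse-strand reads are reverse-complemented by the reader upstream.
    """
    m = CSB2_READ_REGEX.search(sequence)
    if m is None:
        return None
    group = m.group(1)
    t_at = group.find("T")
    if t_at >= 0:
        return Csb2Allele(tract1=t_at, tract2=len(group) - t_at - 1,
                          interrupted=True)
    return Csb2Allele(tract1=len(group), tract2=0, interrupted=False)


def _count_cells(reads: pd.DataFrame, allowlist=None) -> dict[str, Counter]:
    per_cell: dict[str, Counter] = {}
    for barcode, seq in zip(reads["cell_barcode"], reads["sequence"]):
        if allowlist is not None and barcode not in allowlist:
            continue
        allele = classify_read(seq)
        if allele is None:
            continue
        per_cell.setdefault(barcode, Counter())[allele.label] += 1
    return per_cell


def cell_composition(reads: pd.DataFrame, min_reads: int = MIN_CELL_READS,
                     allowlist=None,
                     top_labels: tuple[str, ...] = TOP_BULK_ALLELES
                     ) -> pd.DataFrame:
    """Per-cell length-allele fractions.

    ``reads`` needs ``cell_barcode`` and ``sequence`` columns.  Cells outside
    the barcode allowlist (when given) are dropped; cells with fewer than
    ``min_reads`` classified reads are excluded.  Fractions are reported over
    ``top_labels`` with every other detected allele aggregated into
    ``other``; a ``n_reads`` column carries the classified read count.
    """
    per_cell = _count_cells(reads, allowlist)
    rows = {}
    for barcode, counts in per_cell.items():
        n = sum(counts.values())
        if n < min_reads:
            continue
        row = {lab: counts.get(lab, 0) / n for lab in top_labels}
        row["other"] = sum(v for k, v in counts.items()
                           if k not in top_labels) / n
        row["n_reads"] = n
        rows[barcode] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_barcode"
    return out.sort_index()


def pseudobulk(reads: pd.DataFrame, min_reads: int = MIN_CELL_READS,
               allowlist=None,
               top_labels: tuple[str, ...] = TOP_BULK_ALLELES) -> dict[str, float]:
    """Pseudo-bulk composition: allele counts pooled over retained
    (high-coverage) cells, then renormalised — not the mean of per-cell
    fractions."""
    per_cell = _count_cells(reads, allowlist)
    pooled: Counter = Counter()
    for counts in per_cell.values():
        if sum(counts.values()) >= min_reads:
            pooled.update(counts)
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no classified reads in retained cells")
    out = {lab: pooled.get(lab, 0) / total for lab in top_labels}
    out["other"] = sum(v for k, v in pooled.items() if k not in top_labels) / total
    return out
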