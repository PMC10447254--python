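"""Per-sample consensus ("self-reference") construction and bidirectional liftover.

Variant calling against a per-sample consensus avoids reference bias near
common homoplasmies: homoplasmic calls are folded into the sample's own
reference, reads are (externally) realigned to it, and the resulting calls
and per-base coverage are lifted back to the canonical circular reference
(rCRS-style, 16,569 bp for human mtDNA).  Because coverage collapses at the
linearisation breakpoint of a circular genome, control-region calling is done
against an origin-shifted copy of the molecule; :func:`shift_coordinate`
implements that modular re-numbering.

Coordinate conventions: variant positions are 1-based inclusive (VCF);
alignment blocks are stored 0-based half-open internally.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSequence",
    "MtVariantCall",
    "CoordinateMap",
    "ConsensusBuild",
    "build_consensus",
    "lift_position",
    "lift_calls",
    "lift_coverage",
    "shift_coordinate",
    "MT_LENGTH",
]

#: Length of the human mitochondrial reference genome (bases).
MT_LENGTH = 16_569

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class ReferenceSequence:
    """A named nucleotide sequence, optionally circular."""

    name: str
    bases: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty reference sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MtVariantCall:
    """One allele call at an mtDNA site.

    ``heteroplasmy`` is the allele fraction of ``alt_allele``; ``filters`` is
    the set of caller flags (empty means PASS).
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    heteroplasmy: float
    depth: int = 0
    alt_depth: int = 0
    filters: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError(f"heteroplasmy {self.heteroplasmy} outside [0, 1]")
        if self.alt_depth > self.depth:
            raise ValueError("alt_depth exceeds depth")
        object.__setattr__(self, "filters", frozenset(self.filters))

    @property
    def is_pass(self) -> bool:
        return len(self.filters) == 0

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class CoordinateMap:
    """Block map between a reference and a consensus of the same molecule.

    ``blocks`` are ``(ref_start, cons_start, length)`` aligned runs, 0-based
    half-open, sorted and non-overlapping on both axes.  Gaps on the consensus
    axis are reference bases deleted in the consensus; gaps on the reference
    axis are bases inserted in the consensus.  ``shift`` is an origin offset
    applied to incoming positions before block lookup (0 when the molecule was
    not re-linearised).
    """

    blocks: list[tuple[int, int, int]]
    ref_length: int
    cons_length: int
    shift: int = 0
    circular: bool = False

    def __post_init__(self) -> None:
        prev_r = prev_c = -1
        for r, c, n in self.blocks:
            if n <= 0 or r < prev_r or c < prev_c:
                raise ValueError("blocks must be sorted, non-overlapping, positive-length")
            prev_r, prev_c = r + n, c + n

    @classmethod
    def identity(cls, length: int, circular: bool = False) -> "CoordinateMap":
        return cls(blocks=[(0, 0, length)], ref_length=length, cons_length=length,
                   circular=circular)


def shift_coordinate(pos: int, shift: int, length: int,
                     direction: str = "to_original", circular: bool = True) -> int:
    """Map a 1-based position between an origin-shifted and the original numbering.

    Shifted position 1 corresponds to original position ``shift + 1``; the
    genome must be circular for the wrap-around to be meaningful.
    """
    if not circular:
        raise ValueError("origin shifting requires a circular genome")
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside [1, {length}]")
    if direction == "to_original":
        return (pos - 1 + shift) % length + 1
    if direction == "to_shifted":
        return (pos - 1 - shift) % length + 1
    raise ValueError(f"unknown direction {direction!r}")


def lift_position(cmap: CoordinateMap, pos: int, direction: str) -> int | None:
    """Lift a 1-based position through a :class:`CoordinateMap`.

    ``to_reference``: consensus positions inside an inserted run return the
    insertion's left reference anchor base.  ``to_consensus``: reference
    positions deleted in the consensus return ``None``.
    """
    if direction == "to_reference":
        src_len, src_axis = cmap.cons_length, 1
    elif direction == "to_consensus":
        src_len, src_axis = cmap.ref_length, 0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if cmap.shift:
        pos = shift_coordinate(pos, cmap.shift, src_len, "to_original",
                               circular=cmap.circular or True)
    if not 1 <= pos <= src_len:
        raise ValueError(f"position {pos} outside source axis [1, {src_len}]")
    p0 = pos - 1
    starts = [b[src_axis] for b in cmap.blocks]
    i = bisect_right(starts, p0) - 1
    if i >= 0:
        r, c, n = cmap.blocks[i]
        src_start = (r, c)[src_axis]
        if p0 < src_start + n:
            off = p0 - src_start
            return ((c, r)[src_axis]) + off + 1
    if direction == "to_reference":
        # inserted consensus base: anchor at last reference base of the
        # preceding block (left anchor, matching left-aligned VCF indels)
        if i >= 0:
            r, c, n = cmap.blocks[i]
            return r + n
        return None
    return None  # deleted reference base has no consensus image


@dataclass
class ConsensusBuild:
    """Result of folding homoplasmic calls into a per-sample consensus."""

    consensus: ReferenceSequence
    map: CoordinateMap
    applied: list[MtVariantCall]
    skipped: list[tuple[MtVariantCall, str]]
    reference: ReferenceSequence
    # per applied call: (ref_start0, ref_end0, cons_start0, cons_end0), end-exclusive
    applied_spans: list[tuple[int, int, int, int]] = field(default_factory=list)


def build_consensus(ref: ReferenceSequence, calls: list[MtVariantCall],
                    hom_threshold: float = 0.95) -> ConsensusBuild:
    """Apply homoplasmic PASS calls to ``ref``, producing consensus + coordinate map.

    Calls with allele fraction >= ``hom_threshold`` and no caller flags are
    applied left-to-right; later calls overlapping an already-applied footprint
    are skipped with reason ``"overlap"``.  A homoplasmic call whose ref allele
    disagrees with the reference sequence is a hard error.
    """
    if not 0.5 < hom_threshold <= 1.0:
        raise ValueError(f"hom_threshold {hom_threshold} outside (0.5, 1]")
    calls = sorted(calls, key=lambda c: (c.pos, c.alt_allele))

    applied: list[MtVariantCall] = []
    skipped: list[tuple[MtVariantCall, str]] = []
    spans: list[tuple[int, int, int, int]] = []
    blocks: list[tuple[int, int, int]] = []
    ref_cur = 0   # 0-based cursor on reference
    cons_cur = 0  # 0-based cursor on consensus
    occupied_end = 0  # exclusive end of last applied footprint on reference

    def add_match(n: int) -> None:
        nonlocal ref_cur, cons_cur
        if n <= 0:
            return
        if blocks and blocks[-1][0] + blocks[-1][2] == ref_cur \
                and blocks[-1][1] + blocks[-1][2] == cons_cur:
            r, c, m = blocks[-1]
            blocks[-1] = (r, c, m + n)
        else:
            blocks.append((ref_cur, cons_cur, n))
        ref_cur += n
        cons_cur += n

    for call in calls:
        if call.heteroplasmy < hom_threshold:
            skipped.append((call, "below_threshold"))
            continue
        if not call.is_pass:
            skipped.append((call, "caller_flag"))
            continue
        start0 = call.pos - 1
        end0 = start0 + len(call.ref_allele)
        if end0 > ref.length:
            raise ValueError(f"call at pos {call.pos} runs past the reference end")
        if ref.bases[start0:end0] != call.ref_allele:
            raise ValueError(
                f"ref allele mismatch at pos {call.pos}: call says "
                f"{call.ref_allele!r}, reference has {ref.bases[start0:end0]!r}")
        if start0 < occupied_end:
            skipped.append((call, "overlap"))
            continue

        add_match(start0 - ref_cur)  # matched run up to the call

        r_span_start, c_span_start = ref_cur, cons_cur
        ra, aa = call.ref_allele, call.alt_allele
        # shared prefix stays aligned (left-aligned VCF anchor base)
        k = 0
        while k < min(len(ra), len(aa)) and ra[k] == aa[k]:
            k += 1
        add_match(k)
        r_rest, a_rest = ra[k:], aa[k:]
        sub = min(len(r_rest), len(a_rest))
        add_match(sub)  # substituted bases keep their coordinates
        if len(r_rest) > len(a_rest):      # deletion: extra ref bases unaligned
            ref_cur += len(r_rest) - len(a_rest)
        elif len(a_rest) > len(r_rest):    # insertion: extra alt bases unaligned
            cons_cur += len(a_rest) - len(r_rest)

        applied.append(call)
        spans.append((r_span_start, end0, c_span_start, c_span_start + len(aa)))
        occupied_end = end0

    add_match(ref.length - ref_cur)
    consensus_seq = _render_consensus(ref, applied)
    cons_len = ref.length + sum(len(c.alt_allele) - len(c.ref_allele) for c in applied)
    assert len(consensus_seq) == cons_len

    cmap = CoordinateMap(blocks=blocks, ref_length=ref.length,
                         cons_length=cons_len, circular=ref.circular)
    consensus = ReferenceSequence(name=f"{ref.name}_consensus", bases=consensus_seq,
                                  circular=ref.circular)
    return ConsensusBuild(consensus=consensus, map=cmap, applied=applied,
                          skipped=skipped, reference=ref, applied_spans=spans)


def _render_consensus(ref: ReferenceSequence, applied: list[MtVariantCall]) -> str:
    """Straight string-edit application of non-overlapping sorted calls."""
    parts: list[str] = []
    cur = 0
    for call in applied:
        s = call.pos - 1
        parts.append(ref.bases[cur:s])
        parts.append(call.alt_allele)
        cur = s + len(call.ref_allele)
    parts.append(ref.bases[cur:])
    return "".join(parts)


def lift_coverage(build: ConsensusBuild, cov) -> np.ndarray:
    """Lift a per-base consensus coverage array back to reference coordinates.

    Matched bases copy their value; reference bases deleted in the consensus
    inherit the coverage of the left consensus anchor base; inserted consensus
    bases contribute nothing.
    """
    cov = np.asarray(cov)
    cmap = build.map
    if cov.shape[0] != cmap.cons_length:
        raise ValueError(
            f"coverage length {cov.shape[0]} != consensus length {cmap.cons_length}")
    out = np.zeros(cmap.ref_length, dtype=cov.dtype)
    prev_end_r = 0
    prev_anchor_c: int | None = None
    for r, c, n in cmap.blocks:
        if r > prev_end_r:  # deleted reference run
            anchor = prev_anchor_c if prev_anchor_c is not None else c
            out[prev_end_r:r] = cov[anchor]
        out[r:r + n] = cov[c:c + n]
        prev_end_r = r + n
        prev_anchor_c = c + n - 1
    if prev_end_r < cmap.ref_length:
        anchor = prev_anchor_c if prev_anchor_c is not None else 0
        out[prev_end_r:] = cov[anchor]
    return out


def _trim_allele(pos: int, ref_a: str, alt_a: str) -> tuple[int, str, str]:
    """VCF-style minimal representation: trim shared suffix, then prefix."""
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[-1] == alt_a[-1]:
        ref_a, alt_a = ref_a[:-1], alt_a[:-1]
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
        ref_a, alt_a = ref_a[1:], alt_a[1:]
        pos += 1
    return pos, ref_a, alt_a


def lift_calls(build: ConsensusBuild, calls: list[MtVariantCall]
               ) -> tuple[list[MtVariantCall], list[tuple[MtVariantCall, str]]]:
    """Re-express consensus-coordinate calls against the original reference.

    Each call is composed with the homoplasmic edits that were folded into the
    consensus: a local window covering the call and any overlapping applied
    edit is replayed as three haplotypes (reference segment, consensus segment,
    call-applied segment).  If applying the call restores the reference
    segment, the emitted variant is the consensus allele itself at fraction
    ``1 - f`` (the call "cancelled" the homoplasmy on ``f`` of molecules);
    otherwise the call-applied segment is emitted at fraction ``f``.

    Returns ``(lifted, rejects)``; composition failures land in ``rejects``
    with a reason rather than being dropped.
    """
    cmap = build.map
    ref = build.reference
    cons = build.consensus
    lifted: list[MtVariantCall] = []
    rejects: list[tuple[MtVariantCall, str]] = []

    for call in calls:
        c_lo = call.pos - 1
        c_hi = c_lo + len(call.ref_allele)
        if c_hi > cons.length:
            rejects.append((call, "footprint_past_end"))
            continue
        if cons.bases[c_lo:c_hi] != call.ref_allele:
            rejects.append((call, "consensus_allele_mismatch"))
            continue

        r_lo = lift_position(cmap, c_lo + 1, "to_reference")
        r_hi_pos = lift_position(cmap, c_hi, "to_reference")
        if r_lo is None or r_hi_pos is None:
            rejects.append((call, "unmappable"))
            continue
        r_lo -= 1
        r_hi = r_hi_pos  # 1-based inclusive end -> 0-based exclusive

        # expand to cover every applied edit overlapping either window
        changed = True
        while changed:
            changed = False
            for (ars, are, acs, ace) in build.applied_spans:
                if acs < c_hi and ace > c_lo or ars < r_hi and are > r_lo:
                    n_c_lo, n_c_hi = min(c_lo, acs), max(c_hi, ace)
                    n_r_lo, n_r_hi = min(r_lo, ars), max(r_hi, are)
                    if (n_c_lo, n_c_hi, n_r_lo, n_r_hi) != (c_lo, c_hi, r_lo, r_hi):
                        c_lo, c_hi, r_lo, r_hi = n_c_lo, n_c_hi, n_r_lo, n_r_hi
                        changed = True

        refseg = ref.bases[r_lo:r_hi]
        consseg = cons.bases[c_lo:c_hi]
        off = (call.pos - 1) - c_lo
        newseg = consseg[:off] + call.alt_allele + consseg[off + len(call.ref_allele):]

        if not refseg:
            rejects.append((call, "empty_reference_window"))
            continue
        if newseg == refseg:
            # call reverts the folded homoplasmy on f of molecules; the
            # remaining 1-f carry the consensus allele relative to reference
            pos, ra, aa = _trim_allele(r_lo + 1, refseg, consseg)
            het = 1.0 - call.heteroplasmy
            alt_depth = max(call.depth - call.alt_depth, 0)
        else:
            pos, ra, aa = _trim_allele(r_lo + 1, refseg, newseg)
            het = call.heteroplasmy
            alt_depth = call.alt_depth
        if ra == aa:
            rejects.append((call, "degenerate_composition"))
            continue
        lifted.append(MtVariantCall(
            contig=ref.name, pos=pos, ref_allele=ra, alt_allele=aa,
            heteroplasmy=het, depth=call.depth, alt_depth=alt_depth,
            filters=call.filters))
    return lifted, rejects
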