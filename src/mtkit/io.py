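"""Readers/writers for the standard formats the toolkit exchanges.

FASTA via pyfaidx, VCF via pysam, per-base coverage as plain TSV
(contig, pos, coverage; 1-based), alignment summary stats as JSON.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .coverage import AlignmentStats, CoverageTrack
from .selfref import MtVariantCall, ReferenceSequence

__all__ = [
    "read_fasta", "write_fasta", "read_vcf_calls", "write_vcf_calls",
    "read_coverage_tsv", "write_coverage_tsv", "read_alignment_stats",
    "write_alignment_stats",
]


def read_fasta(path, circular: bool = False) -> ReferenceSequence:
    fa = Fasta(str(path))
    name = list(fa.keys())[0]
    return ReferenceSequence(name=name, bases=str(fa[name][:]).upper(),
                             circular=circular)


def write_fasta(seq: ReferenceSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\n")
        for i in range(0, seq.length, width):
            fh.write(seq.bases[i:i + width] + "\n")


def _vcf_header(contig: str, length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=length)
    header.info.add("DP", 1, "Integer", "Site depth")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AF", "A", "Float", "Allele fraction (heteroplasmy)")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.add_sample("SAMPLE")
    return header


def write_vcf_calls(calls: list[MtVariantCall], path, contig: str = "chrM",
                    length: int = 16_569) -> None:
    header = _vcf_header(contig, length)
    for call in calls:
        for f in sorted(call.filters):
            if f not in header.filters:
                header.filters.add(f, None, None, "caller flag")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: c.pos):
            rec = vcf.new_record(
                contig=contig, start=call.pos - 1,
                alleles=(call.ref_allele, call.alt_allele))
            rec.info["DP"] = call.depth
            rec.samples["SAMPLE"]["GT"] = (0, 1)
            rec.samples["SAMPLE"]["AF"] = (call.heteroplasmy,)
            rec.samples["SAMPLE"]["AD"] = (call.depth - call.alt_depth,
                                           call.alt_depth)
            if call.filters:
                for f in sorted(call.filters):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


def read_vcf_calls(path) -> list[MtVariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0] if rec.samples else None
            af = None
            ad = (0, 0)
            if sample is not None:
                af = sample.get("AF")
                ad = sample.get("AD") or (0, 0)
            het = float(af[0]) if af else 0.0
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            depth = rec.info.get("DP", sum(x or 0 for x in ad))
            calls.append(MtVariantCall(
                contig=rec.contig, pos=rec.pos, ref_allele=rec.ref,
                alt_allele=rec.alts[0], heteroplasmy=het,
                depth=int(depth or 0), alt_depth=int(ad[1] or 0),
                filters=filters))
    return calls


def write_coverage_tsv(track: CoverageTrack, path) -> None:
    pd.DataFrame({
        "contig": track.contig,
        "pos": np.arange(track.start, track.start + track.values.size),
        "coverage": track.values,
    }).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path, circular: bool = False) -> CoverageTrack:
    t = pd.read_csv(path, sep="\t")
    t = t.sort_values("pos")
    return CoverageTrack(contig=str(t["contig"].iloc[0]),
                         values=t["coverage"].to_numpy(),
                         start=int(t["pos"].iloc[0]), circular=circular)


def write_alignment_stats(stats: AlignmentStats, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "total_mapped_reads": stats.total_mapped_reads,
            "singletons": stats.singletons,
            "discordant_mate_reads": stats.discordant_mate_reads,
            "duplicates": stats.duplicates,
            "read_length": stats.read_length,
            "genome_length": stats.genome_length,
        }, fh, indent=1)


def read_alignment_stats(path) -> AlignmentStats:
    with open(path) as fh:
        return AlignmentStats(**json.load(fh))
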