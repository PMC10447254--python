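"""Post-calling sample and variant QC for mtDNA call sets.

Sample-level filters remove likely contaminated or NUMT-dominated samples
(mtCN < 50, contamination > 2%, low-allele-fraction haplogroup patterns,
cross-sample homoplasmy overlap, excluded processing batches).  Variant-level
filters recode trace calls (allele fraction < 0.01) to reference, remove
low-fraction calls (< 0.05, the NUMT-artefact risk zone) and anything the
caller flagged.  Site status at QC-passed sites distinguishes confident
reference from missing using a minimum coverage of 100.

Removed calls are kept in an audit table with reasons rather than deleted:
the chrM:302 composition machinery needs the QC-fail heteroplasmy mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import pandas as pd

from .selfref import MtVariantCall

__all__ = [
    "SampleQCRecord",
    "SiteStatus",
    "sample_qc",
    "variant_qc",
    "cohort_variant_qc",
    "classify_site",
    "annotate_common_low_het",
    "select_common_heteroplasmies",
    "variant_id",
]

HOM_THRESHOLD = 0.95
MIN_SITE_COVERAGE = 100


def variant_id(contig: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant label, e.g. ``chrM:302:A,AC``."""
    return f"{contig}:{pos}:{ref},{alt}"


@dataclass(frozen=True)
class SampleQCRecord:
    sample_id: str
    mtcn: float
    contamination_mt: float = 0.0
    contamination_nuc: float = 0.0
    low_af_haplogroup_flag: bool = False
    overlapping_homoplasmy_flag: bool = False
    batch_label: str = ""

    def __post_init__(self) -> None:
        for f in (self.contamination_mt, self.contamination_nuc):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"contamination fraction {f} outside [0, 1]")


class SiteStatus(Enum):
    HOM_REF = "hom_ref"
    HETEROPLASMIC = "heteroplasmic"
    HOMOPLASMIC_ALT = "homoplasmic_alt"
    MISSING = "missing"


def sample_qc(rec: SampleQCRecord, mtcn_min: float = 50.0,
              contamination_max: float = 0.02,
              excluded_batches: frozenset = frozenset(),
              mtcn_max: float | None = None) -> tuple[bool, list[str]]:
    """Evaluate all sample-level filters; returns (pass, triggered reasons).

    ``mtcn_max`` enables the stricter upper bound (350 in the gnomAD-style
    subset); it is off by default.
    """
    reasons: list[str] = []
    if rec.mtcn < mtcn_min:
        reasons.append("mtcn_below_min")
    if mtcn_max is not None and rec.mtcn > mtcn_max:
        reasons.append("mtcn_above_max")
    if rec.contamination_mt > contamination_max \
            or rec.contamination_nuc > contamination_max:
        reasons.append("contamination")
    if rec.low_af_haplogroup_flag:
        reasons.append("low_af_haplogroup")
    if rec.overlapping_homoplasmy_flag:
        reasons.append("homoplasmy_overlap")
    if rec.batch_label in excluded_batches:
        reasons.append("excluded_batch")
    return (len(reasons) == 0, reasons)


def variant_qc(call: MtVariantCall, floor: float = 0.01, min_het: float = 0.05
               ) -> tuple[MtVariantCall | None, str]:
    """Single-call QC.

    Returns ``(call, "pass")`` when kept unchanged, ``(recoded, "recoded_reference")``
    when the allele fraction is below ``floor`` (recoded to heteroplasmy 0),
    or ``(None, reason)`` when removed (``"low_het"`` for fractions in
    [floor, min_het); ``"caller_flag"`` for flagged calls).  Ties: exactly
    ``min_het`` is kept, exactly ``floor`` is not floored.
    """
    if not call.is_pass:
        return None, "caller_flag"
    if call.heteroplasmy < floor:
        if call.heteroplasmy == 0.0:
            return call, "recoded_reference"
        return replace(call, heteroplasmy=0.0, alt_depth=0), "recoded_reference"
    if call.heteroplasmy < min_het:
        return None, "low_het"
    return call, "pass"


def cohort_variant_qc(calls: pd.DataFrame, floor: float = 0.01,
                      min_het: float = 0.05) -> pd.DataFrame:
    """Vectorised variant QC over a cohort call table.

    ``calls`` needs columns ``heteroplasmy`` and ``filters`` (empty string or
    NaN meaning PASS).  Returns the table with added ``qc_status`` in
    {pass, recoded_reference, low_het, caller_flag} and ``het_post_qc``
    (NaN for removed calls, 0 for recoded ones).  Nothing is dropped.
    """
    out = calls.copy()
    filt = out.get("filters", pd.Series("", index=out.index)).fillna("")
    het = out["heteroplasmy"]
    status = pd.Series("pass", index=out.index)
    status[het < min_het] = "low_het"
    status[het < floor] = "recoded_reference"
    status[filt.str.len() > 0] = "caller_flag"
    out["qc_status"] = status
    post = het.where(status == "pass")
    post[status == "recoded_reference"] = 0.0
    out["het_post_qc"] = post
    return out


def classify_site(calls: list[MtVariantCall], site_coverage: int,
                  min_cov: int = MIN_SITE_COVERAGE,
                  hom_threshold: float = HOM_THRESHOLD) -> SiteStatus:
    """Status of one sample at one site, given its QC-passed calls there."""
    if not calls:
        return SiteStatus.HOM_REF if site_coverage >= min_cov else SiteStatus.MISSING
    if any(c.heteroplasmy >= hom_threshold for c in calls):
        return SiteStatus.HOMOPLASMIC_ALT
    return SiteStatus.HETEROPLASMIC


def annotate_common_low_het(site_table: pd.DataFrame, n_qc_samples: int,
                            min_fraction: float = 0.001) -> pd.Series:
    """Flag variants carried at heteroplasmy strictly in (0, 0.5) by at least
    ``min_fraction`` of QC-passing samples ('common low heteroplasmy').

    ``site_table`` holds one row per QC-pass call with columns ``variant_id``
    and ``het_post_qc``; ``n_qc_samples`` is the QC-passing cohort size.
    Returns a boolean Series indexed by variant_id.
    """
    if n_qc_samples <= 0:
        raise ValueError("empty cohort")
    t = site_table
    in_band = t[(t["het_post_qc"] > 0) & (t["het_post_qc"] < 0.5)]
    counts = in_band.groupby("variant_id")["het_post_qc"].size()
    all_ids = t["variant_id"].unique()
    counts = counts.reindex(all_ids, fill_value=0)
    return counts / n_qc_samples >= min_fraction


def select_common_heteroplasmies(site_table: pd.DataFrame, n_qc_samples: int,
                                 min_carriers: int = 500,
                                 min_fraction: float = 0.001,
                                 hom_threshold: float = HOM_THRESHOLD) -> list[str]:
    """Common-low-heteroplasmy variants heteroplasmic in >= ``min_carriers``
    individuals — the variant set that becomes the heteroplasmy phenotypes."""
    flags = annotate_common_low_het(site_table, n_qc_samples, min_fraction)
    t = site_table
    het_carrier = t[(t["het_post_qc"] > 0) & (t["het_post_qc"] < hom_threshold)]
    n_het = het_carrier.groupby("variant_id")["het_post_qc"].size()
    selected = [v for v in flags.index[flags]
                if n_het.get(v, 0) >= min_carriers]
    return sorted(selected)
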