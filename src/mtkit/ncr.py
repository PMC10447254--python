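"""Non-coding-region coverage-discrepancy phenotypes.

mtDNA replication intermediates leave a coverage signature in the major
non-coding region (NCR): the persistently triple-stranded 7S DNA elevates
coverage, the transient nascent-strand "DNA flap" between CSBII and the
heavy-strand origin (O_H) less so, and the RNA-primer region between CSBIII
and the light-strand promoter (LSP) least.  Residuals of flap coverage
regressed on primer (or 7S DNA) coverage — with haplogroup main effects and
interactions absorbing inherited sequence effects, plus the blood and
technical covariates — form quantitative traits indexing the
transcription-to-replication switch.

Default region coordinates are rCRS-based approximations assembled from
standard control-region annotations (the construction is conventional, the
exact end-points are tunable):

* 7S DNA span 16106..191 (wrapping the origin); the trait uses its first
  third,
* CSBII 299..315, O_H at 191, CSBIII 346..363, LSP 392..445.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coverage import CoverageTrack, region_median

__all__ = ["NcrRegions", "region_medians", "coverage_discrepancy",
           "DEFAULT_ANNOTATIONS"]

#: rCRS-style control-region annotations (1-based inclusive; approximate).
DEFAULT_ANNOTATIONS = {
    "seven_s_dna": (16106, 191),   # wraps the linearisation origin
    "csb2": (299, 315),
    "o_h": (191, 191),
    "csb3": (346, 363),
    "lsp": (392, 445),
    "d_loop": (16024, 576),
}


def _first_third(span: tuple[int, int], length: int) -> tuple[int, int]:
    lo, hi = span
    total = (hi - lo) % length + 1
    return lo, (lo - 1 + total // 3 - 1) % length + 1


@dataclass
class NcrRegions:
    """The three NCR sub-regions the discrepancy traits are computed over."""

    seven_s: tuple[int, int]
    flap: tuple[int, int]
    primer: tuple[int, int]
    annotations: dict = field(default_factory=lambda: dict(DEFAULT_ANNOTATIONS))

    @classmethod
    def default(cls, genome_length: int = 16_569) -> "NcrRegions":
        ann = dict(DEFAULT_ANNOTATIONS)
        return cls(
            seven_s=_first_third(ann["seven_s_dna"], genome_length),
            flap=(ann["o_h"][0] + 1, ann["csb2"][0] - 1),  # 192..298, O_H to CSBII
            primer=(ann["csb3"][1] + 1, ann["lsp"][0] - 1),
            annotations=ann,
        )


def region_medians(track: CoverageTrack, regions: NcrRegions
                   ) -> tuple[float, float, float]:
    """Per-individual median coverages (7S DNA, DNA flap, RNA primer)."""
    return (region_median(track, regions.seven_s),
            region_median(track, regions.flap),
            region_median(track, regions.primer))


def coverage_discrepancy(flap, predictor, haplogroup,
                         covariates: pd.DataFrame | None = None,
                         min_haplogroup_n: int = 30) -> pd.Series:
    """Coverage-discrepancy residual phenotype.

    Regresses flap-region coverage on the predictor region's coverage (RNA
    primer or 7S DNA), top-level haplogroup indicators, predictor x haplogroup
    interactions and any supplied blood/technical covariate columns; the
    residuals are the phenotype.  Samples in haplogroups with fewer than
    ``min_haplogroup_n`` members are excluded (NaN in the output).
    """
    hap = pd.Series(haplogroup)
    idx = hap.index
    y = pd.Series(np.asarray(flap, dtype=float), index=idx)
    x = pd.Series(np.asarray(predictor, dtype=float), index=idx)

    counts = hap.value_counts()
    keep = hap.map(counts).ge(min_haplogroup_n)
    keep &= y.notna() & x.notna()
    if covariates is not None:
        covariates = covariates.reindex(idx)
        keep &= covariates.notna().all(axis=1)

    hk = hap[keep].astype("category")
    dummies = pd.get_dummies(hk, prefix="hap", drop_first=True, dtype=float)
    inter = dummies.mul(x[keep], axis=0).add_prefix("x_")
    parts = [x[keep].rename("predictor"), dummies, inter]
    if covariates is not None:
        parts.append(covariates.loc[keep].astype(float))
    X = pd.concat(parts, axis=1)
    Xm = sm.add_constant(X.to_numpy(float))
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise np.linalg.LinAlgError("coverage-discrepancy design is rank deficient")
    fit = sm.OLS(y[keep].to_numpy(), Xm).fit()
    out = pd.Series(np.nan, index=idx)
    out[keep] = fit.resid
    return out
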