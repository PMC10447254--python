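"""Post-GWAS statistics: colocalization, enrichment, loci, NUMT screening,
cross-cohort effect-size comparison.

* CLPP — colocalization posterior as the product of GWAS and cis-eQTL
  posterior inclusion probabilities (PIPs).
* Functional enrichment — relative risk of an annotation among well
  fine-mapped variants (PIP > 0.1) vs poorly fine-mapped ones (PIP <= 0.01),
  with percentile-bootstrap CIs (5,000 replicates by default).
* Locus definition — single-linkage merge of lead SNPs within 2 Mb, and
  replication classification of previous loci at suggestive (5e-5) and
  genome-wide (5e-8) thresholds within a 2 Mb window.
* NUMT screening — lead variants in LD (r^2 > 0.1) with SNPs inside padded,
  flanked NUMT windows are flagged as potential nuclear-insertion artefacts.
* Effect comparison — inverse-variance-weighted least squares (product
  weights 1/(se_x^2 * se_y^2)) and Deming errors-in-variables regression for
  comparing effect sizes between traits or cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PipTable", "LeadSnp", "clpp", "enrichment_rr", "define_loci",
    "replication_check", "numt_window_screen", "effect_comparison",
]


@dataclass(frozen=True)
class LeadSnp:
    variant: str
    chrom: str
    pos: int
    beta: float = 0.0
    se: float = 1.0
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


class PipTable(pd.DataFrame):
    """Variant table with ``pip_gwas``, ``pip_eqtl`` and ``annotation``
    columns; plain DataFrame subclass kept for naming clarity."""

    @property
    def _constructor(self):
        return PipTable


def clpp(pip_gwas: float, pip_eqtl: float) -> float:
    """Colocalization posterior: ``PIP_GWAS * PIP_eQTL``."""
    for p in (pip_gwas, pip_eqtl):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"PIP {p} outside [0, 1]")
    return pip_gwas * pip_eqtl


@dataclass
class EnrichmentResult:
    category: str
    rr: float | None
    ci_low: float | None
    ci_high: float | None
    n_hi: int
    n_lo: int
    defined: bool = True


def enrichment_rr(pips, annotations, hi: float = 0.1, lo: float = 0.01,
                  n_boot: int = 5000, seed: int = 0,
                  categories=None) -> list[EnrichmentResult]:
    """Functional-category enrichment among fine-mapped variants.

    For each category: RR = P(annot | PIP > hi) / P(annot | PIP <= lo), with a
    95% percentile bootstrap CI resampling variants independently within the
    two PIP strata.  Variants with lo < PIP <= hi belong to neither stratum.
    A zero denominator proportion leaves the RR undefined (flagged).
    """
    pips = np.asarray(pips, dtype=float)
    annotations = np.asarray(annotations)
    hi_mask = pips > hi
    lo_mask = pips <= lo
    n_hi, n_lo = int(hi_mask.sum()), int(lo_mask.sum())
    if n_hi == 0 or n_lo == 0:
        raise ValueError("both PIP strata must be non-empty")
    rng = np.random.default_rng(seed)
    if categories is None:
        categories = sorted(set(annotations))
    a_hi, a_lo = annotations[hi_mask], annotations[lo_mask]
    results = []
    for cat in categories:
        x_hi = (a_hi == cat).astype(float)
        x_lo = (a_lo == cat).astype(float)
        p_hi, p_lo = x_hi.mean(), x_lo.mean()
        if p_lo == 0:
            results.append(EnrichmentResult(cat, None, None, None, n_hi, n_lo,
                                            defined=False))
            continue
        rr = p_hi / p_lo
        bi = rng.integers(0, n_hi, size=(n_boot, n_hi))
        bj = rng.integers(0, n_lo, size=(n_boot, n_lo))
        bp_hi = x_hi[bi].mean(axis=1)
        bp_lo = x_lo[bj].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            brr = bp_hi / bp_lo
        brr = brr[np.isfinite(brr)]
        ci = (float(np.percentile(brr, 2.5)), float(np.percentile(brr, 97.5))) \
            if brr.size else (None, None)
        results.append(EnrichmentResult(cat, float(rr), ci[0], ci[1],
                                        n_hi, n_lo))
    return results


def define_loci(leads: list[LeadSnp], merge_dist: int = 2_000_000
                ) -> list[list[LeadSnp]]:
    """Single-linkage merge of lead SNPs within ``merge_dist`` on the same
    chromosome into distinct loci (conservative locus definition)."""
    loci: list[list[LeadSnp]] = []
    by_chrom: dict[str, list[LeadSnp]] = {}
    for s in leads:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        snps = sorted(by_chrom[chrom], key=lambda s: s.pos)
        current = [snps[0]]
        for s in snps[1:]:
            if s.pos - current[-1].pos <= merge_dist:
                current.append(s)
            else:
                loci.append(current)
                current = [s]
        loci.append(current)
    return loci


def replication_check(prev_loci: list[LeadSnp], sumstats: pd.DataFrame,
                      window: int = 2_000_000, p_suggestive: float = 5e-5,
                      p_gws: float = 5e-8) -> pd.DataFrame:
    """Classify previous loci by the best p-value within ``window`` of each
    locus's most significant variant in the new summary statistics.

    ``sumstats`` needs ``chrom``, ``pos``, ``p`` columns.  Status is
    ``replicated_gws``, ``replicated_suggestive`` or ``not_replicated``; an
    empty window is not_replicated and flagged.
    """
    rows = []
    for locus in prev_loci:
        sel = sumstats[(sumstats["chrom"] == locus.chrom)
                       & (sumstats["pos"] >= locus.pos - window)
                       & (sumstats["pos"] <= locus.pos + window)]
        if sel.empty:
            rows.append({"variant": locus.variant, "min_p": np.nan,
                         "status": "not_replicated", "empty_window": True})
            continue
        min_p = float(sel["p"].min())
        if min_p < p_gws:
            status = "replicated_gws"
        elif min_p < p_suggestive:
            status = "replicated_suggestive"
        else:
            status = "not_replicated"
        rows.append({"variant": locus.variant, "min_p": min_p,
                     "status": status, "empty_window": False})
    return pd.DataFrame(rows)


def _pad_merge_intervals(intervals: list[tuple[int, int]], pad: int,
                         chrom_end: int | None = None
                         ) -> list[tuple[int, int]]:
    padded = []
    for lo, hi in intervals:
        lo, hi = lo - pad, hi + pad
        lo = max(lo, 1)
        if chrom_end is not None:
            hi = min(hi, chrom_end)
        padded.append((lo, hi))
    padded.sort()
    merged = [padded[0]]
    for lo, hi in padded[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def numt_window_screen(leads: list[LeadSnp],
                       numt_intervals: dict[str, list[tuple[int, int]]],
                       ld_lookup, pad: int = 500, flank: int = 10_000,
                       r2_max: float = 0.1,
                       chrom_ends: dict[str, int] | None = None) -> pd.DataFrame:
    """Flag lead variants in LD with SNPs near NUMT insertions.

    NUMT intervals (per chromosome, 1-based inclusive) are padded by ``pad``
    bases, merged, then surrounded by ``flank`` on each side (a 20 kb window
    for the default 10 kb).  ``ld_lookup(lead, chrom, lo, hi)`` returns the
    maximum r^2 between the lead and any SNP in the window (may raise).  A
    lead is flagged when any window yields r^2 > ``r2_max``; lookup failures
    mark the lead unevaluable.
    """
    rows = []
    merged = {
        chrom: _pad_merge_intervals(
            ivs, pad, None if chrom_ends is None else chrom_ends.get(chrom))
        for chrom, ivs in numt_intervals.items() if ivs
    }
    for lead in leads:
        flagged = False
        unevaluable = False
        max_r2 = 0.0
        for lo, hi in merged.get(lead.chrom, []):
            wlo, whi = max(lo - flank, 1), hi + flank
            try:
                r2 = float(ld_lookup(lead, lead.chrom, wlo, whi))
            except Exception:
                unevaluable = True
                continue
            max_r2 = max(max_r2, r2)
            if r2 > r2_max:
                flagged = True
        rows.append({"variant": lead.variant, "flagged": flagged,
                     "max_r2": max_r2, "unevaluable": unevaluable and not flagged})
    return pd.DataFrame(rows)


@dataclass
class EffectComparison:
    slope: float
    se: float
    intercept: float
    method: str
    n: int


def _deming_slope(x, y, lam: float) -> tuple[float, float]:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        return 0.0, float(np.mean(y))
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2
                                       + 4 * lam * sxy ** 2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def effect_comparison(beta_x, se_x, beta_y, se_y, method: str = "ivw_wls"
                      ) -> EffectComparison:
    """Regression of effect sizes y on x across shared variants.

    ``ivw_wls``: weighted least squares with product inverse-variance weights
    ``1/(se_x^2 * se_y^2)`` — attenuated by noise in x, appropriate for
    directional comparisons against a reference trait.  ``deming``:
    errors-in-variables regression with variance ratio
    ``lambda = mean(se_y^2)/mean(se_x^2)``, consistent under noise on both
    axes (the cross-biobank replication setting; orient alleles so the
    reference-cohort effect is positive first).
    """
    x = np.asarray(beta_x, dtype=float)
    y = np.asarray(beta_y, dtype=float)
    sx = np.asarray(se_x, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 shared variants")
    if method == "ivw_wls":
        w = 1.0 / (sx ** 2 * sy ** 2)
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        return EffectComparison(slope=float(fit.params[1]), se=float(fit.bse[1]),
                                intercept=float(fit.params[0]),
                                method=method, n=x.size)
    if method == "deming":
        lam = float(np.mean(sy ** 2) / np.mean(sx ** 2))
        slope, intercept = _deming_slope(x, y, lam)
        # leave-one-out jackknife s.e.
        n = x.size
        loo = np.empty(n)
        for i in range(n):
            m = np.ones(n, dtype=bool)
            m[i] = False
            loo[i], _ = _deming_slope(x[m], y[m], lam)
        se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
        return EffectComparison(slope=slope, se=se, intercept=intercept,
                                method=method, n=n)
    raise ValueError(f"unknown method {method!r}")
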