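"""Heteroplasmy phenotype construction.

Two encodings per common heteroplasmic variant:

* case-only — the allele fraction among carriers; non-carriers and
  homoplasmic-alternative samples are missing, so the trait measures *level*
  given presence;
* case-control — 1 for any detectable heteroplasmy, 0 only for samples that
  are confidently reference at the site (coverage >= 100 and no QC-failed
  call there), missing otherwise.

Plus sensitivity-filtered variants of the case-only traits, inverse-rank
normalisation for genetic analysis, and per-sample mutational spectrum
counts (transitions vs transversion subclasses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qc import HOM_THRESHOLD, MIN_SITE_COVERAGE

__all__ = [
    "PhenotypeMatrix",
    "case_only_matrix",
    "case_control_matrix",
    "sensitivity_filter",
    "inverse_rank_normalize",
    "mutation_spectrum",
]

_MISSING_TOKEN = "NA"


@dataclass
class PhenotypeMatrix:
    """Samples x traits grid with explicit missingness (NaN)."""

    data: pd.DataFrame           # index: sample ids, columns: trait labels
    kind: str                    # "case_only" | "case_control" | generic
    meta: dict = field(default_factory=dict)  # per-trait provenance

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#kind={self.kind}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"#meta:{k}={v}\n")
            self.data.to_csv(fh, sep="\t", na_rep=_MISSING_TOKEN,
                             index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeMatrix":
        kind, meta = "generic", {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#kind="):
                    kind = line.strip().split("=", 1)[1]
                elif line.startswith("#meta:"):
                    k, v = line.strip()[6:].split("=", 1)
                    meta[k] = v
                else:
                    fh.seek(pos)
                    break
                pos = fh.tell()
            data = pd.read_csv(fh, sep="\t", index_col="sample_id",
                               na_values=[_MISSING_TOKEN], keep_default_na=False)
        return cls(data=data, kind=kind, meta=meta)


def _pivot_het(cohort: pd.DataFrame, samples, variants) -> pd.DataFrame:
    t = cohort[cohort["variant_id"].isin(variants)]
    wide = t.pivot_table(index="sample_id", columns="variant_id",
                         values="het_post_qc", aggfunc="first")
    return wide.reindex(index=samples, columns=variants)


def case_only_matrix(cohort: pd.DataFrame, samples: list[str],
                     variants: list[str],
                     hom_threshold: float = HOM_THRESHOLD) -> PhenotypeMatrix:
    """Carrier allele fractions; non-carriers and homoplasmic samples missing.

    ``cohort`` is a QC'd call table with columns ``sample_id``, ``variant_id``,
    ``het_post_qc`` and ``qc_status``; only QC-pass calls contribute values.
    """
    missing = set(variants) - set(cohort["variant_id"].unique())
    if missing:
        raise KeyError(f"variants absent from cohort table: {sorted(missing)}")
    passing = cohort[cohort["qc_status"] == "pass"]
    wide = _pivot_het(passing, samples, variants)
    wide = wide.where((wide > 0) & (wide < hom_threshold))
    return PhenotypeMatrix(data=wide, kind="case_only",
                           meta={v: "raw" for v in variants})


def case_control_matrix(cohort: pd.DataFrame, samples: list[str],
                        variants: list[str], site_coverage: pd.DataFrame,
                        min_cov: int = MIN_SITE_COVERAGE,
                        hom_threshold: float = HOM_THRESHOLD) -> PhenotypeMatrix:
    """Detectable heteroplasmy (1) vs confident reference (0).

    ``site_coverage`` is a samples x variants table of post-realignment depth
    at each variant's site.  A sample is 0 for a variant only when it has no
    call there, coverage >= ``min_cov`` and no QC-failed call at the site;
    homoplasmic-alternative samples are missing.
    """
    passing = cohort[cohort["qc_status"] == "pass"]
    het = _pivot_het(passing, samples, variants)
    cov = site_coverage.reindex(index=samples, columns=variants)

    failed = cohort[cohort["qc_status"].isin(["low_het", "caller_flag"])]
    fail_mask = (
        failed.assign(flag=True)
        .pivot_table(index="sample_id", columns="variant_id", values="flag",
                     aggfunc="any")
        .reindex(index=samples, columns=variants)
        .eq(True)
    )

    values = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"),
                          columns=variants)
    carrier = (het > 0) & (het < hom_threshold)
    homoplasmic = het >= hom_threshold
    confident_ref = het.isna() & (cov >= min_cov) & ~fail_mask
    values[confident_ref] = 0.0
    values[carrier] = 1.0
    values[homoplasmic] = np.nan
    return PhenotypeMatrix(data=values, kind="case_control",
                           meta={v: "raw" for v in variants})


def sensitivity_filter(matrix: PhenotypeMatrix, mode: str,
                       aux: pd.DataFrame) -> PhenotypeMatrix:
    """Sensitivity variants of case-only traits.

    ``mode="ad_alt_floor"``: a value is made missing when the supporting
    alternate-allele depth is below the sample's mean nuclear coverage; ``aux``
    needs a samples x variants ``alt_depth`` layout plus a ``nuc_coverage``
    column (or the column alone indexed by sample).  Residual modes
    (``"local_cov_residual"``, ``"csb2_cov_residual"``) replace each trait by
    the residual of a per-variant regression on the given covariate; ``aux``
    is then a samples x variants (or broadcastable per-sample) covariate
    table aligned to the matrix.
    """
    data = matrix.data.copy()
    if mode == "ad_alt_floor":
        if "nuc_coverage" not in aux.columns:
            raise KeyError("aux must carry a 'nuc_coverage' column")
        nuc = aux["nuc_coverage"].reindex(data.index)
        ad = aux.drop(columns=["nuc_coverage"]).reindex(
            index=data.index, columns=data.columns)
        data = data.where(~ad.lt(nuc, axis=0))
        meta = {v: "ad_alt_filtered" for v in data.columns}
    elif mode in ("local_cov_residual", "csb2_cov_residual"):
        cov_tab = aux.reindex(index=data.index)
        for v in data.columns:
            col = cov_tab[v] if v in cov_tab.columns else cov_tab.iloc[:, 0]
            y = data[v]
            ok = y.notna() & col.notna()
            if ok.sum() < 2:
                continue
            x = col[ok].to_numpy(float)
            yy = y[ok].to_numpy(float)
            X = np.column_stack([np.ones(ok.sum()), x])
            beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
            data.loc[ok, v] = yy - X @ beta
        meta = {v: f"residual:{mode}" for v in data.columns}
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    return PhenotypeMatrix(data=data, kind=matrix.kind, meta=meta)


def inverse_rank_normalize(values) -> np.ndarray:
    """Rank-based inverse normal transform, ``Phi^-1((rank - 0.5) / n)``.

    Ranks are averaged on ties; missing values are preserved.  Applied to
    every quantitative trait before genetic analysis.
    """
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all values missing")
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = sps.rankdata(arr[ok], method="average")
    out = np.full(arr.shape, np.nan)
    out[ok] = sps.norm.ppf((ranks - 0.5) / n)
    return out


_TRANSITIONS = {frozenset({"A", "G"}), frozenset({"C", "T"})}
_TV_CLASSES = {
    frozenset({"A", "C"}): "transversion_AC",
    frozenset({"A", "T"}): "transversion_AT",
    frozenset({"C", "G"}): "transversion_CG",
    frozenset({"G", "T"}): "transversion_GT",
}
SPECTRUM_COLUMNS = ["transition"] + sorted(_TV_CLASSES.values())


def mutation_spectrum(cohort: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-sample heteroplasmic SNV counts by substitution class.

    Transitions (A<->G, C<->T) are pooled; transversions are subclassed by the
    unordered reference-strand base pair.  Every sample appears, with explicit
    zeros, so cohort means are over all individuals.  Non-SNV rows are
    skipped.  ``cohort`` needs ``sample_id``, ``ref``, ``alt`` columns and
    should be restricted to QC-passed heteroplasmic calls.
    """
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                          columns=SPECTRUM_COLUMNS)
    snv = cohort[(cohort["ref"].str.len() == 1) & (cohort["alt"].str.len() == 1)]
    for _, row in snv.iterrows():
        pair = frozenset({row["ref"], row["alt"]})
        if pair in _TRANSITIONS:
            col = "transition"
        elif pair in _TV_CLASSES:
            col = _TV_CLASSES[pair]
        else:
            continue
        if row["sample_id"] in counts.index:
            counts.loc[row["sample_id"], col] += 1
    return counts
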