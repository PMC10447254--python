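"""Mitochondrial genotype PCA, haplogroup prediction and transmission tables.

Homoplasmic variants (allele fraction >= 0.95) at cohort MAF >= 0.001 define
a binary genotype matrix; PCs are computed on the unrelated subset after
centring and scaling, and related samples are projected onto the loadings.
McFadden's pseudo-R^2 of a multinomial haplogroup model on the first PCs
quantifies how much maternal-lineage structure the PCs capture.
Parent-offspring and sibling heteroplasmy pair tables support transmission
analyses (maternally transmitted indel mixtures vs somatic SNVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "MtGenotypeMatrix",
    "PairSet",
    "homoplasmy_genotype_matrix",
    "compute_pcs",
    "project_related",
    "haplogroup_pseudo_r2",
    "transmission_table",
    "pair_correlation",
    "sharing_rate",
]


@dataclass
class MtGenotypeMatrix:
    """Binary samples x variants homoplasmy matrix with per-variant MAF."""

    data: pd.DataFrame          # 0/1, index sample ids
    maf: pd.Series


@dataclass
class PairSet:
    """Relative pairs; relationship in {mother_offspring, father_offspring,
    sibling}."""

    pairs: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for a, b, rel in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
            if rel not in ("mother_offspring", "father_offspring", "sibling"):
                raise ValueError(f"unknown relationship {rel!r}")


def homoplasmy_genotype_matrix(cohort: pd.DataFrame, samples: list[str],
                               maf_min: float = 0.001,
                               hom_threshold: float = 0.95) -> MtGenotypeMatrix:
    """Binary genotype matrix from QC-passed homoplasmies.

    A sample is coded 1 for a variant iff a QC-pass call with allele fraction
    >= ``hom_threshold`` was detected; variants below ``maf_min`` cohort
    frequency are dropped.  ``cohort`` needs ``sample_id``, ``variant_id``,
    ``het_post_qc`` and ``qc_status`` columns.
    """
    hom = cohort[(cohort["qc_status"] == "pass")
                 & (cohort["het_post_qc"] >= hom_threshold)]
    wide = (hom.assign(g=1)
            .pivot_table(index="sample_id", columns="variant_id", values="g",
                         aggfunc="max")
            .reindex(index=samples)
            .fillna(0.0))
    n = len(samples)
    freq = wide.sum(axis=0) / n
    maf = np.minimum(freq, 1 - freq)
    keep = maf.index[maf >= maf_min]
    return MtGenotypeMatrix(data=wide[keep].astype(float), maf=maf[keep])


@dataclass
class PcaResult:
    scores: pd.DataFrame        # unrelated-sample scores
    loadings: pd.DataFrame      # variants x k
    mean: pd.Series
    scale: pd.Series
    explained_variance: np.ndarray


def compute_pcs(matrix: MtGenotypeMatrix, k: int = 50,
                unrelated_mask: pd.Series | None = None) -> PcaResult:
    """Truncated SVD of the centred/scaled genotype matrix over unrelated
    samples.

    Constant columns (after restriction) are dropped with a warning via
    zero-variance guard.  PC signs are fixed by making each component's
    largest-magnitude loading positive, for run-to-run reproducibility.
    """
    X = matrix.data
    if unrelated_mask is not None:
        X = X.loc[unrelated_mask.reindex(X.index).fillna(False)]
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    nonconst = scale > 0
    if not nonconst.all():
        import warnings
        warnings.warn(f"dropping {int((~nonconst).sum())} constant variant columns")
    Xc = ((X.loc[:, nonconst] - mean[nonconst]) / scale[nonconst]).to_numpy(float)
    k = min(k, min(Xc.shape))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign convention
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    cols = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=X.index, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=X.columns[nonconst], columns=cols)
    ev = s ** 2 / max(Xc.shape[0] - 1, 1)
    return PcaResult(scores=scores, loadings=loadings, mean=mean[nonconst],
                     scale=scale[nonconst], explained_variance=ev)


def project_related(pca: PcaResult, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Project (related) samples onto existing loadings using the unrelated
    centring/scaling."""
    X = genotypes.reindex(columns=pca.loadings.index).fillna(0.0)
    Xc = ((X - pca.mean) / pca.scale).to_numpy(float)
    return pd.DataFrame(Xc @ pca.loadings.to_numpy(),
                        index=genotypes.index, columns=pca.loadings.columns)


def haplogroup_pseudo_r2(scores: pd.DataFrame, labels: pd.Series,
                         n_pcs: int = 30, min_class_n: int = 30
                         ) -> tuple[float, bool]:
    """McFadden pseudo-R^2 of a multinomial haplogroup-on-PCs model.

    ``1 - loglik / null_loglik`` with an intercept-only null; haplogroups
    with fewer than ``min_class_n`` samples are excluded.  Returns
    ``(pseudo_r2, separated)``; under (near-)perfect separation the value
    saturates toward 1 and is flagged.
    """
    labels = labels.reindex(scores.index)
    counts = labels.value_counts()
    keep = labels.map(counts).ge(min_class_n) & labels.notna()
    y = labels[keep]
    if y.nunique() < 2:
        raise ValueError("need at least two haplogroup classes after filtering")
    X = scores.loc[keep].iloc[:, :n_pcs].to_numpy(float)

    # effectively-unpenalised multinomial fit (tiny ridge for stability)
    clf = LogisticRegression(C=1e8, max_iter=2000)
    clf.fit(X, y)
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    idx = y.map({c: i for i, c in enumerate(classes)}).to_numpy()
    ll = float(np.sum(np.log(np.clip(proba[np.arange(len(y)), idx], 1e-300, None))))
    p_null = y.value_counts(normalize=True)
    ll_null = float(np.sum(np.log(y.map(p_null).to_numpy())))
    r2 = 1.0 - ll / ll_null
    separated = bool(r2 > 0.999)
    return (min(r2, 1.0), separated)


def transmission_table(cohort: pd.DataFrame, pairs: PairSet,
                       site_status: pd.DataFrame | None = None,
                       min_variant_samples: int = 5) -> pd.DataFrame:
    """Per-variant heteroplasmy pair table for transmission analysis.

    One row per (variant, pair) where at least one member carries the variant
    heteroplasmically; the partner's value is 0 when the site is confidently
    reference (``site_status`` samples x variants boolean table, True =
    confident reference) and missing otherwise.  Variants carried by fewer
    than ``min_variant_samples`` samples are excluded.  Columns: variant_id,
    id_a, id_b, relationship, het_a, het_b, type (SNV/indel).
    """
    carriers = cohort[(cohort["qc_status"] == "pass")
                      & (cohort["het_post_qc"] > 0)]
    n_samples = carriers.groupby("variant_id")["sample_id"].nunique()
    keep_variants = set(n_samples.index[n_samples >= min_variant_samples])
    het = {}
    vtype = {}
    for row in carriers.itertuples():
        if row.variant_id not in keep_variants:
            continue
        het[(row.sample_id, row.variant_id)] = row.het_post_qc
        vtype[row.variant_id] = ("SNV" if len(row.ref) == 1 == len(row.alt)
                                 else "indel")

    def partner_value(sample: str, variant: str):
        if (sample, variant) in het:
            return het[(sample, variant)]
        if site_status is not None:
            try:
                if bool(site_status.loc[sample, variant]):
                    return 0.0
            except KeyError:
                pass
            return np.nan
        return 0.0  # without status info, absence is taken as reference

    rows = []
    for a, b, rel in pairs.pairs:
        variants = {v for (s, v) in het if s in (a, b)}
        for v in sorted(variants):
            rows.append({
                "variant_id": v, "id_a": a, "id_b": b, "relationship": rel,
                "het_a": partner_value(a, v), "het_b": partner_value(b, v),
                "type": vtype[v],
            })
    return pd.DataFrame(rows, columns=["variant_id", "id_a", "id_b",
                                       "relationship", "het_a", "het_b", "type"])


def _subset_pairs(table: pd.DataFrame, relationship: str | None,
                  variant_type: str | None) -> pd.DataFrame:
    t = table
    if relationship is not None:
        t = t[t["relationship"] == relationship]
    if variant_type is not None:
        t = t[t["type"] == variant_type]
    return t


def pair_correlation(table: pd.DataFrame, relationship: str | None = None,
                     variant_type: str | None = None,
                     both_carriers: bool = True) -> float:
    """Pearson correlation of heteroplasmy between pair members.

    With ``both_carriers`` (default) the quantitative-transmission convention
    is used: only rows where both members carry the variant contribute, so
    coincidental co-occurrence of independent (somatic) variants yields
    r ~ 0 while transmitted mixtures yield high r.
    """
    t = _subset_pairs(table, relationship, variant_type).dropna(
        subset=["het_a", "het_b"])
    if both_carriers:
        t = t[(t["het_a"] > 0) & (t["het_b"] > 0)]
    if len(t) < 3:
        return np.nan
    return float(np.corrcoef(t["het_a"], t["het_b"])[0, 1])


def sharing_rate(table: pd.DataFrame, relationship: str | None = None,
                 variant_type: str | None = None) -> float:
    """Fraction of pair rows in which both members carry the variant."""
    t = _subset_pairs(table, relationship, variant_type).dropna(
        subset=["het_a", "het_b"])
    if t.empty:
        return np.nan
    return float(((t["het_a"] > 0) & (t["het_b"] > 0)).mean())
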