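"""Covariate adjustment for mtDNA phenotypes.

Blood mtCN is strongly confounded by blood-cell composition and, more
surprisingly, by technical circumstances of the blood draw (time of day,
season, fasting duration).  The correction model residualises each mtDNA
trait on:

* technical terms — a natural-spline basis over draw time (5 df), assessment
  centre and month indicators, fasting-hour indicators (0 recoded to 1,
  capped at 18 h), and a natural spline over assessment date with knots on a
  seasonal (3-month) grid;
* blood terms — 14 non-redundant cell-count/volume indices, with individual
  measurements at |Z| > 4 masked out.

Residualisation is gated per trait by a joint-model F-test at a
Bonferroni-corrected alpha of 0.05/40 (39 common heteroplasmies + mtCN);
mtCN is adjusted on the log scale and re-exponentiated for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignConfig",
    "AdjustmentReport",
    "natural_spline_basis",
    "build_design",
    "gated_adjust",
    "rescale_adjusted",
    "residualize_demographics",
    "carrier_phenotype_test",
    "carrier_phenotype_tests",
    "disease_association",
    "BLOOD_COLUMNS",
    "ALPHA_BONFERRONI_40",
]

ALPHA_BONFERRONI_40 = 0.05 / 40

#: The 14 non-redundant blood-count covariates of the blood model.
BLOOD_COLUMNS = [
    "wbc_count", "haematocrit_pct", "platelet_crit", "monocyte_pct",
    "neutrophil_pct", "eosinophil_pct", "basophil_pct", "reticulocyte_pct",
    "hls_reticulocyte_pct", "immature_reticulocyte_fraction",
    "mean_corpuscular_volume", "mean_reticulocyte_volume",
    "mean_sphered_cell_volume", "mean_platelet_volume",
]


def _default_seasonal_knots() -> list[np.datetime64]:
    """3-month grid from 2007-07-01 to 2010-07-01 inclusive (13 knots)."""
    return list(pd.date_range("2007-07-01", "2010-07-01", freq="3MS").values)


@dataclass
class DesignConfig:
    draw_time_df: int = 5
    seasonal_knots: list = field(default_factory=_default_seasonal_knots)
    fasting_cap: int = 18
    fasting_floor_recode: int = 1   # fasting time 0 relabelled to this
    blood_z_cut: float = 4.0
    blood_columns: list = field(default_factory=lambda: list(BLOOD_COLUMNS))

    def __post_init__(self) -> None:
        if self.draw_time_df < 1:
            raise ValueError("draw_time_df must be >= 1")
        knots = pd.to_datetime(pd.Series(self.seasonal_knots))
        if not knots.is_monotonic_increasing or knots.duplicated().any():
            raise ValueError("seasonal knots must be strictly increasing")


@dataclass
class AdjustmentReport:
    trait: str
    f_statistic: float
    f_pvalue: float
    gated: bool
    n_used: int
    model_terms: list[str]


def natural_spline_basis(x, df: int | None = None, knots=None,
                         boundary_knots=None) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), linear beyond the
    boundary knots.

    Either ``df`` (interior knots at quantiles, boundary at data min/max) or
    an explicit interior ``knots`` sequence may be given.  The construction is
    the standard truncated-power one: with all knots xi_1 < ... < xi_K
    (boundary included), columns are ``x`` and ``d_k - d_{K-1}`` for
    k = 1..K-2, where ``d_k(x) = ((x - xi_k)^3_+ - (x - xi_K)^3_+)/(xi_K - xi_k)``.
    Column count equals ``df`` (= number of interior knots + 1).
    """
    x = np.asarray(x, dtype=float)
    if knots is not None:
        interior = np.sort(np.asarray(knots, dtype=float))
    else:
        if df is None:
            raise ValueError("give either df or knots")
        if df < 1:
            raise ValueError("df must be >= 1")
        if df == 1:
            return x[:, None]
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior = np.quantile(x, probs)
    if boundary_knots is None:
        boundary = (np.min(x), np.max(x))
    else:
        boundary = (float(boundary_knots[0]), float(boundary_knots[1]))
    allk = np.concatenate([[boundary[0]], interior, [boundary[1]]])
    allk = np.unique(allk)
    K = allk.size
    if K < 2 or np.unique(x).size < K:
        raise ValueError(
            f"need at least {K} distinct x values for {K} knots")

    def d(k):  # truncated-cubic difference quotient
        return (np.clip(x - allk[k], 0, None) ** 3
                - np.clip(x - allk[K - 1], 0, None) ** 3) / (allk[K - 1] - allk[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


def _indicators(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Indicator expansion dropping the first (reference) level."""
    dummies = pd.get_dummies(series.astype("category"), prefix=prefix,
                             drop_first=True, dtype=float)
    return dummies


def build_design(samples: pd.DataFrame, config: DesignConfig | None = None,
                 model: str = "joint"
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Construct the correction design matrix (without intercept).

    ``samples`` columns used: ``draw_time`` (hour of day), ``centre``,
    ``fasting_time`` (hours), ``assessment_date`` (datetime-like), and the
    blood columns of the config.  Assessment month is derived from the date.
    Returns ``(X, row_mask)``; rows failing the blood |Z| cut are masked out
    for the blood and joint models rather than imputed.
    """
    config = config or DesignConfig()
    if model not in ("technical", "blood", "joint"):
        raise ValueError(f"unknown model {model!r}")
    parts: list[pd.DataFrame] = []
    mask = pd.Series(True, index=samples.index)

    if model in ("technical", "joint"):
        dt = samples["draw_time"].astype(float)
        ns_dt = natural_spline_basis(dt.to_numpy(), df=config.draw_time_df)
        parts.append(pd.DataFrame(
            ns_dt, index=samples.index,
            columns=[f"ns_draw_time_{i+1}" for i in range(ns_dt.shape[1])]))
        parts.append(_indicators(samples["centre"], "centre"))

        fasting = samples["fasting_time"].astype(float).round().astype(int)
        fasting = fasting.where(fasting != 0, config.fasting_floor_recode)
        fasting = fasting.clip(upper=config.fasting_cap)
        parts.append(_indicators(fasting, "fasting"))

        dates = pd.to_datetime(samples["assessment_date"])
        epoch = pd.Timestamp("1970-01-01")
        day = (dates - epoch) / pd.Timedelta(days=1)  # days since epoch
        knots_day = (pd.to_datetime(pd.Series(config.seasonal_knots))
                     - epoch) / pd.Timedelta(days=1)
        ns_date = natural_spline_basis(
            day.to_numpy(), knots=knots_day.to_numpy()[1:-1],
            boundary_knots=(knots_day.iloc[0], knots_day.iloc[-1]))
        parts.append(pd.DataFrame(
            ns_date, index=samples.index,
            columns=[f"ns_date_{i+1}" for i in range(ns_date.shape[1])]))
        parts.append(_indicators(dates.dt.month, "month"))

    if model in ("blood", "joint"):
        blood = samples[config.blood_columns].astype(float)
        z = (blood - blood.mean()) / blood.std(ddof=0)
        mask &= ~(z.abs() > config.blood_z_cut).any(axis=1)
        parts.append(blood)

    X = pd.concat(parts, axis=1)
    return X, mask


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name likely-collinear columns via small R diagonal in QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.argsort(diag)[: X.shape[1] - rank]]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns likely include {bad}")


def gated_adjust(values, design: pd.DataFrame,
                 alpha: float = ALPHA_BONFERRONI_40, scale: str = "identity",
                 row_mask: pd.Series | None = None, trait: str = "trait"
                 ) -> tuple[pd.Series, AdjustmentReport]:
    """F-test-gated residualisation of one trait on a covariate design.

    The joint model is compared against intercept-only; only when the F-test
    p-value clears ``alpha`` (Bonferroni-corrected 0.05/40 by default) is the
    residualised trait returned, otherwise the input comes back unchanged.
    ``scale="log"`` fits log(values) (the mtCN convention).  Rows masked out
    or with missing data are returned as NaN in the adjusted series.
    """
    y = pd.Series(np.asarray(values, dtype=float), index=design.index)
    if scale == "log":
        y = np.log(y)
    elif scale != "identity":
        raise ValueError(f"unknown scale {scale!r}")
    ok = y.notna() & design.notna().all(axis=1)
    if row_mask is not None:
        ok &= row_mask
    if design.shape[1] == 0:
        # intercept-only residualisation: no covariates to gate on
        out = pd.Series(np.nan, index=design.index)
        out[ok] = y[ok] - y[ok].mean()
        report = AdjustmentReport(trait=trait, f_statistic=np.nan,
                                  f_pvalue=np.nan, gated=True,
                                  n_used=int(ok.sum()), model_terms=[])
        return out, report
    Xm = design.loc[ok].to_numpy(float)
    _check_full_rank(Xm, list(design.columns))
    # standardise columns before fitting: the residuals are unchanged (same
    # column span) but conditioning improves by orders of magnitude when
    # spline columns dwarf indicator columns
    sd = Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xm - Xm.mean(axis=0)) / sd
    fit = sm.OLS(y[ok].to_numpy(), sm.add_constant(Xs)).fit(method="qr")
    gated = bool(fit.f_pvalue < alpha)
    out = pd.Series(np.nan, index=design.index)
    if gated:
        out[ok] = fit.resid
    else:
        out[ok] = y[ok]
    report = AdjustmentReport(
        trait=trait, f_statistic=float(fit.fvalue), f_pvalue=float(fit.f_pvalue),
        gated=gated, n_used=int(ok.sum()), model_terms=list(design.columns))
    return out, report


def rescale_adjusted(residuals, pre_mean: float, mode: str = "add_mean"):
    """Return residualised values to a display scale.

    ``add_mean`` adds the pre-adjustment mean back; ``exp_add_mean`` adds the
    pre-adjustment log-scale mean and exponentiates (the mtCN_adj convention,
    returning absolute copies per diploid genome).
    """
    res = np.asarray(residuals, dtype=float)
    if mode == "add_mean":
        return res + pre_mean
    if mode == "exp_add_mean":
        return np.exp(res + pre_mean)
    raise ValueError(f"unknown mode {mode!r}")


def _demographic_design(samples: pd.DataFrame) -> pd.DataFrame:
    age = samples["age"].astype(float)
    sex = samples["sex"].astype(float)
    X = pd.DataFrame({
        "age": age, "sex": sex, "age2": age ** 2,
        "age2_sex": age ** 2 * sex, "age_sex": age * sex,
    }, index=samples.index)
    if "population" in samples.columns:
        X = pd.concat([X, _indicators(samples["population"], "pop")], axis=1)
    return X


def residualize_demographics(measure, samples: pd.DataFrame,
                             log_scale: bool = False,
                             lr_average: bool = False) -> pd.Series:
    """Residualise a continuous measure on age, sex, age^2, their interactions
    and genetic-ancestry group, adding the dataset mean back.

    ``lr_average`` first averages a two-column (left, right) measure (hearing
    and vision tests).  ``log_scale`` log-transforms before fitting and
    exponentiates after the mean is added back (log-normal biomarkers such as
    HbA1c and triglycerides).
    """
    if lr_average:
        m = pd.DataFrame(measure)
        if m.shape[1] != 2:
            raise ValueError("lr_average expects a two-column measure")
        y = m.mean(axis=1)
    else:
        y = pd.Series(np.asarray(measure, dtype=float), index=samples.index)
    if log_scale:
        y = np.log(y)
    X = _demographic_design(samples)
    ok = y.notna() & X.notna().all(axis=1)
    fit = sm.OLS(y[ok].to_numpy(), sm.add_constant(X.loc[ok].to_numpy(float))).fit()
    out = pd.Series(np.nan, index=samples.index)
    out[ok] = fit.resid + y[ok].mean()
    if log_scale:
        out = np.exp(out)
    return out


@dataclass
class CarrierTestResult:
    variant: str
    phenotype: str
    n_carriers: int
    n_controls: int
    t_statistic: float | None
    p_value: float | None
    q_value: float | None = None
    tested: bool = True


def carrier_phenotype_test(carrier_values, control_values, min_n: int = 10,
                           variant: str = "", phenotype: str = ""
                           ) -> CarrierTestResult:
    """Two-sample t-test of residualised phenotype, carriers vs controls.

    Run only when carriers contribute strictly more than ``min_n`` defined
    values; otherwise the pair is flagged untested.
    """
    ca = np.asarray(carrier_values, dtype=float)
    co = np.asarray(control_values, dtype=float)
    ca, co = ca[~np.isnan(ca)], co[~np.isnan(co)]
    if ca.size <= min_n:
        return CarrierTestResult(variant, phenotype, ca.size, co.size,
                                 None, None, tested=False)
    t, p = sps.ttest_ind(ca, co)
    return CarrierTestResult(variant, phenotype, ca.size, co.size,
                             float(t), float(p))


def carrier_phenotype_tests(pairs: list[tuple]) -> list[CarrierTestResult]:
    """Run carrier tests over (carrier_values, control_values, variant,
    phenotype) tuples and attach Benjamini-Hochberg q-values across the
    tested set."""
    results = [carrier_phenotype_test(ca, co, variant=v, phenotype=ph)
               for ca, co, v, ph in pairs]
    tested = [r for r in results if r.tested]
    if tested:
        _, q, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    return results


@dataclass
class DiseaseAssociation:
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n: int
    separated: bool = False


def disease_association(trait_z, disease, samples: pd.DataFrame,
                        haplogroup: pd.Series | None = None,
                        min_haplogroup_n: int = 30) -> DiseaseAssociation:
    """Logistic regression of a binary disease phenotype on a standardised
    trait with demographic covariates (age, sex, age^2 and interactions,
    ancestry group) and, for mtDNA-derived traits, top-level haplogroup
    indicators restricted to haplogroups with >= ``min_haplogroup_n`` members.

    OR = exp(beta_trait); 95% CI = exp(beta +/- 1.96 * s.e.).
    """
    y = pd.Series(np.asarray(disease, dtype=float), index=samples.index)
    z = pd.Series(np.asarray(trait_z, dtype=float), index=samples.index)
    X = pd.concat([z.rename("trait"), _demographic_design(samples)], axis=1)
    keep = pd.Series(True, index=samples.index)
    if haplogroup is not None:
        counts = haplogroup.value_counts()
        keep &= haplogroup.map(counts).ge(min_haplogroup_n).fillna(False)
        X = pd.concat([X, _indicators(haplogroup, "hap")], axis=1)
    ok = keep & y.notna() & X.notna().all(axis=1)
    Xm = sm.add_constant(X.loc[ok].to_numpy(float))
    try:
        fit = sm.Logit(y[ok].to_numpy(), Xm).fit(disp=0, maxiter=200)
    except Exception:
        return DiseaseAssociation(None, None, None, None, int(ok.sum()),
                                  separated=True)
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        return DiseaseAssociation(None, None, None, None, int(ok.sum()),
                                  separated=True)
    beta, se = fit.params[1], fit.bse[1]
    return DiseaseAssociation(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(fit.pvalues[1]), n=int(ok.sum()))
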