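"""Synthetic cohorts, pedigrees, coverage and reads for the mtDNA pipeline.

The generator emulates the statistical structure the pipeline assumes so that
every module is exercisable without access to biobank data:

* log mtDNA copy number with an age slope (~-0.002/yr, i.e. roughly 2% per
  decade), a time-of-day sinusoid on the blood draw, a seasonal sinusoid on
  the assessment date, and blood-cell-index slopes — with the first blood
  index deliberately age-correlated so that the *raw* age slope is
  confounded and only the covariate-adjusted one is unbiased;
* heteroplasmy: inherited indel sites with Beta-distributed maternal founder
  fractions transmitted with truncated-Gaussian jitter, somatic SNVs whose
  expected count rises with age, and NUMT-artefact calls at low allele
  fraction (< 0.05) that post-calling QC is supposed to remove;
* reads spanning the chrM:300-318 poly-C locus for the length-heteroplasmy
  classifier, with substitution errors.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import BLOOD_COLUMNS
from .mtpop import PairSet
from .qc import variant_id

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_csb2_reads",
    "simulate_pedigree_heteroplasmy",
    "simulate_qc_cohort",
    "write_cohort",
]

#: Inherited length-variant (indel) sites with lineage carrier probabilities.
INHERITED_INDEL_SITES = {
    "chrM:302:A,AC": 0.45,
    "chrM:302:A,ACC": 0.25,
    "chrM:16183:A,AC": 0.30,
    "chrM:16182:A,ACC": 0.15,
    "chrM:567:A,ACCCCCC": 0.10,
}

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Generative parameters for a synthetic biobank-style cohort.

    Effect sizes are on log mtCN; amplitudes are sinusoid half-ranges.  The
    defaults are the study conditions the package's recovery tests assume.
    """

    n_samples: int = 2000
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 70.0)
    mtcn_base: float = 61.66          # copies per diploid genome at age 55
    age_slope_log: float = -0.002     # per year, on log mtCN
    draw_time_amplitude: float = 0.05
    seasonal_amplitude: float = 0.05
    blood_slopes: tuple[float, ...] = (0.10, -0.05, 0.03)  # first k indices
    blood_age_corr: float = 0.01      # age loading on the first blood index
    noise_sd: float = 0.15            # residual s.d. of log mtCN
    # heteroplasmy model
    inherited_sites: dict = field(
        default_factory=lambda: dict(INHERITED_INDEL_SITES))
    maternal_beta: tuple[float, float] = (2.0, 8.0)
    transmission_sd: float = 0.05
    somatic_rate_base: float = 0.5    # expected SNVs at the youngest age
    somatic_rate_per_year: float = 0.05
    numt_artifact_rate: float = 0.7   # expected low-fraction artefact calls
    # read / coverage model
    mt_depth: float = 250.0
    nuc_coverage_mean: float = 30.0
    nuc_coverage_sd: float = 3.0
    error_rate: float = 0.001
    # pedigree
    n_trios: int = 100
    n_sib_pairs: int = 50

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.transmission_sd < 0 or self.error_rate < 0:
            raise ValueError("rates and s.d. values must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("inconsistent age range")


def _truncnorm01(rng, mean, sd):
    """Gaussian jitter truncated (by resampling) to the open unit interval."""
    out = np.asarray(rng.normal(mean, sd))
    bad = (out <= 0) | (out >= 1)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], sd)
        bad = (out <= 0) | (out >= 1)
        tries += 1
        if tries > 1000:  # sd = 0 with a boundary mean cannot terminate
            out = np.clip(out, 1e-6, 1 - 1e-6)
            break
    return out


def _metadata(rng, cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_samples
    ids = [f"S{i:06d}" for i in range(n)]
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    draw_time = rng.uniform(7.0, 19.0, size=n)
    start = np.datetime64("2007-07-01")
    span_days = int((np.datetime64("2010-07-01") - start)
                    / np.timedelta64(1, "D"))
    date = start + rng.integers(0, span_days, size=n).astype("timedelta64[D]")
    centre = rng.choice([f"centre_{i}" for i in range(5)], size=n)
    fasting = np.clip(rng.poisson(4.0, size=n), 0, 24)
    hapl = rng.choice(list("HUJKTVXW"), size=n,
                      p=[0.44, 0.14, 0.11, 0.09, 0.09, 0.05, 0.04, 0.04])
    pop = rng.choice(["EUR", "AFR", "CSA", "EAS"], size=n,
                     p=[0.85, 0.06, 0.06, 0.03])
    meta = pd.DataFrame({
        "sample_id": ids, "age": age, "sex": sex, "draw_time": draw_time,
        "assessment_date": date, "centre": centre, "fasting_time": fasting,
        "haplogroup": hapl, "population": pop,
    }).set_index("sample_id")
    blood = rng.standard_normal((n, len(BLOOD_COLUMNS)))
    blood[:, 0] += cfg.blood_age_corr * (age - age.mean())
    for j, c in enumerate(BLOOD_COLUMNS):
        meta[c] = blood[:, j]
    return meta


def _log_mtcn(rng, cfg: SimConfig, meta: pd.DataFrame) -> np.ndarray:
    age = meta["age"].to_numpy()
    doy = pd.to_datetime(meta["assessment_date"]).dt.dayofyear.to_numpy()
    lm = (np.log(cfg.mtcn_base)
          + cfg.age_slope_log * (age - age.mean())
          + cfg.draw_time_amplitude
          * np.sin(2 * np.pi * (meta["draw_time"].to_numpy() - 7.0) / 12.0)
          + cfg.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25))
    for j, b in enumerate(cfg.blood_slopes):
        lm = lm + b * meta[BLOOD_COLUMNS[j]].to_numpy()
    return lm + cfg.noise_sd * rng.standard_normal(len(meta))


def _split_variant(vid: str) -> tuple[str, int, str, str]:
    contig, pos, alleles = vid.split(":")
    ref, alt = alleles.split(",")
    return contig, int(pos), ref, alt


def _call_rows(rng, cfg, sample, vids, hets, origin, depth_mean):
    rows = []
    for vid, h in zip(vids, hets):
        contig, pos, ref, alt = _split_variant(vid)
        depth = max(int(rng.poisson(depth_mean)), 1)
        rows.append({
            "sample_id": sample, "contig": contig, "pos": pos, "ref": ref,
            "alt": alt, "variant_id": vid, "heteroplasmy": float(h),
            "depth": depth, "alt_depth": int(round(h * depth)),
            "filters": "", "origin": origin,
        })
    return rows


def simulate_cohort(config: SimConfig | None = None) -> dict:
    """Generate a full synthetic cohort.

    Returns a dict of tables: ``metadata`` (covariates, haplogroup, nuclear
    coverage, mtCN), ``calls`` (per-sample variant calls with allele
    fraction, depth and an ``origin`` provenance column), and ``truth``
    (the planted generative parameters).  Deterministic given
    ``config.seed``.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    meta = _metadata(rng, cfg)
    log_mtcn = _log_mtcn(rng, cfg, meta)
    meta["mtcn"] = np.exp(log_mtcn)
    meta["nuc_coverage"] = np.clip(
        rng.normal(cfg.nuc_coverage_mean, cfg.nuc_coverage_sd, len(meta)), 5, None)
    meta["mt_mean_coverage"] = meta["mtcn"] * meta["nuc_coverage"] / 2.0

    a, b = cfg.maternal_beta
    rows: list[dict] = []
    somatic_pool = rng.integers(600, 16_000, size=200)
    for sample, srow in meta.iterrows():
        depth_mean = srow["mt_mean_coverage"]
        # inherited indel mixtures
        for vid, p_carrier in cfg.inherited_sites.items():
            if rng.random() < p_carrier:
                het = float(rng.beta(a, b))
                rows += _call_rows(rng, cfg, sample, [vid], [het],
                                   "inherited", depth_mean)
        # somatic SNVs, expected count rising with age
        lam = cfg.somatic_rate_base + cfg.somatic_rate_per_year \
            * (srow["age"] - cfg.age_range[0])
        n_som = rng.poisson(max(lam, 0))
        if n_som:
            sites = rng.choice(somatic_pool, size=n_som, replace=False)
            vids, hets = [], []
            for s in sites:
                ref = str(rng.choice(_BASES))
                alt = _TRANSITION[ref] if rng.random() < 0.7 else \
                    str(rng.choice([x for x in "ACGT" if x not in (ref, _TRANSITION[ref])]))
                vids.append(variant_id("chrM", int(s), ref, alt))
                hets.append(0.05 + 0.95 * rng.beta(1.0, 15.0))
            rows += _call_rows(rng, cfg, sample, vids, hets, "somatic",
                               depth_mean)
        # NUMT-derived artefacts at sub-0.05 fraction
        n_art = rng.poisson(cfg.numt_artifact_rate)
        if n_art:
            sites = rng.integers(600, 16_000, size=n_art)
            vids, hets = [], []
            for s in sites:
                ref = str(rng.choice(_BASES))
                alt = str(rng.choice([x for x in "ACGT" if x != ref]))
                vids.append(variant_id("chrM", int(s), ref, alt))
                hets.append(float(rng.uniform(0.01, 0.049)))
            rows += _call_rows(rng, cfg, sample, vids, hets, "numt_artifact",
                               depth_mean)
    calls = pd.DataFrame(rows, columns=[
        "sample_id", "contig", "pos", "ref", "alt", "variant_id",
        "heteroplasmy", "depth", "alt_depth", "filters", "origin"])

    truth = pd.DataFrame({
        "parameter": ["mtcn_base", "age_slope_log", "draw_time_amplitude",
                      "seasonal_amplitude", "noise_sd", "blood_age_corr",
                      "transmission_sd", "somatic_rate_per_year"]
                     + [f"blood_slope_{i+1}" for i in range(len(cfg.blood_slopes))],
        "value": [cfg.mtcn_base, cfg.age_slope_log, cfg.draw_time_amplitude,
                  cfg.seasonal_amplitude, cfg.noise_sd, cfg.blood_age_corr,
                  cfg.transmission_sd, cfg.somatic_rate_per_year]
                 + list(cfg.blood_slopes),
    })
    return {"metadata": meta, "calls": calls, "truth": truth}


# --- chrM:302 read simulation -------------------------------------------------

_READ_FLANK5 = "TAAAGTGTGTTAATTAATTAATGCTTGTAGGACATAATAAT"
_READ_FLANK3 = "CGCTTCTGGCCACAGCACTTAAACACATCTCTGCCAAACCCC"


def _allele_sequence(label: str) -> str:
    """Read-space sequence of one length allele, e.g. G6AG8 -> AA C6 T C8 GC."""
    if label.startswith("G") and "AG" in label[1:]:
        t1, t2 = label[1:].split("AG")
        core = "C" * int(t1) + "T" + "C" * int(t2)
    elif label.startswith("C"):
        core = "C" * int(label[1:])
    else:
        raise ValueError(f"unknown allele label {label!r}")
    return _READ_FLANK5 + "AA" + core + "GC" + _READ_FLANK3


def simulate_csb2_reads(mixture: dict[str, float], n_reads: int,
                        error_rate: float = 0.0, seed: int = 0,
                        barcodes: list[str] | None = None,
                        reads_per_cell: int | None = None) -> pd.DataFrame:
    """Reads spanning the chrM:300-318 poly-C locus drawn from an allele
    mixture.

    ``mixture`` maps allele labels (``G6AG8`` style) to fractions summing
    to 1.  Substitution errors are applied uniformly at ``error_rate`` per
    base.  When ``barcodes`` is given reads are assigned round-robin
    (``reads_per_cell`` each) to emulate single cells.
    """
    labels = list(mixture)
    fracs = np.asarray([mixture[k] for k in labels], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9 or (fracs < 0).any():
        raise ValueError("mixture must lie on the simplex")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(labels), size=n_reads, p=fracs)
    rows = []
    for i, k in enumerate(picks):
        seq = _allele_sequence(labels[k])
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            hit = rng.random(arr.size) < error_rate
            if hit.any():
                repl = rng.choice(_BASES, size=int(hit.sum()))
                arr[hit] = repl
                seq = "".join(arr)
        if barcodes is not None:
            cell = barcodes[(i // (reads_per_cell or 1)) % len(barcodes)] \
                if reads_per_cell else barcodes[i % len(barcodes)]
        else:
            cell = "bulk"
        rows.append({"cell_barcode": cell, "read_id": f"r{i:07d}",
                     "sequence": seq})
    return pd.DataFrame(rows)


# --- pedigree transmission ----------------------------------------------------

#: Somatic SNV hotspot sites used in the pedigree model (recurrent, so the
#: five-carrier filter keeps them while carriage stays independent in pairs).
SOMATIC_HOTSPOTS = [variant_id("chrM", p, r, a) for p, r, a in [
    (3243, "A", "G"), (16093, "T", "C"), (189, "A", "G"), (204, "T", "C"),
    (414, "T", "G"), (72, "T", "C"), (1555, "A", "G"), (5178, "C", "A"),
    (10398, "A", "G"), (12705, "C", "T"), (7028, "C", "T"), (14766, "C", "T"),
    (11719, "G", "A"), (8860, "A", "G"), (15326, "A", "G"),
]]

#: Father-lineage indel sites (never transmitted to the index child, whose
#: mtDNA is maternal).
PATERNAL_INDEL_SITES = {
    "chrM:955:A,AC": 0.35,
    "chrM:5899:C,CCCCC": 0.20,
    "chrM:8270:C,CACCCCCTCTA": 0.15,
}


def simulate_pedigree_heteroplasmy(config: SimConfig | None = None
                                   ) -> tuple[PairSet, pd.DataFrame]:
    """Trios and sibling pairs with maternally transmitted indel mixtures.

    Mothers draw founder fractions from Beta(a, b) at inherited indel sites;
    children inherit them with truncated-Gaussian jitter
    (``transmission_sd``).  Fathers carry indels only at father-lineage sites,
    so father-offspring indel sharing is zero by construction.  Somatic SNVs
    arise independently per individual at recurrent hotspot sites.  Returns
    the pair set and a QC'd-style call table (``qc_status`` = "pass").
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    a, b = cfg.maternal_beta
    rows: list[dict] = []
    pairs: list[tuple[str, str, str]] = []

    def add_calls(sample: str, vid: str, het: float) -> None:
        contig, pos, ref, alt = _split_variant(vid)
        rows.append({"sample_id": sample, "contig": contig, "pos": pos,
                     "ref": ref, "alt": alt, "variant_id": vid,
                     "het_post_qc": float(het), "heteroplasmy": float(het),
                     "qc_status": "pass"})

    def somatic(sample: str) -> None:
        for vid in SOMATIC_HOTSPOTS:
            if rng.random() < 0.4:
                add_calls(sample, vid, 0.05 + 0.95 * float(rng.beta(1.0, 15.0)))

    def maternal_founder() -> dict[str, float]:
        return {vid: float(rng.beta(a, b))
                for vid, p in cfg.inherited_sites.items() if rng.random() < p}

    def transmit(founder: dict[str, float]) -> dict[str, float]:
        return {vid: float(_truncnorm01(rng, h, cfg.transmission_sd))
                for vid, h in founder.items()}

    for t in range(cfg.n_trios):
        mother, father, child = f"M{t:04d}", f"F{t:04d}", f"C{t:04d}"
        founder = maternal_founder()
        for vid, h in founder.items():
            add_calls(mother, vid, h)
        for vid, h in transmit(founder).items():
            add_calls(child, vid, h)
        for vid, p in PATERNAL_INDEL_SITES.items():
            if rng.random() < p:
                add_calls(father, vid, float(rng.beta(a, b)))
        for s in (mother, father, child):
            somatic(s)
        pairs.append((mother, child, "mother_offspring"))
        pairs.append((father, child, "father_offspring"))

    for t in range(cfg.n_sib_pairs):
        mother_founder = maternal_founder()
        s1, s2 = f"A{t:04d}", f"B{t:04d}"
        for sib in (s1, s2):
            for vid, h in transmit(mother_founder).items():
                add_calls(sib, vid, h)
            somatic(sib)
        pairs.append((s1, s2, "sibling"))

    calls = pd.DataFrame(rows, columns=["sample_id", "contig", "pos", "ref",
                                        "alt", "variant_id", "het_post_qc",
                                        "heteroplasmy", "qc_status"])
    return PairSet(pairs=pairs), calls


# --- QC fixture ---------------------------------------------------------------

def simulate_qc_cohort(seed: int = 0, n_clean: int = 20) -> dict:
    """A small cohort with planted QC violations and their expected outcomes.

    Planted: one sample at mtCN 45 (below the 50 floor), one at 3%
    contamination, calls at allele fraction 0.03 (removed as NUMT risk) and
    0.005 (recoded to reference), and no-call sites at coverage 80 (missing,
    not confident reference).  ``truth`` tables enumerate the expected
    pass/fail/recode/missing pattern.
    """
    from .qc import SampleQCRecord

    rng = np.random.default_rng(seed)
    records = []
    sample_truth = []
    for i in range(n_clean):
        sid = f"OK{i:03d}"
        records.append(SampleQCRecord(sample_id=sid,
                                      mtcn=float(rng.uniform(60, 200))))
        sample_truth.append({"sample_id": sid, "expect_pass": True,
                             "expect_reasons": ""})
    records.append(SampleQCRecord(sample_id="LOWCN", mtcn=45.0))
    sample_truth.append({"sample_id": "LOWCN", "expect_pass": False,
                         "expect_reasons": "mtcn_below_min"})
    records.append(SampleQCRecord(sample_id="CONTAM", mtcn=120.0,
                                  contamination_mt=0.03))
    sample_truth.append({"sample_id": "CONTAM", "expect_pass": False,
                         "expect_reasons": "contamination"})

    call_rows = [
        {"sample_id": "OK000", "variant_id": "chrM:3243:A,G",
         "heteroplasmy": 0.20, "filters": "", "expect_status": "pass"},
        {"sample_id": "OK001", "variant_id": "chrM:750:A,G",
         "heteroplasmy": 0.97, "filters": "", "expect_status": "pass"},
        {"sample_id": "OK002", "variant_id": "chrM:5000:C,T",
         "heteroplasmy": 0.03, "filters": "", "expect_status": "low_het"},
        {"sample_id": "OK003", "variant_id": "chrM:6000:G,A",
         "heteroplasmy": 0.005, "filters": "",
         "expect_status": "recoded_reference"},
        {"sample_id": "OK004", "variant_id": "chrM:7000:T,C",
         "heteroplasmy": 0.30, "filters": "weak_evidence",
         "expect_status": "caller_flag"},
        {"sample_id": "OK005", "variant_id": "chrM:8000:A,C",
         "heteroplasmy": 0.05, "filters": "", "expect_status": "pass"},
    ]
    calls = pd.DataFrame(call_rows)

    site_rows = [
        {"sample_id": "OK000", "pos": 10000, "coverage": 150,
         "expect_site_status": "hom_ref"},
        {"sample_id": "OK001", "pos": 10000, "coverage": 80,
         "expect_site_status": "missing"},
        {"sample_id": "OK002", "pos": 10000, "coverage": 100,
         "expect_site_status": "hom_ref"},
    ]
    sites = pd.DataFrame(site_rows)
    return {"records": records, "calls": calls, "sites": sites,
            "sample_truth": pd.DataFrame(sample_truth)}


def write_cohort(cohort: dict, outdir) -> None:
    """Write cohort tables as TSV under ``outdir`` (metadata.tsv, calls.tsv,
    truth.tsv)."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort["metadata"].to_csv(out / "metadata.tsv", sep="\t")
    cohort["calls"].to_csv(out / "calls.tsv", sep="\t", index=False)
    cohort["truth"].to_csv(out / "truth.tsv", sep="\t", index=False)
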