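"""Synthetic cohort generator with tracked ground truth.

Emulates the statistical structure of a restricted-access veteran cohort used
to study whether traumatic brain injury (TBI) interacts with polygenic risk
for Alzheimer's disease (AD) on the CSF Abeta42/40 ratio: ~88 male subjects
(49 TBI — 23 mild, 24 moderate/severe, 2 of indeterminate severity — and
39 without TBI), covariates age / education / PTSD symptom severity
(CAPS-IV), an APOE-like large-effect locus with ~25% carriers, imputed-
genotype dosage uncertainty and missingness, and a planted TBI x PRS
interaction on the standardized outcome.

Genotypes come from a block-diagonal first-order autoregressive
latent-Gaussian haplotype model: within an LD block, latent normals follow an
AR(1) correlation ``ld_rho`` and are thresholded at the allele-frequency
quantile, so marginal allele frequencies are exact and between-block SNPs are
independent by construction.

The module also houses two small clinical utilities usable on real data: the
VA/DOD TBI-severity classifier and the immunoassay technical-limit flagger.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import APOE_REGION, GenomicRegion, write_dosages

__all__ = [
    "SnpPanelError",
    "InjuryEvent",
    "SyntheticTruth",
    "CohortDesign",
    "child_seed",
    "simulate_genotype_panel",
    "simulate_summary_stats",
    "true_prs",
    "simulate_cohort_phenotypes",
    "make_paper_like_fixture",
    "classify_tbi_severity",
    "flag_assay_limits",
    "SEVERITY_LEVELS",
]

SEVERITY_LEVELS = ("none", "mild", "moderate_severe", "indeterminate")

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


class SnpPanelError(ValueError):
    """Invalid genotype-panel simulation parameters."""


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific child seed (< 2**31) from a master seed.

    A fixed sha256 derivation, so each pipeline stage is independently
    reproducible from the single configured seed.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Ground truth and design containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted generative parameters, in standardized-outcome units.

    ``causal_betas`` maps SNP id -> true per-allele effect used to build the
    true polygenic score; the ``effect_*`` fields are regression coefficients
    of the outcome model; ``noise_sd`` is the residual standard deviation.
    ``noise_sd=None`` (the default) calibrates the residual SD so the
    generated outcome has unit sample variance — i.e. the planted
    coefficients are already on the standardized-outcome scale the analysis
    re-standardizes to. Defaults mirror the effect sizes of the cohort the
    generator emulates (e.g. a TBI x PRS interaction of -0.45 and an
    APOE-carrier main effect of -1.12 standardized units).
    """

    causal_betas: dict[str, float] = field(default_factory=dict)
    effect_tbi: float = -0.19
    effect_prs: float = -0.12
    effect_interaction: float = -0.45
    effect_caps: float = 0.01
    effect_age: float = 0.01
    effect_edu: float = -0.05
    effect_apoe_carrier: float = -1.12
    noise_sd: float | None = None
    apoe_tag_snp: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 (or None for unit-variance calibration)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition and covariate distributions.

    Group sizes default to the emulated study (39 no-TBI; 49 TBI split
    23 mild / 24 moderate-severe / 2 indeterminate). Covariates are truncated
    normals: means/SDs from the emulated cohort's descriptives, truncation at
    plausible instrument bounds (age 45-90 y, education 8-20 y, CAPS-IV total
    0-136). ``severity_interaction_multipliers`` optionally scales the
    planted TBI x PRS interaction per severity level (dose-response).
    """

    n_no_tbi: int = 39
    n_mild: int = 23
    n_moderate_severe: int = 24
    n_indeterminate: int = 2
    age_mean: float = 68.3
    age_sd: float = 3.60
    age_bounds: tuple[float, float] = (45.0, 90.0)
    education_mean: float = 15.1
    education_sd: float = 2.39
    education_bounds: tuple[float, float] = (8.0, 20.0)
    caps_mean: float = 46.1
    caps_sd: float = 34.8
    caps_bounds: tuple[float, float] = (0.0, 136.0)
    severity_interaction_multipliers: Mapping[str, float] | None = None

    @property
    def n_tbi(self) -> int:
        return self.n_mild + self.n_moderate_severe + self.n_indeterminate

    @property
    def n_subjects(self) -> int:
        return self.n_no_tbi + self.n_tbi


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def simulate_genotype_panel(
    n_subjects: int,
    n_snps: int,
    block_size: int = 40,
    ld_rho: float = 0.6,
    maf_range: tuple[float, float] = (0.05, 0.5),
    apoe_region: GenomicRegion = APOE_REGION,
    seed: int = 0,
    apoe_fraction: float = 0.03,
    dosage_noise_sd: float = 0.08,
    missing_fraction: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an imputed-dosage panel and its SNP metadata.

    Two latent-Gaussian haplotypes per subject are generated per LD block
    with AR(1) correlation ``ld_rho`` and thresholded at the Phi^{-1}(maf)
    quantile, so each SNP's marginal allele frequency equals its drawn
    ``maf_true``. True genotypes (0/1/2) are then blurred with
    Normal(0, dosage_noise_sd^2) noise clipped to [0, 2] and a
    ``missing_fraction`` of cells is set missing, so downstream hard-calling
    has genuine work to do. The last ``apoe_fraction`` of SNPs is placed
    inside ``apoe_region`` (contiguous blocks, chr19); the rest are spread
    over chromosomes 1-22 outside it.

    Returns ``(dosages, panel)``: a subjects x SNPs DataFrame and a metadata
    DataFrame with columns ``snp_id, chrom, pos, ref_allele, alt_allele,
    maf_true``. Identical seed and parameters give identical output.
    """
    if n_subjects < 2 or n_snps < 1:
        raise SnpPanelError("need n_subjects >= 2 and n_snps >= 1")
    if not (0.0 <= ld_rho < 1.0):
        raise SnpPanelError(f"ld_rho must be in [0, 1), got {ld_rho}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise SnpPanelError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if block_size < 1:
        raise SnpPanelError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)

    # SNP placement: the trailing apoe_fraction of SNPs sits inside the region.
    n_apoe = int(round(apoe_fraction * n_snps))
    n_out = n_snps - n_apoe
    chroms = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    chroms[:n_out] = rng.integers(1, 23, size=n_out).astype(str)
    pos[:n_out] = rng.integers(1, 100_000_000, size=n_out)
    # keep non-region chr19 SNPs out of the excluded interval
    on19 = (chroms[:n_out] == "19")
    clash = on19 & (pos[:n_out] >= apoe_region.start) & (pos[:n_out] <= apoe_region.end)
    pos[:n_out][clash] = rng.integers(1, apoe_region.start, size=int(clash.sum()))
    if n_apoe:
        chroms[n_out:] = "19"
        pos[n_out:] = rng.integers(apoe_region.start, apoe_region.end + 1, size=n_apoe)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    # Haplotypes: AR(1) latent Gaussians within blocks, thresholded.
    n_hap = 2 * n_subjects
    z = np.empty((n_hap, n_snps))
    scale = np.sqrt(1.0 - ld_rho**2)
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        e = rng.standard_normal((n_hap, stop - start))
        z[:, start] = e[:, 0]
        for j in range(1, stop - start):
            z[:, start + j] = ld_rho * z[:, start + j - 1] + scale * e[:, j]
    alleles = (z < stats.norm.ppf(mafs)[None, :]).astype(np.int8)
    geno = alleles[0::2] + alleles[1::2]

    dose = geno + rng.normal(0.0, dosage_noise_sd, size=geno.shape)
    dose = np.clip(dose, 0.0, 2.0)
    if missing_fraction > 0:
        dose[rng.random(dose.shape) < missing_fraction] = np.nan

    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    dosages = pd.DataFrame(dose, index=pd.Index(subjects, name="subject_id"), columns=snp_ids)
    panel = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "ref_allele": ref,
            "alt_allele": alt,
            "maf_true": mafs,
        }
    )
    return dosages, panel


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    panel: pd.DataFrame,
    prop_causal: float = 0.10,
    effect_sd: float = 0.05,
    gwas_n: int = 50_000,
    seed: int = 0,
    forced_betas: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate GWAS summary statistics over a SNP panel.

    A ``prop_causal`` fraction of SNPs receives a true effect
    beta ~ Normal(0, effect_sd^2); the rest are null. Estimated effects add
    sampling noise with the standard GWAS standard error
    se = 1 / sqrt(2 * gwas_n * maf * (1 - maf)), and each SNP's p-value is
    the two-sided normal tail of z = beta_hat / se (exactly 1.0 at
    beta_hat = 0). ``forced_betas`` pins chosen SNPs to fixed true effects
    (and marks them causal), e.g. an APOE-like large-effect locus.

    Returns the summary-stat table (columns SNP, CHR, BP, A1, A2, BETA, P;
    A1 = panel alt allele) and a :class:`SyntheticTruth` carrying the causal
    effects (phenotype-model effects keep their defaults).
    """
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    if not (0.0 < prop_causal <= 1.0):
        raise ValueError("prop_causal must be in (0, 1]")
    if gwas_n < 1:
        raise ValueError("gwas_n must be >= 1")

    rng = np.random.default_rng(seed)
    m = len(panel)
    n_causal = max(1, int(round(prop_causal * m)))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    beta_true = np.zeros(m)
    beta_true[causal_idx] = rng.normal(0.0, effect_sd, size=n_causal)

    ids = panel["snp_id"].to_numpy()
    if forced_betas:
        id_pos = {s: i for i, s in enumerate(ids)}
        for sid, b in forced_betas.items():
            beta_true[id_pos[sid]] = b

    maf = panel["maf_true"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * gwas_n * maf * (1.0 - maf))
    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)

    ss = pd.DataFrame(
        {
            "SNP": ids,
            "CHR": panel["chrom"].to_numpy(),
            "BP": panel["pos"].to_numpy(),
            "A1": panel["alt_allele"].to_numpy(),
            "A2": panel["ref_allele"].to_numpy(),
            "BETA": beta_hat,
            "P": p,
        }
    )
    causal = {ids[i]: float(beta_true[i]) for i in np.flatnonzero(beta_true != 0.0)}
    return ss, SyntheticTruth(causal_betas=causal)


def true_prs(dosages: pd.DataFrame, truth: SyntheticTruth) -> pd.Series:
    """Standardized true-beta genotype score (the planted 'PRS_true').

    Missing dosages are filled with the SNP's mean dosage before scoring;
    the score is z-scored (sample SD, n-1 denominator) across subjects.
    """
    snps = [s for s in truth.causal_betas if s in dosages.columns]
    if not snps:
        raise ValueError("no causal SNPs present in the dosage matrix")
    g = dosages[snps].astype(float)
    g = g.fillna(g.mean(axis=0))
    w = np.array([truth.causal_betas[s] for s in snps])
    score = g.to_numpy() @ w
    return pd.Series(
        (score - score.mean()) / score.std(ddof=1), index=dosages.index, name="prs_true"
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort_phenotypes(
    dosages: pd.DataFrame,
    truth: SyntheticTruth,
    design: CohortDesign = CohortDesign(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-subject phenotypes with the planted outcome model.

    The standardized Abeta42/40 outcome is

        y = b_age*(age - mean) + b_edu*(edu - mean) + b_caps*(caps - mean)
            + b_tbi*TBI + b_prs*PRS_true + b_int*m(sev)*TBI*PRS_true
            + b_carrier*carrier + eps,   eps ~ Normal(0, noise_sd^2)

    with PRS_true the standardized true-beta genotype score and m(sev) the
    optional per-severity interaction multiplier. With ``truth.noise_sd``
    left at ``None`` the residual SD is calibrated so Var(y) ~= 1 (see
    :class:`SyntheticTruth`). Raw analytes are generated
    ratio-first: Abeta40 ~ log-normal clamped inside its (11, 43000) pg/mL
    technical range, the raw ratio is an affine map of y, and
    Abeta42 = ratio * Abeta40. APOE e4-like allele count is the rounded
    dosage at ``truth.apoe_tag_snp`` (all zeros when no tag is set).

    Returns a DataFrame with columns ``subject_id, age, education_yrs,
    caps_total, tbi, tbi_severity, apoe_e4_count, abeta42_pg_ml,
    abeta40_pg_ml``.
    """
    n = len(dosages)
    if design.n_subjects != n:
        raise ValueError(
            f"design group sizes sum to {design.n_subjects} but dosage matrix has {n} rows"
        )
    rng = np.random.default_rng(seed)

    labels = (
        ["none"] * design.n_no_tbi
        + ["mild"] * design.n_mild
        + ["moderate_severe"] * design.n_moderate_severe
        + ["indeterminate"] * design.n_indeterminate
    )
    severity = np.array(labels, dtype=object)[rng.permutation(n)]
    tbi = (severity != "none").astype(int)

    age = _trunc_normal(rng, design.age_mean, design.age_sd, design.age_bounds, n)
    edu = _trunc_normal(rng, design.education_mean, design.education_sd, design.education_bounds, n)
    caps = _trunc_normal(rng, design.caps_mean, design.caps_sd, design.caps_bounds, n)

    prs = true_prs(dosages, truth).to_numpy()

    if truth.apoe_tag_snp is not None and truth.apoe_tag_snp in dosages.columns:
        tag = dosages[truth.apoe_tag_snp].astype(float)
        tag = tag.fillna(tag.mean())
        e4 = np.clip(np.floor(tag.to_numpy() + 0.5), 0, 2).astype(int)
    else:
        e4 = np.zeros(n, dtype=int)
    carrier = (e4 >= 1).astype(float)

    mult = np.ones(n)
    if design.severity_interaction_multipliers:
        for lev, m_ in design.severity_interaction_multipliers.items():
            mult[severity == lev] = m_

    systematic = (
        truth.effect_age * (age - design.age_mean)
        + truth.effect_edu * (edu - design.education_mean)
        + truth.effect_caps * (caps - design.caps_mean)
        + truth.effect_tbi * tbi
        + truth.effect_prs * prs
        + truth.effect_interaction * mult * tbi * prs
        + truth.effect_apoe_carrier * carrier
    )
    if truth.noise_sd is None:
        # residual variance calibrated so Var(y) ~= 1: the planted effects
        # then live on the standardized-outcome scale the analysis uses
        resid_sd = np.sqrt(max(1.0 - systematic.var(ddof=1), 0.04))
    else:
        resid_sd = truth.noise_sd
    y = systematic + rng.normal(0.0, resid_sd, size=n)

    ab40 = np.exp(rng.normal(np.log(15_000.0), 0.18, size=n))
    ab40 = np.clip(ab40, 12.0, 42_000.0)
    ratio = np.maximum(0.09 + 0.015 * y, 0.005)
    ab42 = ratio * ab40

    return pd.DataFrame(
        {
            "subject_id": dosages.index.to_numpy(),
            "age": age,
            "education_yrs": edu,
            "caps_total": caps,
            "tbi": tbi,
            "tbi_severity": severity,
            "apoe_e4_count": e4,
            "abeta42_pg_ml": ab42,
            "abeta40_pg_ml": ab40,
        }
    )


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------

def make_paper_like_fixture(
    seed: int,
    out_dir: str | Path,
    n_snps: int = 2400,
    design: CohortDesign | None = None,
) -> dict[str, Path]:
    """Write a complete study-shaped synthetic data set to ``out_dir``.

    Produces an 88-subject cohort (49 TBI: 23 mild / 24 moderate-severe /
    2 indeterminate; 39 no-TBI) with a ~2,400-SNP panel, GWAS summary
    statistics whose weight mass concentrates below p < 0.05, an APOE-like
    large-effect tag SNP (~25% carriers, carrier effect -1.12), and a planted
    TBI x PRS interaction of -0.45 with a mild-vs-moderate/severe
    dose-response (multipliers 0.6 / 1.4, population-weighted mean ~1).

    Files written (all plain text): ``sumstats.tsv``, ``panel.tsv``,
    ``dosages.tsv``, ``phenotypes.csv``, ``truth.json``. Deterministic given
    ``seed``; returns the path of each file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or CohortDesign(
        severity_interaction_multipliers={"mild": 0.6, "moderate_severe": 1.4}
    )

    dosages, panel = simulate_genotype_panel(
        n_subjects=design.n_subjects,
        n_snps=n_snps,
        block_size=40,
        ld_rho=0.7,
        maf_range=(0.05, 0.5),
        seed=child_seed(seed, "panel"),
        apoe_fraction=0.03,
        dosage_noise_sd=0.08,
        missing_fraction=0.01,
    )

    # APOE-like tag: region SNP with true MAF nearest 0.134, so the carrier
    # fraction 1 - (1 - maf)^2 lands near 25%; forced large GWAS effect.
    in_region = panel["chrom"].eq("19") & panel["pos"].between(
        APOE_REGION.start, APOE_REGION.end
    )
    region_panel = panel[in_region]
    if region_panel.empty:
        raise ValueError("fixture panel has no SNPs in the APOE-like region")
    tag = region_panel.iloc[(region_panel["maf_true"] - 0.134).abs().argmin()]["snp_id"]

    ss, truth = simulate_summary_stats(
        panel,
        prop_causal=0.10,
        effect_sd=0.05,
        gwas_n=50_000,
        seed=child_seed(seed, "sumstats"),
        forced_betas={tag: 0.4},
    )
    truth.apoe_tag_snp = str(tag)

    pheno = simulate_cohort_phenotypes(
        dosages, truth, design, seed=child_seed(seed, "phenotypes")
    )

    paths = {
        "sumstats": out / "sumstats.tsv",
        "panel": out / "panel.tsv",
        "dosages": out / "dosages.tsv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    ss.to_csv(paths["sumstats"], sep="\t", index=False, float_format="%.6e")
    panel.to_csv(paths["panel"], sep="\t", index=False, float_format="%.6f")
    write_dosages(dosages, paths["dosages"])
    pheno.to_csv(paths["phenotypes"], index=False, float_format="%.6f")
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Clinical utilities (usable on real data)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjuryEvent:
    """Durations characterising a single head injury; ``None`` = unknown.

    ``loc_minutes``: loss of consciousness; ``pta_hours``: post-traumatic
    amnesia; ``ams_hours``: altered mental state.
    """

    loc_minutes: float | None = None
    pta_hours: float | None = None
    ams_hours: float | None = None

    def __post_init__(self) -> None:
        for name in ("loc_minutes", "pta_hours", "ams_hours"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be >= 0 or None, got {v}")


def classify_tbi_severity(event: InjuryEvent) -> str:
    """Classify a head injury per VA/DOD criteria.

    ``moderate_severe`` iff loss of consciousness >= 30 min, post-traumatic
    amnesia > 24 h, or altered mental state > 24 h; otherwise ``mild``.
    When multiple criteria disagree, the higher severity wins; unknown
    (``None``) fields are skipped rather than treated as zero. If every
    field is unknown the injury is ``indeterminate`` — distinct from mild,
    mirroring subjects excluded from severity analyses for discrepant
    interview records.
    """
    known = [
        v for v in (event.loc_minutes, event.pta_hours, event.ams_hours) if v is not None
    ]
    if not known:
        return "indeterminate"
    if (
        (event.loc_minutes is not None and event.loc_minutes >= 30)
        or (event.pta_hours is not None and event.pta_hours > 24)
        or (event.ams_hours is not None and event.ams_hours > 24)
    ):
        return "moderate_severe"
    return "mild"


def flag_assay_limits(abeta42: float, abeta40: float) -> frozenset[str]:
    """Flag CSF analyte values outside the immunoassay's technical limits.

    Abeta1-42: reliable range 200-1700 pg/mL (values above 1700 were
    extrapolated off the calibration curve in the assay this mirrors, hence
    only flagged here). Abeta1-40: technical limits 11-43,000 pg/mL.
    Returns a (possibly empty) set drawn from ``{"ab42_above_1700",
    "ab42_below_200", "ab40_outside_11_43000"}``.
    """
    for name, v in (("abeta42", abeta42), ("abeta40", abeta40)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v}")
    flags = set()
    if abeta42 > 1700:
        flags.add("ab42_above_1700")
    if abeta42 < 200:
        flags.add("ab42_below_200")
    if not (11 <= abeta40 <= 43_000):
        flags.add("ab40_outside_11_43000")
    return frozenset(flags)
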