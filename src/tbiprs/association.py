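"""Regression and group-comparison analyses on the merged cohort table.

Implements the hierarchical ordinary-least-squares models used to test a
TBI x polygenic-risk interaction on standardized CSF Abeta42/40:

* model 1: outcome ~ age + education + CAPS (covariates only)
* model 2: model 1 + TBI + PRS (main effects)
* model 3: model 2 + TBI:PRS (interaction)

plus Welch t-tests and Fisher's exact test for group descriptives,
stratified within-group PRS slopes with the equivalent partial correlation,
a TBI-severity x PRS ANCOVA (omnibus 2-df interaction F), and the APOE
follow-up models (APOE-region-excluded PRS interaction; e4 carrier main
effect and interaction). Outcome and PRS are standardized (M = 0, SD = 1)
over the analysis sample; models are complete-case; p-values are two-sided;
95% CIs use the t distribution on residual df.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .synthetic_cohort import flag_assay_limits

__all__ = [
    "RegressionFit",
    "WelchResult",
    "FisherResult",
    "StratifiedEffect",
    "AncovaResult",
    "read_phenotypes",
    "compute_ratio_and_standardize",
    "fit_hierarchical_models",
    "group_comparisons",
    "stratified_prs_effect",
    "severity_ancova",
    "apoe_models",
    "descriptives",
    "partial_f",
    "write_results",
]

PHENOTYPE_COLUMNS = (
    "subject_id",
    "age",
    "education_yrs",
    "caps_total",
    "tbi",
    "tbi_severity",
    "apoe_e4_count",
    "abeta42_pg_ml",
    "abeta40_pg_ml",
)


@dataclass
class RegressionFit:
    """An OLS fit: per-term B, SE, two-sided p and 95% CI, plus model-level
    R^2 and overall F."""

    label: str
    coefficients: pd.DataFrame  # index: term; columns B, SE, p, ci_low, ci_high
    r_squared: float
    f_stat: float
    f_df: tuple[float, float]
    f_pvalue: float
    n_used: int

    def term(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_no_tbi: float
    mean_tbi: float
    sd_no_tbi: float
    sd_tbi: float


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows (no-TBI, TBI) x (non-carrier, carrier)
    odds_ratio: float  # cross-product ad/bc
    odds_ratio_cmle: float  # conditional maximum likelihood
    p: float  # Fisher exact, two-sided
    n_used: int


@dataclass(frozen=True)
class StratifiedEffect:
    B: float
    se: float
    p: float
    partial_r: float
    n: int


@dataclass(frozen=True)
class AncovaResult:
    interaction_f: float
    interaction_df: tuple[int, int]
    p: float
    cell_slopes: dict[str, float]  # PRS slope per severity level
    n_used: int


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate CSV and validate its columns."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype column(s) {missing}")
    bad = df["tbi"].eq(0) & ~df["tbi_severity"].eq("none")
    if bad.any():
        raise ValueError(
            f"{path}: tbi=0 rows must have severity 'none' "
            f"(subjects {df.loc[bad, 'subject_id'].tolist()[:5]})"
        )
    return df


def compute_ratio_and_standardize(t: pd.DataFrame) -> pd.DataFrame:
    """Attach the Abeta42/40 ratio, its z-score, and assay-limit flags.

    ratio = abeta42 / abeta40 per subject; ``abeta_ratio_std`` is the ratio
    z-scored (sample SD) over the rows of ``t``, i.e. over the subjects
    entering analysis. ``assay_flags`` holds semicolon-joined technical-limit
    flags (empty string when all analytes are in range).
    """
    out = t.copy()
    ab42 = out["abeta42_pg_ml"].to_numpy(dtype=float)
    ab40 = out["abeta40_pg_ml"].to_numpy(dtype=float)
    if (ab40 <= 0).any() or (ab42 <= 0).any():
        raise ValueError("CSF analyte concentrations must be positive")
    ratio = ab42 / ab40
    out["abeta_ratio"] = ratio
    out["abeta_ratio_std"] = (ratio - ratio.mean()) / ratio.std(ddof=1)
    out["assay_flags"] = [
        ";".join(sorted(flag_assay_limits(a, b))) for a, b in zip(ab42, ab40)
    ]
    return out


def _frame(t: pd.DataFrame, prs_std) -> pd.DataFrame:
    """Merge the analysis variables into one complete-case-ready frame."""
    if "abeta_ratio_std" not in t.columns:
        raise ValueError("run compute_ratio_and_standardize first (abeta_ratio_std missing)")
    df = pd.DataFrame(
        {
            "y": t["abeta_ratio_std"].to_numpy(dtype=float),
            "age": t["age"].to_numpy(dtype=float),
            "education": t["education_yrs"].to_numpy(dtype=float),
            "caps": t["caps_total"].to_numpy(dtype=float),
            "tbi": t["tbi"].to_numpy(dtype=float),
        },
        index=t.index,
    )
    if prs_std is not None:
        df["prs"] = np.asarray(prs_std, dtype=float)
    if "tbi_severity" in t.columns:
        df["severity"] = t["tbi_severity"].to_numpy(dtype=object)
    if "apoe_e4_count" in t.columns:
        e4 = pd.to_numeric(t["apoe_e4_count"], errors="coerce")
        df["carrier"] = (e4 >= 1).astype(float).where(e4.notna())
    return df


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns via the QR diagonal
        _, rr = np.linalg.qr(X)
        diag = np.abs(np.diag(rr))
        aliased = [names[j] for j in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise ValueError(f"collinear design: aliased term(s) {aliased or names}")


def _ols(y: np.ndarray, X: pd.DataFrame, label: str) -> RegressionFit:
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"{label}: n = {n} too small for {k} design columns")
    _check_full_rank(X.to_numpy(), list(X.columns))
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "B": res.params,
            "SE": res.bse,
            "p": res.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    return RegressionFit(
        label=label,
        coefficients=coef,
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        f_df=(float(res.df_model), float(res.df_resid)),
        f_pvalue=float(res.f_pvalue),
        n_used=int(res.nobs),
    )


def _design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = df[a] * df[b]
        else:
            X[term] = df[term]
    return X


# ---------------------------------------------------------------------------
# Hierarchical models
# ---------------------------------------------------------------------------

MODEL_TERMS = {
    "model1": ["age", "education", "caps"],
    "model2": ["age", "education", "caps", "tbi", "prs"],
    "model3": ["age", "education", "caps", "tbi", "prs", "tbi:prs"],
}


def fit_hierarchical_models(t: pd.DataFrame, prs_std) -> dict[str, RegressionFit]:
    """Fit the three nested models on the same complete cases.

    model 1 adjusts for age, education and CAPS severity only; model 2 adds
    the TBI and PRS main effects (the main effects reported); model 3 adds
    the TBI x PRS product (the interaction reported). All three use the rows
    complete on every model-3 term, so n is constant across models.
    """
    df = _frame(t, prs_std)
    df = df.dropna(subset=["y", "age", "education", "caps", "tbi", "prs"])
    y = df["y"].to_numpy()
    return {
        label: _ols(y, _design(df, terms), label) for label, terms in MODEL_TERMS.items()
    }


def partial_f(reduced: RegressionFit, full: RegressionFit) -> tuple[float, float]:
    """Partial F for nested OLS fits from their R^2 increments.

    F = ((R2_full - R2_red) / q) / ((1 - R2_full) / df_resid_full), with q
    the number of added terms; returns (F, p).
    """
    q = len(full.coefficients) - len(reduced.coefficients)
    df2 = full.f_df[1]
    num = (full.r_squared - reduced.r_squared) / q
    den = (1.0 - full.r_squared) / df2
    F = num / den
    return float(F), float(stats.f.sf(F, q, df2))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _welch(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch two-sample t (no-TBI minus TBI) with Welch-Satterthwaite df."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    tstat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return WelchResult(
        t=float(tstat), df=float(df), p=float(p),
        mean_no_tbi=float(a.mean()), mean_tbi=float(b.mean()),
        sd_no_tbi=float(a.std(ddof=1)), sd_tbi=float(b.std(ddof=1)),
    )


def group_comparisons(t: pd.DataFrame, prs_std=None) -> dict[str, WelchResult | FisherResult]:
    """Compare TBI vs no-TBI groups on demographics and outcome.

    Continuous variables (age, education, CAPS, standardized outcome, and
    PRS when supplied) use Welch's unequal-variance t-test; APOE e4 carrier
    status (0 vs >= 1 alleles) uses Fisher's exact test, reporting both the
    cross-product odds ratio ad/bc and the conditional-MLE OR. Subjects with
    missing e4 count are dropped from the Fisher test only.
    """
    df = _frame(t, prs_std)
    no = df["tbi"] == 0
    results: dict[str, WelchResult | FisherResult] = {}
    cont = {"age": "age", "education": "education", "caps": "caps", "abeta_ratio_std": "y"}
    if prs_std is not None:
        cont["prs"] = "prs"
    for name, col in cont.items():
        results[name] = _welch(df.loc[no, col].to_numpy(), df.loc[~no, col].to_numpy())

    if "carrier" in df.columns:
        sub = df.dropna(subset=["carrier"])
        a = int(((sub["tbi"] == 0) & (sub["carrier"] == 0)).sum())  # no-TBI non-carrier
        b = int(((sub["tbi"] == 0) & (sub["carrier"] == 1)).sum())
        c = int(((sub["tbi"] == 1) & (sub["carrier"] == 0)).sum())
        d = int(((sub["tbi"] == 1) & (sub["carrier"] == 1)).sum())
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            or_cross = or_cmle = float("nan")
            p = 1.0
        else:
            or_cross = (a * d) / (b * c) if b * c > 0 else float("inf")
            or_cmle = float(stats.contingency.odds_ratio(table).statistic)
            p = float(stats.fisher_exact(table)[1])
        results["apoe_carrier"] = FisherResult(
            table=((a, b), (c, d)),
            odds_ratio=float(or_cross),
            odds_ratio_cmle=or_cmle,
            p=p,
            n_used=int(table.sum()),
        )
    return results


# ---------------------------------------------------------------------------
# Follow-up analyses
# ---------------------------------------------------------------------------

def stratified_prs_effect(t: pd.DataFrame, prs_std, group: bool | int) -> StratifiedEffect:
    """Covariate-adjusted PRS slope within one TBI stratum.

    OLS of the standardized outcome on standardized PRS + age + education +
    CAPS within the stratum; returns the PRS coefficient, its two-sided p,
    and the equivalent partial correlation r = sign(B) * sqrt(t^2/(t^2+df)).
    """
    df = _frame(t, prs_std)
    df = df[df["tbi"] == int(bool(group))].dropna(subset=["y", "age", "education", "caps", "prs"])
    k = 5  # intercept + prs + 3 covariates
    if len(df) < k + 2:
        raise ValueError(f"stratum too small (n = {len(df)}) for covariate adjustment")
    fit = _ols(df["y"].to_numpy(), _design(df, ["prs", "age", "education", "caps"]), "stratum")
    B = float(fit.term("prs")["B"])
    se = float(fit.term("prs")["SE"])
    tt = B / se
    dfr = fit.f_df[1]
    partial_r = float(np.sign(B) * np.sqrt(tt**2 / (tt**2 + dfr)))
    return StratifiedEffect(B=B, se=se, p=float(fit.term("prs")["p"]), partial_r=partial_r, n=fit.n_used)


def severity_ancova(t: pd.DataFrame, prs_std) -> AncovaResult:
    """TBI-severity x PRS ANCOVA with indeterminate-severity rows excluded.

    Severity is treatment-coded with 'none' as reference; the interaction is
    the 2-df block of severity x PRS products, tested with a partial F
    against the main-effects model. Per-level PRS slopes (reference slope
    plus the level's interaction coefficient) are returned for plotting.
    """
    df = _frame(t, prs_std)
    df = df[df["severity"] != "indeterminate"].dropna(
        subset=["y", "age", "education", "caps", "prs"]
    )
    levels = ["none", "mild", "moderate_severe"]
    counts = df["severity"].value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"empty severity level(s): {empty}")

    for lv in levels[1:]:
        df[f"sev_{lv}"] = (df["severity"] == lv).astype(float)
    base_terms = ["age", "education", "caps", "sev_mild", "sev_moderate_severe", "prs"]
    int_terms = ["sev_mild:prs", "sev_moderate_severe:prs"]
    y = df["y"].to_numpy()
    red = _ols(y, _design(df, base_terms), "ancova_main")
    full = _ols(y, _design(df, base_terms + int_terms), "ancova_interaction")
    F, p = partial_f(red, full)
    slope_none = float(full.term("prs")["B"])
    slopes = {
        "none": slope_none,
        "mild": slope_none + float(full.term("sev_mild:prs")["B"]),
        "moderate_severe": slope_none + float(full.term("sev_moderate_severe:prs")["B"]),
    }
    return AncovaResult(
        interaction_f=F,
        interaction_df=(2, int(full.f_df[1])),
        p=p,
        cell_slopes=slopes,
        n_used=full.n_used,
    )


def apoe_models(t: pd.DataFrame, prs_noapoe_std) -> dict[str, RegressionFit]:
    """Follow-up models isolating the APOE contribution.

    ``prs_no_apoe``: covariates + TBI + APOE-region-excluded PRS + TBI:PRS —
    tests whether the interaction survives removing APOE-region variants.
    ``e4_carrier``: covariates + TBI + carrier (0 vs >= 1 e4 alleles) +
    TBI:carrier, on subjects with known e4 count.
    """
    df = _frame(t, prs_noapoe_std)
    out: dict[str, RegressionFit] = {}

    d1 = df.dropna(subset=["y", "age", "education", "caps", "tbi", "prs"])
    out["prs_no_apoe"] = _ols(
        d1["y"].to_numpy(),
        _design(d1, ["age", "education", "caps", "tbi", "prs", "tbi:prs"]),
        "prs_no_apoe",
    )
    d2 = df.dropna(subset=["y", "age", "education", "caps", "tbi", "carrier"])
    out["e4_carrier"] = _ols(
        d2["y"].to_numpy(),
        _design(d2, ["age", "education", "caps", "tbi", "carrier", "tbi:carrier"]),
        "e4_carrier",
    )
    return out


# ---------------------------------------------------------------------------
# Descriptives and output
# ---------------------------------------------------------------------------

def descriptives(t: pd.DataFrame, prs_std=None) -> pd.DataFrame:
    """Demographics table: mean (SD) overall and by TBI group, plus carrier
    counts and percentages (percentages rounded to whole percent)."""
    df = _frame(t, prs_std)
    groups = {"total": df, "no_tbi": df[df["tbi"] == 0], "tbi": df[df["tbi"] == 1]}
    rows = []
    cont = [("age", "age"), ("education", "education"), ("caps", "caps"), ("abeta_ratio_std", "y")]
    if prs_std is not None:
        cont.insert(3, ("prs", "prs"))
    for name, col in cont:
        rows.append(
            {"variable": name, **{g: f"{sub[col].mean():.2f} ({sub[col].std(ddof=1):.2f})" for g, sub in groups.items()}}
        )
    if "carrier" in df.columns:
        for level, lab in ((0.0, "e4_noncarrier"), (1.0, "e4_carrier")):
            row = {"variable": lab}
            for g, sub in groups.items():
                known = sub.dropna(subset=["carrier"])
                n = int((known["carrier"] == level).sum())
                pct = round(100.0 * n / len(known)) if len(known) else float("nan")
                row[g] = f"{n} ({pct:.0f}%)"
            rows.append(row)
    counts = {"variable": "n", **{g: str(len(sub)) for g, sub in groups.items()}}
    return pd.DataFrame([counts] + rows)


def write_results(fits: dict[str, RegressionFit], path: str | Path) -> None:
    """Tidy per-term results TSV across a set of fitted models."""
    rows = []
    for label, fit in fits.items():
        for term, row in fit.coefficients.iterrows():
            rows.append(
                {
                    "model": label, "term": term, "B": row["B"], "SE": row["SE"],
                    "p": row["p"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "r_squared": fit.r_squared, "model_f": fit.f_stat, "n": fit.n_used,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
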