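"""Polygenic risk score construction across GWAS p-value thresholds.

A score at threshold t is the weighted sum of hard-called allele counts over
all SNPs with GWAS p strictly below t ("SNPs under the threshold"):
``score_i = sum_j beta_j * g_ij``. Scores are built at six nested thresholds
(0.05, 0.10, 0.20, 0.30, 0.40, 0.50 by default), with or without the APOE
region, and standardized (mean 0, SD 1, sample SD with n-1 denominator)
within the analysis sample.

Missing hard calls are mean-imputed by default (replaced by twice the SNP's
counted-allele frequency, the expected dosage — equal to 2*MAF whenever the
counted allele is the minor one), or omitted from the sum. An optional
greedy LD-clumping pass (keep the lowest-p SNP, drop neighbours above an r^2
cutoff within a window) is provided for parity with scoring tools, but is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenomicRegion, exclude_region

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ClumpParams",
    "PrsConfig",
    "PrsMatrix",
    "select_by_threshold",
    "compute_prs",
    "score_all_thresholds",
    "prs_threshold_correlations",
    "standardize",
    "threshold_column",
    "write_prs_matrix",
    "read_prs_matrix",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


def threshold_column(t: float, standardized: bool = False) -> str:
    base = f"prs_p{t:g}"
    return f"{base}_std" if standardized else base


@dataclass(frozen=True)
class ClumpParams:
    """Greedy LD-clumping parameters: drop SNPs with r^2 > ``r2`` within
    ``window_kb`` of a lower-p retained SNP on the same chromosome."""

    r2: float = 0.1
    window_kb: float = 250.0


@dataclass(frozen=True)
class PrsConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    missing_policy: str = "mean_impute"  # or "omit"
    aggregate: str = "sum"  # or "average"
    clumping: ClumpParams | None = None

    def __post_init__(self) -> None:
        ts = tuple(self.thresholds)
        if not ts or any(not (0 < t <= 1) for t in ts) or list(ts) != sorted(set(ts)):
            raise ValueError(
                f"thresholds must be strictly increasing and in (0, 1], got {ts}"
            )
        if self.missing_policy not in {"mean_impute", "omit"}:
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.aggregate not in {"sum", "average"}:
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        object.__setattr__(self, "thresholds", ts)


@dataclass
class PrsMatrix:
    """Per-subject scores at each p-value threshold, raw and standardized.

    ``raw`` and ``standardized`` are subjects x thresholds DataFrames (raw
    columns ``prs_p0.05`` ..., standardized ``prs_p0.05_std`` ...);
    ``snp_counts`` maps threshold -> number of contributing SNPs (non-
    decreasing in the threshold); ``snp_sets`` records the contributing ids.
    """

    subjects: pd.Index
    thresholds: tuple[float, ...]
    raw: pd.DataFrame
    standardized: pd.DataFrame
    snp_counts: dict[float, int]
    apoe_excluded: bool = False
    snp_sets: dict[float, list[str]] = field(default_factory=dict)

    def std_values(self) -> np.ndarray:
        return self.standardized.to_numpy(dtype=float)


def standardize(x: pd.Series | np.ndarray) -> np.ndarray:
    """Z-score with the sample SD (n-1 denominator)."""
    a = np.asarray(x, dtype=float)
    sd = a.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant column")
    return (a - a.mean()) / sd


def select_by_threshold(weights: pd.DataFrame, t: float) -> list[str]:
    """SNP ids with GWAS p strictly under the cutoff (p < t)."""
    if not (0 < t <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    return weights.loc[weights["gwas_p"] < t, "snp_id"].tolist()


def compute_prs(
    h: pd.DataFrame,
    weights: pd.DataFrame,
    snp_set: Iterable[str],
    policy: str = "mean_impute",
    aggregate: str = "sum",
) -> pd.Series:
    """Weighted allele-count score over ``snp_set``.

    ``h`` is the hard-call matrix (0/1/2/NaN); ``weights`` carries aligned
    per-alt-allele betas (columns ``snp_id``, ``beta``). With
    ``policy="mean_impute"`` a missing call contributes ``2*f_j*beta_j``
    where f_j is the SNP's counted-allele frequency in the sample; with
    ``"omit"`` the term is dropped. ``aggregate="average"`` divides each
    subject's sum by twice the number of contributing SNPs.
    """
    snps = list(snp_set)
    if not snps:
        raise ValueError("empty SNP set yields a degenerate score")
    missing_w = [s for s in snps if s not in h.columns]
    if missing_w:
        raise KeyError(f"SNPs absent from hard-call matrix: {missing_w[:5]}")
    w = weights.set_index("snp_id")["beta"].reindex(snps)
    if w.isna().any():
        raise KeyError(f"SNPs without aligned weights: {w.index[w.isna()].tolist()[:5]}")

    g = h[snps].to_numpy(dtype=float)
    wv = w.to_numpy()
    miss = ~np.isfinite(g)
    if policy == "mean_impute":
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nanmean(g, axis=0) / 2.0
        f = np.where(np.isfinite(f), f, 0.0)
        gg = np.where(miss, 2.0 * f[None, :], g)
        score = gg @ wv
        n_contrib = np.full(len(h), len(snps))
    elif policy == "omit":
        gg = np.where(miss, 0.0, g)
        score = gg @ wv
        n_contrib = (~miss).sum(axis=1)
    else:
        raise ValueError(f"unknown missing policy {policy!r}")

    if aggregate == "average":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(n_contrib > 0, score / (2.0 * n_contrib), np.nan)
    elif aggregate != "sum":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return pd.Series(score, index=h.index, name="prs")


def _clump(weights: pd.DataFrame, h: pd.DataFrame, params: ClumpParams) -> pd.DataFrame:
    """Greedy clumping: iterate SNPs by ascending GWAS p; keep a SNP unless a
    kept same-chromosome SNP within the window correlates above sqrt(r2)."""
    w = weights.sort_values("gwas_p", kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    corr_cache = h[w["snp_id"]].astype(float)
    r_cut = np.sqrt(params.r2)
    win = params.window_kb * 1000.0
    for i in range(len(w)):
        ok = True
        for k in kept:
            if w.at[i, "chrom"] == w.at[k, "chrom"] and abs(w.at[i, "pos"] - w.at[k, "pos"]) <= win:
                r = corr_cache.iloc[:, i].corr(corr_cache.iloc[:, k])
                if np.isfinite(r) and abs(r) > r_cut:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return w.iloc[kept].sort_index().reset_index(drop=True)


def score_all_thresholds(
    h: pd.DataFrame,
    weights: pd.DataFrame,
    cfg: PrsConfig = PrsConfig(),
    exclude: GenomicRegion | None = None,
) -> PrsMatrix:
    """Score every configured threshold, optionally excising a region first.

    Region exclusion (e.g. the APOE locus) is applied to the weight table
    before threshold selection; clumping (if configured) likewise precedes
    selection, so every threshold draws from the same clumped pool. Raises
    if any threshold selects no SNPs, naming the threshold.
    """
    w = weights
    if exclude is not None:
        pan = w.rename(columns={})[["snp_id", "chrom", "pos"]]
        retained, _ = exclude_region(pan, exclude)
        w = w[w["snp_id"].isin(retained)]
        if w.empty:
            raise ValueError("region exclusion removed every weighted SNP")
    if cfg.clumping is not None:
        w = _clump(w, h, cfg.clumping)

    raw = {}
    counts: dict[float, int] = {}
    sets: dict[float, list[str]] = {}
    for t in cfg.thresholds:
        snps = select_by_threshold(w, t)
        if not snps:
            raise ValueError(f"no SNPs selected at threshold p < {t:g}")
        raw[threshold_column(t)] = compute_prs(
            h, w, snps, policy=cfg.missing_policy, aggregate=cfg.aggregate
        )
        counts[t] = len(snps)
        sets[t] = snps
    raw_df = pd.DataFrame(raw, index=h.index)
    std_df = pd.DataFrame(
        {threshold_column(t, True): standardize(raw_df[threshold_column(t)]) for t in cfg.thresholds},
        index=h.index,
    )
    return PrsMatrix(
        subjects=h.index,
        thresholds=cfg.thresholds,
        raw=raw_df,
        standardized=std_df,
        snp_counts=counts,
        apoe_excluded=exclude is not None,
        snp_sets=sets,
    )


def prs_threshold_correlations(m: PrsMatrix) -> pd.DataFrame:
    """Pearson correlation matrix of the raw threshold scores.

    Symmetric with unit diagonal; a constant column produces NaNs and a
    warning (undefined correlation).
    """
    if len(m.subjects) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    sds = m.raw.std(ddof=1)
    if (sds == 0).any():
        import warnings

        warnings.warn(
            f"constant PRS column(s) {list(sds.index[sds == 0])}: correlation undefined",
            stacklevel=2,
        )
    return m.raw.corr()


def write_prs_matrix(m: PrsMatrix, path: str | Path) -> None:
    out = pd.concat([m.raw, m.standardized], axis=1)
    out.insert(0, "apoe_excluded", int(m.apoe_excluded))
    out.to_csv(path, sep="\t", float_format="%.10g", index_label="subject_id")


def read_prs_matrix(path: str | Path, thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> PrsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ts = tuple(thresholds)
    raw = df[[threshold_column(t) for t in ts]]
    std = df[[threshold_column(t, True) for t in ts]]
    return PrsMatrix(
        subjects=df.index,
        thresholds=ts,
        raw=raw,
        standardized=std,
        snp_counts={},
        apoe_excluded=bool(df["apoe_excluded"].iloc[0]) if "apoe_excluded" in df else False,
    )
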