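"""Genotype ingestion, hard-calling, and SNP-level quality control.

This module turns imputed genotype dosages (VCF ``DS``/``GP`` fields or a
plain subjects-by-SNPs TSV) into integer hard calls, computes per-SNP minor
allele frequency and missingness on the analysis sample, harmonizes GWAS
summary-statistic effect alleles against the genotype panel, and applies the
region exclusion used to build APOE-free polygenic scores.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention), GRCh37/hg19.
* Dosages live in [0, 2] (expected count of the alt allele); missing values
  are ``NaN`` in memory and ``NA`` on disk.
* QC filters use strict inequalities exactly as printed in the protocol they
  implement: a SNP is excluded when MAF < 0.01 or missing rate > 0.05, so a
  missing rate of exactly 0.05 passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "APOE_REGION",
    "SUMMARY_STAT_COLUMNS",
    "read_summary_stats",
    "read_dosages",
    "write_dosages",
    "hard_call",
    "compute_snp_qc",
    "write_snp_qc",
    "harmonize_alleles",
    "exclude_region",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Required columns of a GWAS summary-statistics file. A1 is the effect allele.
SUMMARY_STAT_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P")


@dataclass(frozen=True)
class GenomicRegion:
    """A closed genomic interval, 1-based inclusive, on a named build."""

    chrom: str
    start: int
    end: int
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == _norm_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )


#: The extended APOE linkage-disequilibrium region excised when computing
#: APOE-free polygenic scores (chr19, GRCh37).
APOE_REGION = GenomicRegion(chrom="19", start=44_409_039, end=46_412_650)


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated GWAS summary-statistics file.

    Expected columns: SNP, CHR, BP, A1 (effect allele), A2, BETA, P.
    Malformed rows are reported with 1-based file line numbers (the header
    is line 1). Returns a DataFrame with one row per SNP.

    Raises
    ------
    ValueError
        On a missing column, a p-value outside (0, 1], a non-ACGT allele,
        or a duplicated SNP id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing_cols = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing required summary-stat column(s) {missing_cols}"
        )
    lines = df.index.to_numpy() + 2  # header occupies line 1

    bad_p = (~np.isfinite(df["P"])) | (df["P"] <= 0) | (df["P"] > 1)
    if bad_p.any():
        where = ", ".join(str(ln) for ln in lines[bad_p.to_numpy()][:10])
        raise ValueError(f"{path}: p-values outside (0, 1] at line(s) {where}")
    for col in ("A1", "A2"):
        bad = ~df[col].str.upper().isin(VALID_ALLELES)
        if bad.any():
            where = ", ".join(str(ln) for ln in lines[bad.to_numpy()][:10])
            raise ValueError(f"{path}: invalid {col} allele at line(s) {where}")
    dup = df["SNP"].duplicated(keep=False)
    if dup.any():
        ids = sorted(df.loc[dup, "SNP"].unique())
        raise ValueError(f"{path}: duplicated SNP id(s): {ids[:10]}")
    if not np.isfinite(df["BETA"]).all():
        raise ValueError(f"{path}: non-finite BETA values")

    df = df.copy()
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    df["BP"] = df["BP"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Dosages
# ---------------------------------------------------------------------------

def read_dosages(path: str | Path, format: str = "auto") -> pd.DataFrame:
    """Read a subjects x SNPs dosage matrix from TSV or VCF.

    TSV layout: first column ``subject_id``, one column per SNP, values in
    [0, 2] or ``NA``. VCF: per-sample ``DS`` is used directly; otherwise
    genotype probabilities ``GP`` = (P(hom-ref), P(het), P(hom-alt)) are
    converted to dosage = P(het) + 2*P(hom-alt).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_dosages_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    _validate_dosage_values(df, path)
    return df.astype(float)


def _validate_dosage_values(df: pd.DataFrame, path: Path) -> None:
    vals = df.to_numpy(dtype=float)
    bad = np.isfinite(vals) & ((vals < 0) | (vals > 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: dosage {vals[i, j]} outside [0, 2] "
            f"(subject {df.index[i]}, SNP {df.columns[j]})"
        )


def _read_dosages_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            arr = var.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(len(subjects), -1)[:, 0]
        else:
            try:
                gp = var.format("GP")
            except KeyError:
                gp = None
            if gp is None:
                raise ValueError(f"{path}: record {snp_id} carries neither DS nor GP")
            gp = np.asarray(gp, dtype=float).reshape(len(subjects), 3)
            ds = gp[:, 1] + 2.0 * gp[:, 2]
        ds = np.where(np.isfinite(ds) & (ds >= 0), ds, np.nan)
        cols[snp_id] = ds
    df = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    _validate_dosage_values(df, path)
    return df


def write_dosages(d: pd.DataFrame, path: str | Path) -> None:
    """Write a dosage matrix as TSV with 4-decimal precision and NA missing."""
    d.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA", index_label="subject_id")


# ---------------------------------------------------------------------------
# Hard calling
# ---------------------------------------------------------------------------

def hard_call(
    d: pd.DataFrame,
    call_threshold: float = 0.8,
    gp: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convert dosages (and optionally genotype probabilities) to hard calls.

    With genotype probabilities ``gp`` (shape n_subjects x n_snps x 3) the
    argmax genotype is called iff its probability >= ``call_threshold``.
    With dosages only, ``round(d)`` is called iff |d - round(d)| <= 1 -
    ``call_threshold`` — the dosage-space analogue of the probability rule,
    exact when probability mass is split between the two nearest genotypes.
    Ties at .5 round half-up. Cells failing the band, and cells already
    missing, are missing (NaN) in the result.
    """
    if not (1.0 / 3.0 < call_threshold <= 1.0):
        raise ValueError(f"call_threshold must be in (1/3, 1], got {call_threshold}")
    vals = d.to_numpy(dtype=float)
    if gp is not None:
        gp = np.asarray(gp, dtype=float)
        if gp.shape != (*vals.shape, 3):
            raise ValueError(f"gp shape {gp.shape} incompatible with dosages {vals.shape}")
        calls = gp.argmax(axis=2).astype(float)
        ok = gp.max(axis=2) >= call_threshold
    else:
        calls = np.floor(vals + 0.5)
        ok = np.abs(vals - calls) <= (1.0 - call_threshold) + 1e-12
    out = np.where(ok & np.isfinite(vals), calls, np.nan)
    return pd.DataFrame(out, index=d.index, columns=d.columns)


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

def compute_snp_qc(
    h: pd.DataFrame,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP QC on a hard-call matrix computed within the analysis sample.

    Returns a DataFrame with columns ``snp_id, maf, missing_rate, n_called,
    included, exclusion_reason``. The counted-allele frequency is
    f = (sum of calls) / (2 * n_nonmissing); maf = min(f, 1 - f), invariant
    to ref/alt relabeling. Exclusion reasons: ``high_missing`` when
    missing_rate > miss_max (takes precedence; covers all-missing SNPs,
    whose MAF is undefined), ``rare`` when maf < maf_min, else ``none``.
    """
    if h.shape[0] < 1 or h.shape[1] < 1:
        raise ValueError("empty hard-call matrix")
    vals = h.to_numpy(dtype=float)
    n = vals.shape[0]
    n_called = np.isfinite(vals).sum(axis=0)
    # integer-count ratio, so a rate of exactly 1/20 compares == 0.05
    missing_rate = (n - n_called) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(vals, axis=0) / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    maf = np.where(n_called > 0, maf, np.nan)

    reason = np.full(vals.shape[1], "none", dtype=object)
    reason[np.isnan(maf) | (maf < maf_min)] = "rare"
    reason[missing_rate > miss_max] = "high_missing"
    return pd.DataFrame(
        {
            "snp_id": h.columns,
            "maf": maf,
            "missing_rate": missing_rate,
            "n_called": n_called.astype(int),
            "included": reason == "none",
            "exclusion_reason": reason,
        }
    ).reset_index(drop=True)


def write_snp_qc(qc: pd.DataFrame, path: str | Path) -> None:
    qc.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(
    ss: pd.DataFrame,
    panel: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align GWAS effect alleles to the genotype panel's counted (alt) allele.

    Parameters
    ----------
    ss : summary statistics as returned by :func:`read_summary_stats`.
    panel : DataFrame with columns ``snp_id, chrom, pos, ref_allele,
        alt_allele`` describing the genotyped SNPs.
    drop_ambiguous : drop strand-ambiguous (palindromic A/T, C/G) SNPs, for
        which a strand flip is indistinguishable from an allele swap.

    Returns
    -------
    (aligned, exclusions)
        ``aligned`` has columns ``snp_id, chrom, pos, beta, gwas_p`` with
        beta expressed per copy of the panel alt allele (negated when the
        GWAS effect allele matched the panel ref allele, directly or after
        strand complementation). ``exclusions`` has columns ``snp_id,
        reason`` with reasons ``ambiguous_allele`` or ``unmatched``.
    """
    pan = panel.set_index("snp_id")
    aligned_rows: list[tuple] = []
    excl_rows: list[tuple[str, str]] = []
    for row in ss.itertuples(index=False):
        sid = row.SNP
        if sid not in pan.index:
            excl_rows.append((sid, "unmatched"))
            continue
        ref = str(pan.at[sid, "ref_allele"]).upper()
        alt = str(pan.at[sid, "alt_allele"]).upper()
        a1, a2 = row.A1, row.A2
        if drop_ambiguous and COMPLEMENT.get(a1) == a2:
            excl_rows.append((sid, "ambiguous_allele"))
            continue
        if (a1, a2) == (alt, ref):
            beta = row.BETA
        elif (a1, a2) == (ref, alt):
            beta = -row.BETA
        elif (COMPLEMENT.get(a1), COMPLEMENT.get(a2)) == (alt, ref):
            beta = row.BETA
        elif (COMPLEMENT.get(a1), COMPLEMENT.get(a2)) == (ref, alt):
            beta = -row.BETA
        else:
            excl_rows.append((sid, "unmatched"))
            continue
        aligned_rows.append((sid, pan.at[sid, "chrom"], int(pan.at[sid, "pos"]), beta, row.P))
    aligned = pd.DataFrame(aligned_rows, columns=["snp_id", "chrom", "pos", "beta", "gwas_p"])
    exclusions = pd.DataFrame(excl_rows, columns=["snp_id", "reason"])
    return aligned, exclusions


# ---------------------------------------------------------------------------
# Region exclusion
# ---------------------------------------------------------------------------

def exclude_region(
    panel: pd.DataFrame,
    region: GenomicRegion,
    build: str = "GRCh37",
) -> tuple[list[str], list[str]]:
    """Split SNP ids into (retained, excluded) by a closed genomic interval.

    A SNP is excluded iff its chromosome matches and region.start <= pos <=
    region.end (both bounds inclusive). A build-label mismatch warns but does
    not abort, matching the permissive contract for pre-curated inputs.
    """
    if region.build != build:
        warnings.warn(
            f"genome build mismatch: region is {region.build}, panel declared {build}",
            stacklevel=2,
        )
    chroms = panel["chrom"].map(_norm_chrom)
    in_region = (chroms == _norm_chrom(region.chrom)) & panel["pos"].between(
        region.start, region.end
    )
    retained = panel.loc[~in_region, "snp_id"].tolist()
    excluded = panel.loc[in_region, "snp_id"].tolist()
    return retained, excluded
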