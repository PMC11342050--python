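"""End-to-end orchestration: simulate -> qc -> score -> analyze -> permute.

A single YAML config (or :class:`PipelineConfig`) drives all stages with one
master seed fanned out to per-stage child seeds, so each stage is
independently reproducible. The run emits a demographics table, the
hierarchical model table, the severity ANCOVA, the APOE follow-up models,
and the min-p correction, as a plain-text report plus a machine-readable
JSON sidecar; a timestamped log records stage inputs/outputs (timestamps go
to the log only, keeping the report byte-identical across reruns).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import genotype_qc as gqc
from . import minp as minp_mod
from . import prs_scoring as prs_mod
from .genotype_qc import APOE_REGION, GenomicRegion
from .synthetic_cohort import child_seed, make_paper_like_fixture

__all__ = [
    "PipelineConfig",
    "CohortAudit",
    "PipelineError",
    "apply_cohort_filters",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class CohortAudit:
    """Subject-exclusion accounting for the analysis cohort."""

    n_initial: int
    n_excluded_clinical: int
    n_excluded_csf: int
    n_overlap: int
    n_final: int

    def __post_init__(self) -> None:
        expect = self.n_initial - self.n_excluded_clinical - self.n_excluded_csf + self.n_overlap
        if expect != self.n_final:
            raise ValueError(
                f"audit arithmetic violated: {self.n_initial} - {self.n_excluded_clinical}"
                f" - {self.n_excluded_csf} + {self.n_overlap} != {self.n_final}"
            )


def apply_cohort_filters(roster: pd.DataFrame) -> tuple[pd.DataFrame, CohortAudit]:
    """Drop subjects flagged missing_clinical or missing_csf; audit counts.

    The audit reports both exclusion counts and their overlap, so the final
    n is never silently assumed to equal initial minus the two counts.
    """
    for col in ("missing_clinical", "missing_csf"):
        if col not in roster.columns:
            raise ValueError(f"roster lacks boolean flag column {col!r}")
    clin = roster["missing_clinical"].astype(bool)
    csf = roster["missing_csf"].astype(bool)
    retained = roster[~clin & ~csf].copy()
    audit = CohortAudit(
        n_initial=len(roster),
        n_excluded_clinical=int(clin.sum()),
        n_excluded_csf=int(csf.sum()),
        n_overlap=int((clin & csf).sum()),
        n_final=len(retained),
    )
    return retained, audit


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Pipeline settings; defaults equal the emulated protocol's printed
    values (hard-call 0.8, MAF >= 0.01, missingness <= 0.05, six thresholds,
    APOE region chr19:44,409,039-46,412,650, 10,000 permutation replicates).
    """

    out_dir: str = "tbiprs_out"
    seed: int = 0
    # input paths; all None -> a synthetic study-shaped fixture is generated
    sumstats: str | None = None
    dosages: str | None = None
    phenotypes: str | None = None
    panel: str | None = None
    # qc
    call_threshold: float = 0.8
    maf_min: float = 0.01
    miss_max: float = 0.05
    # scoring
    thresholds: tuple[float, ...] = prs_mod.DEFAULT_THRESHOLDS
    apoe_chrom: str = APOE_REGION.chrom
    apoe_start: int = APOE_REGION.start
    apoe_end: int = APOE_REGION.end
    clump_r2: float | None = None
    clump_kb: float = 250.0
    # analysis toggles
    severity: bool = True
    apoe_models: bool = True
    # permutation
    n_replicates: int = 10_000

    def apoe_region(self) -> GenomicRegion:
        return GenomicRegion(self.apoe_chrom, self.apoe_start, self.apoe_end)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(d["thresholds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "thresholds" in d:
            d["thresholds"] = tuple(float(t) for t in d["thresholds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage(log: list[str], name: str):
    """Context helper: wrap a stage body so failures name the stage."""

    class _Ctx:
        def __enter__(self):
            log.append(f"{datetime.datetime.now().isoformat()}  stage {name}: start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.append(f"{datetime.datetime.now().isoformat()}  stage {name}: FAILED {exc}")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.append(f"{datetime.datetime.now().isoformat()}  stage {name}: done")

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``cfg.out_dir``.

    Returns a dict with the in-memory results (descriptives, fits, ANCOVA,
    APOE models, min-p result, audit paths). Raises :class:`PipelineError`
    naming the failed stage on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    bundle: dict = {"out_dir": str(out)}

    with _stage(log, "inputs"):
        if cfg.sumstats is None or cfg.dosages is None or cfg.phenotypes is None:
            paths = make_paper_like_fixture(child_seed(cfg.seed, "simulate"), out / "fixture")
        else:
            paths = {
                "sumstats": Path(cfg.sumstats),
                "dosages": Path(cfg.dosages),
                "phenotypes": Path(cfg.phenotypes),
                "panel": Path(cfg.panel) if cfg.panel else None,
            }
        ss = gqc.read_summary_stats(paths["sumstats"])
        dosages = gqc.read_dosages(paths["dosages"])
        pheno = assoc.read_phenotypes(paths["phenotypes"])
        if paths.get("panel"):
            panel = pd.read_csv(paths["panel"], sep="\t", dtype={"chrom": str})
        else:
            # fall back to summary-stat coordinates for region exclusion
            panel = ss.rename(
                columns={"SNP": "snp_id", "CHR": "chrom", "BP": "pos", "A2": "ref_allele", "A1": "alt_allele"}
            )[["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]]
        bundle["n_subjects"] = len(pheno)

    with _stage(log, "qc"):
        calls = gqc.hard_call(dosages, call_threshold=cfg.call_threshold)
        qc = gqc.compute_snp_qc(calls, maf_min=cfg.maf_min, miss_max=cfg.miss_max)
        gqc.write_snp_qc(qc, out / "snp_qc.tsv")
        kept = set(qc.loc[qc["included"], "snp_id"])
        aligned, excl = gqc.harmonize_alleles(ss, panel)
        excl.to_csv(out / "harmonization_exclusions.tsv", sep="\t", index=False)
        weights = aligned[aligned["snp_id"].isin(kept)].reset_index(drop=True)
        bundle["n_snps_scored"] = len(weights)

    with _stage(log, "score"):
        clump = (
            prs_mod.ClumpParams(r2=cfg.clump_r2, window_kb=cfg.clump_kb)
            if cfg.clump_r2 is not None
            else None
        )
        pcfg = prs_mod.PrsConfig(thresholds=cfg.thresholds, clumping=clump)
        prs_full = prs_mod.score_all_thresholds(calls, weights, pcfg)
        prs_noapoe = prs_mod.score_all_thresholds(calls, weights, pcfg, exclude=cfg.apoe_region())
        prs_mod.write_prs_matrix(prs_full, out / "prs_matrix.tsv")
        prs_mod.write_prs_matrix(prs_noapoe, out / "prs_matrix_noapoe.tsv")
        corr = prs_mod.prs_threshold_correlations(prs_full)
        corr.to_csv(out / "prs_threshold_correlations.tsv", sep="\t", float_format="%.4f")
        bundle["prs_full"] = prs_full
        bundle["prs_noapoe"] = prs_noapoe
        bundle["min_threshold_r"] = float(
            corr.to_numpy()[~np.eye(len(corr), dtype=bool)].min()
        )

    with _stage(log, "analyze"):
        table = assoc.compute_ratio_and_standardize(pheno)
        obs = minp_mod.observed_interaction_pvals(table, prs_full)
        best_t = cfg.thresholds[int(np.argmin(obs))]
        best_col = prs_mod.threshold_column(best_t, standardized=True)
        prs_best = (
            prs_full.standardized[best_col].loc[table["subject_id"]].to_numpy()
        )
        bundle["best_threshold"] = best_t
        bundle["descriptives"] = assoc.descriptives(table, prs_best)
        bundle["group_comparisons"] = assoc.group_comparisons(table, prs_best)
        fits = assoc.fit_hierarchical_models(table, prs_best)
        bundle["fits"] = fits
        assoc.write_results(fits, out / "hierarchical_models.tsv")
        bundle["stratified"] = {
            "tbi": assoc.stratified_prs_effect(table, prs_best, True),
            "no_tbi": assoc.stratified_prs_effect(table, prs_best, False),
        }
        if cfg.severity:
            bundle["ancova"] = assoc.severity_ancova(table, prs_best)
        if cfg.apoe_models:
            noapoe_best = (
                prs_noapoe.standardized[best_col].loc[table["subject_id"]].to_numpy()
            )
            bundle["apoe_models"] = assoc.apoe_models(table, noapoe_best)

    with _stage(log, "permute"):
        mcfg = minp_mod.MinPConfig(
            n_replicates=cfg.n_replicates, seed=child_seed(cfg.seed, "permute")
        )
        res = minp_mod.minp_permutation(table, prs_full, mcfg)
        minp_mod.write_minp_report(res, out / "minp_observed.tsv", out / "minp.json")
        bundle["minp"] = res

    with _stage(log, "report"):
        _write_report(bundle, cfg, out)
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return bundle


def _fmt_fit(fit: assoc.RegressionFit) -> str:
    lines = [f"  {fit.label}:  R^2 = {fit.r_squared:.3f}, "
             f"F({fit.f_df[0]:.0f}, {fit.f_df[1]:.0f}) = {fit.f_stat:.3f}, n = {fit.n_used}"]
    for term, row in fit.coefficients.iterrows():
        lines.append(
            f"    {term:<22s} B = {row['B']:+.3f}  SE = {row['SE']:.3f}  p = {row['p']:.4f}"
            f"  95% CI [{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]"
        )
    return "\n".join(lines)


def _write_report(bundle: dict, cfg: PipelineConfig, out: Path) -> None:
    lines = ["TBI x polygenic-risk interaction analysis report", "=" * 48, ""]
    lines.append(f"subjects analysed: {bundle['n_subjects']}")
    lines.append(f"SNPs entering scoring after QC/harmonization: {bundle['n_snps_scored']}")
    lines.append(f"minimum pairwise threshold-score correlation: {bundle['min_threshold_r']:.3f}")
    lines.append("")
    lines.append("Demographics (mean (SD) / n (%)):")
    lines.append(bundle["descriptives"].to_string(index=False))
    lines.append("")
    gc = bundle["group_comparisons"]
    lines.append("Group comparisons (no-TBI vs TBI):")
    for name, r in gc.items():
        if isinstance(r, assoc.WelchResult):
            lines.append(f"  {name:<16s} t({r.df:.2f}) = {r.t:+.2f}, p = {r.p:.2f}")
        else:
            lines.append(
                f"  {name:<16s} OR = {r.odds_ratio:.2f} (cMLE {r.odds_ratio_cmle:.2f}),"
                f" p = {r.p:.2f}, n = {r.n_used}"
            )
    lines.append("")
    lines.append(f"Follow-up PRS threshold (strongest interaction): p < {bundle['best_threshold']:g}")
    lines.append("Hierarchical models (standardized Abeta42/40 outcome):")
    for fit in bundle["fits"].values():
        lines.append(_fmt_fit(fit))
    lines.append("")
    st = bundle["stratified"]
    lines.append("Stratified covariate-adjusted PRS slopes:")
    for g, r in st.items():
        lines.append(
            f"  {g:<7s} B = {r.B:+.3f}, p = {r.p:.3f}, partial r = {r.partial_r:+.3f}, n = {r.n}"
        )
    if "ancova" in bundle:
        a = bundle["ancova"]
        lines.append("")
        lines.append(
            f"Severity x PRS ANCOVA: F({a.interaction_df[0]}, {a.interaction_df[1]})"
            f" = {a.interaction_f:.3f}, p = {a.p:.3f}; slopes "
            + ", ".join(f"{k} {v:+.3f}" for k, v in a.cell_slopes.items())
        )
    if "apoe_models" in bundle:
        lines.append("")
        lines.append("APOE follow-up models:")
        for fit in bundle["apoe_models"].values():
            lines.append(_fmt_fit(fit))
    mp = bundle["minp"]
    lines.append("")
    lines.append(
        "Min-p correction: observed p per threshold "
        + ", ".join(f"{t:g}: {p:.4f}" for t, p in zip(mp.thresholds, mp.observed_p))
    )
    lines.append(
        f"  best threshold p < {mp.best_threshold:g}; observed min p = {mp.observed_min_p:.4f};"
        f" corrected p = {mp.corrected_p:.4f} (B = {mp.n_replicates}, seed = {mp.seed})"
    )
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    sidecar = {
        "n_subjects": bundle["n_subjects"],
        "n_snps_scored": bundle["n_snps_scored"],
        "min_threshold_r": bundle["min_threshold_r"],
        "best_threshold": bundle["best_threshold"],
        "interaction_B_model3": float(bundle["fits"]["model3"].term("tbi:prs")["B"]),
        "interaction_p_model3": float(bundle["fits"]["model3"].term("tbi:prs")["p"]),
        "corrected_p": mp.corrected_p,
        "observed_min_p": mp.observed_min_p,
        "seed": cfg.seed,
    }
    (out / "report.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
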