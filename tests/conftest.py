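import numpy as np
import pandas as pd
import pytest

from tbiprs import association as assoc
from tbiprs import genotype_qc as gqc
from tbiprs import prs_scoring as prs_mod
from tbiprs.synthetic_cohort import make_paper_like_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Study-shaped synthetic data set written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return make_paper_like_fixture(FIXTURE_SEED, out)


@pytest.fixture(scope="session")
def cohort(fixture_paths):
    """Fixture data pushed through hard-calling, QC, harmonization and
    scoring — the shared starting point for analysis-level tests."""
    ss = gqc.read_summary_stats(fixture_paths["sumstats"])
    dosages = gqc.read_dosages(fixture_paths["dosages"])
    panel = pd.read_csv(fixture_paths["panel"], sep="\t", dtype={"chrom": str})
    pheno = assoc.read_phenotypes(fixture_paths["phenotypes"])
    calls = gqc.hard_call(dosages)
    qc = gqc.compute_snp_qc(calls)
    aligned, _ = gqc.harmonize_alleles(ss, panel)
    weights = aligned[aligned["snp_id"].isin(set(qc.loc[qc["included"], "snp_id"]))]
    weights = weights.reset_index(drop=True)
    prs_full = prs_mod.score_all_thresholds(calls, weights)
    prs_noapoe = prs_mod.score_all_thresholds(calls, weights, exclude=gqc.APOE_REGION)
    table = assoc.compute_ratio_and_standardize(pheno)
    return {
        "ss": ss,
        "dosages": dosages,
        "panel": panel,
        "pheno": pheno,
        "table": table,
        "calls": calls,
        "qc": qc,
        "weights": weights,
        "prs_full": prs_full,
        "prs_noapoe": prs_noapoe,
    }


@pytest.fixture()
def tiny_hardcalls():
    """5 subjects x 4 SNPs with one missing call, for hand-computable scores."""
    rng = np.random.default_rng(11)
    vals = rng.integers(0, 3, size=(5, 4)).astype(float)
    vals[2, 1] = np.nan
    return pd.DataFrame(
        vals,
        index=[f"S{i}" for i in range(5)],
        columns=["rs1", "rs2", "rs3", "rs4"],
    )


@pytest.fixture()
def tiny_weights():
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": ["1", "1", "2", "19"],
            "pos": [100, 200, 300, 45_000_000],
            "beta": [0.5, -0.2, 0.1, 0.4],
            "gwas_p": [0.01, 0.04, 0.2, 0.45],
        }
    )
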