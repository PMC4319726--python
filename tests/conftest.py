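import io

import pytest

from snpcc import datasets
from snpcc.data_model import CohortTable, read_subject_table

import pandas as pd


@pytest.fixture(scope="session")
def snp_defs():
    return datasets.snp_defs()


@pytest.fixture(scope="session")
def study_counts():
    return datasets.genotype_counts()


@pytest.fixture(scope="session")
def study_cohort():
    """Subject-level cohort whose per-SNP margins match the study tables."""
    return datasets.example_cohort(seed=7, exact=True)


SMALL_TSV = """subject_id\tstatus\tage\tsex\tsmoking\tpack_years_cat\tdrinking\tbmi_cat\tsite\tstage\trs2294008\trs2976392\trs2274223\trs4072037
P1\tcase\t61\tmale\tever\tle_mean\tnever\tnormal\tcardia\tI_II\tCT\tAG\tAA\tTT
P2\tcontrol\t58\tfemale\tnever\tnone\tnever\thigh\tnot_applicable\tnot_applicable\tCC\tGG\tAG\tCT
"""


@pytest.fixture
def small_tsv():
    return SMALL_TSV


@pytest.fixture
def small_cohort(snp_defs):
    return read_subject_table(io.StringIO(SMALL_TSV), snp_defs)


def cohort_from_groups(snp_defs, rows):
    """Build a CohortTable from (status, age, genotype-dict, n) tuples.

    Covariates not supplied default to a fixed benign profile.
    """
    records = []
    i = 0
    for spec in rows:
        status = spec["status"]
        n = spec.get("n", 1)
        for _ in range(n):
            i += 1
            rec = {
                "subject_id": f"X{i:05d}",
                "status": status,
                "age": spec.get("age", 60),
                "sex": spec.get("sex", "male"),
                "smoking": spec.get("smoking", "never"),
                "pack_years_cat": spec.get("pack_years_cat", "none"),
                "drinking": spec.get("drinking", "never"),
                "bmi_cat": spec.get("bmi_cat", "normal"),
                "site": spec.get(
                    "site", "not_applicable" if status == "control" else "non_cardia"
                ),
                "stage": spec.get(
                    "stage", "not_applicable" if status == "control" else "III_IV"
                ),
            }
            for snp_id in snp_defs:
                rec[snp_id] = spec.get("genotypes", {}).get(snp_id)
            records.append(rec)
    df = pd.DataFrame(records, columns=list(records[0]))
    return CohortTable(df, dict(snp_defs))
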