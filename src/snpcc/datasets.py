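"""Bundled example dataset: printed count tables from a published
stomach-cancer case-control study (692 cases / 774 controls, four GWAS
SNPs), used as fixtures and for end-to-end demos.

One printed case row (rs2294008 CC) is internally inconsistent: 332 does not
match its own percentage (46.53% of 692 = 322) and makes the column sum to
702.  The fixture stores the percentage-derived 322/309/61, which also
reproduces the printed crude OR 1.31 (1.05-1.63).
"""

from __future__ import annotations

from .data_model import GenotypeCounts, SnpDef, TwoByTwo

#: The four SNPs genotyped by the study.
def snp_defs() -> dict[str, SnpDef]:
    return {
        "rs2294008": SnpDef.from_alleles(
            "rs2294008", "PSCA", "C>T", ["CT", "TT"], "risk"
        ),
        "rs2976392": SnpDef.from_alleles(
            "rs2976392", "PSCA", "G>A", ["AG", "AA"], "risk"
        ),
        "rs2274223": SnpDef.from_alleles(
            "rs2274223", "PLCE1", "A>G", ["AG", "GG"], "risk"
        ),
        # the protective SNP: its *reference* homozygote TT is the risk genotype
        "rs4072037": SnpDef.from_alleles(
            "rs4072037", "MUC1", "T>C", ["TT"], "protective"
        ),
    }


#: (ref-hom, het, var-hom) counts; cases then controls.
_CASE_COUNTS = {
    "rs2294008": (322, 309, 61),  # percentage-derived, see module docstring
    "rs2976392": (319, 308, 65),
    "rs2274223": (405, 254, 33),
    "rs4072037": (528, 143, 21),
}
_CONTROL_COUNTS = {
    "rs2294008": (405, 297, 72),
    "rs2976392": (403, 299, 72),
    "rs2274223": (514, 226, 34),
    "rs4072037": (553, 201, 20),
}


def genotype_counts() -> dict[str, GenotypeCounts]:
    """Per-SNP 2x3 count tables."""
    defs = snp_defs()
    return {
        snp_id: GenotypeCounts(
            snp_id, _CASE_COUNTS[snp_id], _CONTROL_COUNTS[snp_id], defs[snp_id].genotypes
        )
        for snp_id in defs
    }


def risk_group_table() -> TwoByTwo:
    """Combined risk-genotype contrast: carriers of 2-4 risk genotypes vs 0-1."""
    return TwoByTwo(404, 288, 405, 369, "2-4", "0-1")


#: Published statistical-power values (to detect OR 1.50 / 0.67) per contrast,
#: used as inputs when reproducing the published FPRP cells; the study's exact
#: power recipe is not recoverable from the printed counts.
published_power = {
    ("rs2294008", "het_vs_ref"): 0.919,
    ("rs2294008", "dominant"): 0.951,
    ("rs2976392", "het_vs_ref"): 0.927,
    ("rs2976392", "dominant"): 0.943,
    ("rs2274223", "het_vs_ref"): 0.697,
    ("rs2274223", "dominant"): 0.739,
    ("rs4072037", "het_vs_ref"): 0.795,
    ("rs4072037", "dominant"): 0.881,
    ("combined", "high_vs_low"): 0.933,
}

#: Published FPRP cells for the same contrasts, keyed by prior probability
#: (reproduction tolerance: +/-0.002 with full-precision observed p).
published_fprp = {
    ("rs2294008", "het_vs_ref"): {0.25: 0.046, 0.1: 0.127, 0.01: 0.615, 0.001: 0.941, 0.0001: 0.994},
    ("rs2294008", "dominant"): {0.25: 0.078, 0.1: 0.202, 0.01: 0.736, 0.001: 0.966, 0.0001: 0.996},
    ("rs2976392", "het_vs_ref"): {0.25: 0.052, 0.1: 0.142, 0.01: 0.646, 0.001: 0.949, 0.0001: 0.995},
    ("rs2976392", "dominant"): {0.25: 0.067, 0.1: 0.177, 0.01: 0.703, 0.001: 0.960, 0.0001: 0.996},
    ("rs2274223", "het_vs_ref"): {0.25: 0.007, 0.1: 0.021, 0.01: 0.194, 0.001: 0.709, 0.0001: 0.961},
    ("rs2274223", "dominant"): {0.25: 0.007, 0.1: 0.021, 0.01: 0.194, 0.001: 0.709, 0.0001: 0.961},
    ("rs4072037", "het_vs_ref"): {0.25: 0.066, 0.1: 0.175, 0.01: 0.701, 0.001: 0.959, 0.0001: 0.996},
    ("rs4072037", "dominant"): {0.25: 0.106, 0.1: 0.263, 0.01: 0.797, 0.001: 0.975, 0.0001: 0.997},
    ("combined", "high_vs_low"): {0.25: 0.060, 0.1: 0.161, 0.01: 0.679, 0.001: 0.955, 0.0001: 0.995},
}


def covariate_margins() -> dict:
    """Per-group covariate category counts from the study's demographic table.

    Used to parameterize marginal-mode simulation so synthetic cohorts carry
    the study's case-control imbalance in smoking/drinking/BMI.
    """
    return {
        "case": {
            "n": 692,
            "sex": {"male": 492, "female": 200},
            "smoking": {"never": 427, "ever": 265},
            # pack-years among ever smokers only (never smokers are 'none')
            "pack_years_ever": {"le_mean": 133, "gt_mean": 132},
            "drinking": {"never": 539, "ever": 153},
            "bmi_cat": {"under": 53, "normal": 423, "high": 216},
            "site": {"cardia": 199, "non_cardia": 493},
            "stage": {"I_II": 274, "III_IV": 418},
            "age_mean": 59.2,
            "age_sd": 11.1,
            "age_range": (24, 85),
        },
        "control": {
            "n": 774,
            "sex": {"male": 549, "female": 225},
            "smoking": {"never": 362, "ever": 412},
            "pack_years_ever": {"le_mean": 250, "gt_mean": 162},
            "drinking": {"never": 542, "ever": 232},
            "bmi_cat": {"under": 5, "normal": 244, "high": 525},
            "age_mean": 59.7,
            "age_sd": 11.3,
            "age_range": (23, 87),
        },
    }


def example_cohort(seed: int = 0, exact: bool = True):
    """Synthetic subject-level cohort whose per-SNP genotype margins
    reproduce the study's printed count tables exactly (in exact mode).

    Joint genotype structure is not preserved — the printed combined
    risk-genotype counts come from :func:`risk_group_table` instead.
    """
    from .synthetic_data import SimulationConfig, simulate_marginal

    cfg = SimulationConfig.from_margins(
        snp_defs(), genotype_counts(), covariate_margins()
    )
    return simulate_marginal(cfg, seed=seed, exact=exact)
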