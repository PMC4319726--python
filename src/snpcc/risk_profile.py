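"""Combined risk-genotype profiling: count risk genotypes per subject and
contrast high (>= threshold) vs low carrier groups."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .association import EffectEstimate, crude_or
from .data_model import CohortTable, SnpDef, Subject, TwoByTwo
from .errors import ValidationError

DEFAULT_THRESHOLD = 2  # the published split: 0-1 vs 2-4 risk genotypes


@dataclass(frozen=True)
class RiskProfile:
    subject_id: str
    n_risk: int
    group: str | None  # "low" / "high", None when incomplete
    complete: bool


def profile_subject(
    subject: Subject,
    snp_defs: Mapping[str, SnpDef],
    threshold: int = DEFAULT_THRESHOLD,
) -> RiskProfile:
    """Count risk genotypes across the declared SNPs.

    Subjects missing any genotype are flagged incomplete and carry no group
    (they are excluded from the group contrast, not imputed).
    """
    n_risk = 0
    complete = True
    for snp_id, snp in snp_defs.items():
        genotype = subject.genotypes.get(snp_id)
        if genotype is None:
            complete = False
            continue
        if genotype in snp.risk_genotypes:
            n_risk += 1
    group = None
    if complete:
        group = "high" if n_risk >= threshold else "low"
    return RiskProfile(subject.subject_id, n_risk, group, complete)


def profile_cohort(
    cohort: CohortTable, threshold: int = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-subject risk profiles as a DataFrame (vectorized)."""
    if threshold < 1 or threshold > len(cohort.snp_defs):
        raise ValidationError(
            f"threshold {threshold} outside 1..{len(cohort.snp_defs)}"
        )
    df = cohort.df
    n_risk = pd.Series(0, index=df.index)
    complete = pd.Series(True, index=df.index)
    for snp_id, snp in cohort.snp_defs.items():
        g = df[snp_id]
        complete &= g.notna()
        n_risk += g.isin(snp.risk_genotypes).astype(int)
    group = pd.Series(None, index=df.index, dtype=object)
    group[complete & (n_risk >= threshold)] = "high"
    group[complete & (n_risk < threshold)] = "low"
    return pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "status": df["status"],
            "n_risk": n_risk,
            "group": group,
            "complete": complete,
        }
    )


def group_contrast_table(profiles: pd.DataFrame) -> TwoByTwo:
    """2x2 table of high vs low carrier groups (complete profiles only)."""
    sub = profiles[profiles["complete"]]

    def cell(status: str, group: str) -> int:
        return int(((sub["status"] == status) & (sub["group"] == group)).sum())

    return TwoByTwo(
        cell("case", "high"),
        cell("case", "low"),
        cell("control", "high"),
        cell("control", "low"),
        "high",
        "low",
    )


def group_contrast(
    cohort: CohortTable, threshold: int = DEFAULT_THRESHOLD
) -> tuple[TwoByTwo, EffectEstimate]:
    """High-vs-low carrier crude OR for a cohort."""
    table = group_contrast_table(profile_cohort(cohort, threshold))
    return table, crude_or(table)
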