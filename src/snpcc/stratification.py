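"""Subgroup analyses with Cochran-Q heterogeneity and interaction LRTs.

Strata are complete-case partitions on the stratifier; tumor site and TNM
stage are case-only stratifiers, contrasting each case subgroup against the
full control group.  Within a stratum the stratification variable (and
pack-years when stratifying on smoking, and vice versa) is removed from the
adjustment set to avoid collinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import (
    EffectEstimate,
    crude_or,
    encode_covariates,
    genotype_exposure,
)
from .data_model import CohortTable, TwoByTwo, make_contrast, tabulate_genotypes
from .errors import ComputationError, ValidationError, ZeroCellError

#: Stratifier name -> covariates that must leave the adjustment set inside
#: its own strata.
_DROP_FROM_ADJUSTMENT = {
    "age_median": {"age"},
    "sex": {"sex"},
    "smoking": {"smoking", "pack_years"},
    "pack_years": {"pack_years", "smoking"},
    "drinking": {"drinking"},
    "bmi": {"bmi"},
    "site": set(),
    "stage": set(),
}

STRATIFIERS = tuple(_DROP_FROM_ADJUSTMENT)


@dataclass(frozen=True)
class StratumSpec:
    """How to split a cohort: the stratifier and its category labels."""

    variable: str
    labels: tuple[str, ...]
    case_only: bool = False
    cut: float | None = None  # e.g. the age median

    def masks(self, df: pd.DataFrame) -> list[tuple[str, pd.Series]]:
        out = []
        for label in self.labels:
            if self.variable == "age_median":
                if label.startswith("<="):
                    member = df["age"] <= self.cut
                else:
                    member = df["age"] > self.cut
            else:
                col = {
                    "sex": "sex",
                    "smoking": "smoking",
                    "pack_years": "pack_years_cat",
                    "drinking": "drinking",
                    "bmi": "bmi_cat",
                    "site": "site",
                    "stage": "stage",
                }[self.variable]
                member = df[col] == label
            if self.case_only:
                mask = (member & (df["status"] == "case")) | (df["status"] == "control")
            else:
                mask = member
            out.append((label, mask))
        return out


def stratum_spec(
    name: str, cohort: CohortTable, age_cut: float | None = None
) -> StratumSpec:
    """Build the standard stratifiers (age at the cohort median — or an
    explicit ``age_cut`` — categorical variables on their declared levels,
    case-only site/stage)."""
    if name == "age_median":
        cut = float(np.median(cohort.df["age"])) if age_cut is None else float(age_cut)
        return StratumSpec("age_median", (f"<={cut:g}", f">{cut:g}"), cut=cut)
    if name == "sex":
        return StratumSpec("sex", ("female", "male"))
    if name == "smoking":
        return StratumSpec("smoking", ("never", "ever"))
    if name == "pack_years":
        return StratumSpec("pack_years", ("none", "le_mean", "gt_mean"))
    if name == "drinking":
        return StratumSpec("drinking", ("never", "ever"))
    if name == "bmi":
        return StratumSpec("bmi", ("under", "normal", "high"))
    if name == "site":
        return StratumSpec("site", ("cardia", "non_cardia"), case_only=True)
    if name == "stage":
        return StratumSpec("stage", ("I_II", "III_IV"), case_only=True)
    raise ValidationError(f"unknown stratifier {name!r}; choose from {STRATIFIERS}")


@dataclass(frozen=True)
class StratumResult:
    label: str
    table: TwoByTwo
    estimate: EffectEstimate | None


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    weights: tuple[float, ...]


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float


def stratified_estimates(
    cohort: CohortTable,
    snp_id: str,
    model: str,
    spec: StratumSpec,
    covariates: Sequence[str] | None = None,
) -> list[StratumResult]:
    """Per-stratum 2x2 tables and (crude or adjusted) effect estimates.

    Strata where the crude OR is undefined (zero margin/cell) or the
    adjusted fit fails are reported with ``estimate=None`` and a warning.
    """
    from .association import fit_logistic  # local import to keep cycles out

    if snp_id not in cohort.snp_defs:
        raise ValidationError(f"unknown snp_id {snp_id!r}")
    adjust: list[str] | None = None
    if covariates is not None:
        dropped = _DROP_FROM_ADJUSTMENT[spec.variable]
        adjust = [c for c in covariates if c not in dropped]

    results: list[StratumResult] = []
    for label, mask in spec.masks(cohort.df):
        sub = CohortTable(cohort.df[mask].reset_index(drop=True), cohort.snp_defs)
        table = make_contrast(tabulate_genotypes(sub, snp_id), model)
        estimate: EffectEstimate | None
        try:
            if adjust is None:
                estimate = crude_or(table)
            else:
                estimate = fit_logistic(sub, snp_id, model, adjust)
        except (ZeroCellError, ComputationError, ValidationError) as exc:
            warnings.warn(f"stratum {label!r}: estimate omitted ({exc})")
            estimate = None
        results.append(StratumResult(label, table, estimate))
    return results


def cochran_q(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q over stratum log-ORs with inverse-variance weights."""
    usable = [e for e in estimates if e is not None and np.isfinite(e.se_log) and e.se_log > 0]
    if len(usable) < 2:
        raise ValidationError("heterogeneity test needs >= 2 usable strata")
    log_ors = np.array([e.log_or for e in usable])
    weights = np.array([1.0 / e.se_log**2 for e in usable])
    pooled = float((weights * log_ors).sum() / weights.sum())
    q = float((weights * (log_ors - pooled) ** 2).sum())
    df = len(usable) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)), tuple(weights))


def interaction_lrt(
    cohort: CohortTable,
    snp_id: str,
    model: str,
    covariate: str,
    covariates: Sequence[str] = (),
) -> LrtResult:
    """Likelihood-ratio test for genotype x covariate interaction.

    Compares adjusted logistic models with and without the product term(s);
    df equals the number of added product columns.
    """
    if snp_id not in cohort.snp_defs:
        raise ValidationError(f"unknown snp_id {snp_id!r}")
    snp = cohort.snp_defs[snp_id]
    sub, x = genotype_exposure(cohort.df, snp, model)

    all_covs = [covariate] + [c for c in covariates if c != covariate]
    cov_frame = encode_covariates(sub, all_covs)
    inter_cols = encode_covariates(sub, [covariate])
    for name in inter_cols.columns:
        if inter_cols[name].std() == 0:
            raise ValidationError(f"covariate column {name!r} is constant; "
                                  "interaction inestimable")
    if x.std() == 0:
        raise ValidationError("genotype exposure is constant; interaction inestimable")

    base = pd.concat([x.rename("genotype"), cov_frame], axis=1).dropna()
    product = inter_cols.loc[base.index].mul(base["genotype"], axis=0)
    product.columns = [f"genotype:{c}" for c in inter_cols.columns]
    full = pd.concat([base, product], axis=1)
    y = (sub.loc[base.index, "status"] == "case").to_numpy(dtype=float)

    llf_base = _logit_llf(y, base)
    llf_full = _logit_llf(y, full)
    chi2 = max(0.0, 2.0 * (llf_full - llf_base))
    df = product.shape[1]
    return LrtResult(float(chi2), df, float(stats.chi2.sf(chi2, df)))


def _logit_llf(y: np.ndarray, design: pd.DataFrame) -> float:
    exog = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ComputationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ComputationError("logistic fit did not converge")
    return float(res.llf)
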