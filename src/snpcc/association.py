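"""Odds ratios, contingency-table tests, and adjusted logistic regression.

Crude ORs use the cross-product estimate with Woolf standard errors and
Wald confidence intervals / p-values; contingency tests are Pearson
chi-squares with no continuity correction.  These conventions jointly
reproduce published case-control tables at printed precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import CohortTable, GenotypeCounts, SnpDef, TwoByTwo, make_contrast
from .errors import (
    CollinearityError,
    ComputationError,
    SeparationError,
    ValidationError,
    ZeroCellError,
)

Z975 = float(stats.norm.ppf(0.975))

#: Adjustment variables accepted by :func:`fit_logistic` and their encodings.
COVARIATE_COLUMNS = {
    "age": ("age",),
    "sex": ("sex_male",),
    "smoking": ("smoking_ever",),
    "drinking": ("drinking_ever",),
    "bmi": ("bmi_under", "bmi_high"),
    "pack_years": ("pack_years_le", "pack_years_gt"),
}


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with its log-scale SE, 95% CI and two-sided p."""

    label: str
    or_hat: float
    se_log: float
    ci_low: float
    ci_high: float
    p: float
    adjusted: bool = False
    covariates: tuple = ()
    n_used: int = 0

    @property
    def log_or(self) -> float:
        return float(np.log(self.or_hat))


@dataclass(frozen=True)
class GenotypeTestResult:
    chi2: float
    df: int
    p: float
    warning: str | None = None


def crude_or(t: TwoByTwo, correction: float = 0.0) -> EffectEstimate:
    """Cross-product odds ratio with Woolf CI and Wald p.

    Zero cells are an error unless a continuity ``correction`` (typically
    0.5) is requested explicitly; no correction is ever applied by default.
    """
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    if correction:
        cells = cells + correction
    if np.any(cells == 0):
        raise ZeroCellError(
            f"2x2 table {tuple(int(x) for x in (t.a, t.b, t.c, t.d))} has a zero "
            "cell; pass correction=0.5 to apply a continuity correction"
        )
    a, b, c, d = cells
    or_hat = (a * d) / (b * c)
    se_log = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(or_hat))
    ci_low = float(np.exp(log_or - Z975 * se_log))
    ci_high = float(np.exp(log_or + Z975 * se_log))
    p = float(2 * stats.norm.sf(abs(log_or) / se_log))
    return EffectEstimate(
        label=f"{t.exposed_label} vs {t.unexposed_label}",
        or_hat=float(or_hat),
        se_log=se_log,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        adjusted=False,
        n_used=t.n_cases + t.n_controls,
    )


def genotype_distribution_test(counts: GenotypeCounts) -> GenotypeTestResult:
    """Pearson chi-square comparing the full genotype distribution (df = 2).

    Genotypes absent from both groups are dropped with a warning and the
    degrees of freedom reduced accordingly.
    """
    table = np.array([counts.case, counts.control], dtype=float)
    if table.sum() == 0:
        raise ValidationError("empty genotype table")
    keep = table.sum(axis=0) > 0
    warning = None
    if not keep.all():
        dropped = [i for i, k in enumerate(keep) if not k]
        warning = f"dropped empty genotype column(s) {dropped}; df reduced"
        warnings.warn(warning)
        table = table[:, keep]
    return _pearson(table, warning)


def chisq_2x2(t: TwoByTwo) -> GenotypeTestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if table.sum() == 0:
        raise ValidationError("empty 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate margin in 2x2 table; chi2 = 0")
        return GenotypeTestResult(0.0, 1, 1.0, "degenerate margin")
    return _pearson(table, None)


def _pearson(table: np.ndarray, warning: str | None) -> GenotypeTestResult:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    if df == 0:
        return GenotypeTestResult(0.0, 1, 1.0, warning or "degenerate table")
    return GenotypeTestResult(chi2, df, float(stats.chi2.sf(chi2, df)), warning)


def trend_test(counts: GenotypeCounts) -> GenotypeTestResult:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    Provided for completeness; the published "additive model" p-values in
    the bundled study correspond to the 2-df genotype-distribution test,
    not to this trend test.
    """
    case = np.array(counts.case, dtype=float)
    ctrl = np.array(counts.control, dtype=float)
    n = case + ctrl
    total = n.sum()
    if total == 0:
        raise ValidationError("empty genotype table")
    scores = np.array([0.0, 1.0, 2.0])
    r = case.sum()
    t_stat = (scores * case).sum() - r / total * (scores * n).sum()
    s_bar = (scores * n).sum() / total
    var = r * (total - r) / total / (total - 1) * ((scores - s_bar) ** 2 * n).sum()
    if var == 0:
        return GenotypeTestResult(0.0, 1, 1.0, "degenerate trend variance")
    chi2 = float(t_stat**2 / var)
    return GenotypeTestResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Logistic regression


def encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Encode adjustment variables: age continuous, sex/smoking/drinking as
    indicators, BMI and pack-years as two indicators against their baseline
    category."""
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov not in COVARIATE_COLUMNS:
            raise ValidationError(
                f"unknown covariate {cov!r}; choose from {sorted(COVARIATE_COLUMNS)}"
            )
        if cov == "age":
            cols["age"] = df["age"].to_numpy(dtype=float)
        elif cov == "sex":
            cols["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
        elif cov == "smoking":
            cols["smoking_ever"] = (df["smoking"] == "ever").to_numpy(dtype=float)
        elif cov == "drinking":
            cols["drinking_ever"] = (df["drinking"] == "ever").to_numpy(dtype=float)
        elif cov == "bmi":
            cols["bmi_under"] = (df["bmi_cat"] == "under").to_numpy(dtype=float)
            cols["bmi_high"] = (df["bmi_cat"] == "high").to_numpy(dtype=float)
        elif cov == "pack_years":
            cols["pack_years_le"] = (df["pack_years_cat"] == "le_mean").to_numpy(dtype=float)
            cols["pack_years_gt"] = (df["pack_years_cat"] == "gt_mean").to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def genotype_exposure(
    df: pd.DataFrame, snp: SnpDef, model: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Subset the cohort frame per genetic model and return the 0/1 exposure.

    ``het_vs_ref`` / ``hom_vs_ref`` drop the third genotype; ``dominant`` and
    ``recessive`` keep everyone with a genotype.
    """
    g = df[snp.snp_id]
    ref, het, hom = snp.genotypes
    if model == "het_vs_ref":
        sub = df[g.isin([ref, het])]
        x = (sub[snp.snp_id] == het).astype(float)
    elif model == "hom_vs_ref":
        sub = df[g.isin([ref, hom])]
        x = (sub[snp.snp_id] == hom).astype(float)
    elif model == "dominant":
        sub = df[g.notna()]
        x = (sub[snp.snp_id] != ref).astype(float)
    elif model == "recessive":
        sub = df[g.notna()]
        x = (sub[snp.snp_id] == hom).astype(float)
    else:
        raise ValidationError(f"unknown model {model!r}")
    return sub, x


def fit_logistic(
    cohort: CohortTable,
    snp_id: str,
    model: str = "dominant",
    covariates: Sequence[str] = (),
) -> EffectEstimate:
    """Maximum-likelihood logistic regression of status on a genotype
    contrast plus encoded covariates; returns the Wald OR/CI/p for the
    genotype term.

    Raises :class:`SeparationError` when a predictor perfectly predicts the
    outcome and :class:`CollinearityError` for rank-deficient designs.
    """
    if snp_id not in cohort.snp_defs:
        raise ValidationError(f"unknown snp_id {snp_id!r}")
    snp = cohort.snp_defs[snp_id]
    sub, x = genotype_exposure(cohort.df, snp, model)
    cov = encode_covariates(sub, covariates)
    design = pd.concat([x.rename("genotype"), cov], axis=1).dropna()
    sub = sub.loc[design.index]
    y = (sub["status"] == "case").to_numpy(dtype=float)
    if len(design) == 0 or y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("need at least one case and one control")

    _check_separation(design, y)
    exog = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(design.columns)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {exog.shape[1]}); "
            f"columns: {names}"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ComputationError("logistic fit did not converge")
    if np.any(np.abs(res.params) > 20):
        bad = names[int(np.argmax(np.abs(res.params)))]
        raise SeparationError(f"separation suspected: term {bad!r} diverged")

    beta = float(res.params[1])
    se = float(res.bse[1])
    return EffectEstimate(
        label=f"{snp_id} {model}",
        or_hat=float(np.exp(beta)),
        se_log=se,
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=float(res.pvalues[1]),
        adjusted=bool(covariates),
        covariates=tuple(covariates),
        n_used=int(len(design)),
    )


def _check_separation(design: pd.DataFrame, y: np.ndarray) -> None:
    """Flag complete separation on any single predictor before fitting."""
    for name in design.columns:
        x = design[name].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValidationError(f"predictor {name!r} is constant")
        cases, controls = x[y == 1], x[y == 0]
        if cases.min() > controls.max() or cases.max() < controls.min():
            raise SeparationError(
                f"predictor {name!r} perfectly separates cases from controls"
            )


def crude_or_from_counts(
    counts: GenotypeCounts, model: str, correction: float = 0.0
) -> EffectEstimate:
    """Convenience: :func:`make_contrast` then :func:`crude_or`."""
    return crude_or(make_contrast(counts, model), correction=correction)
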