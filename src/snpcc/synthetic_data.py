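"""Synthetic case-control cohorts with known truth.

Two modes:

``marginal``
    Regenerates a cohort from per-group genotype/covariate distributions
    (optionally *exact*: deterministic largest-remainder rounding makes the
    tabulated genotype counts match the targets exactly).  Used to rebuild
    printed count tables as subject-level fixtures.

``causal``
    Draws a source population with HWE genotypes and independent covariates,
    assigns disease through a logistic model with known odds ratios, then
    samples cases and controls to the requested sizes.  The emitted truth
    record carries every parameter, so estimator-recovery tests can compare
    against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import IO, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    FIXED_COLUMNS,
    CohortTable,
    GenotypeCounts,
    SnpDef,
)
from .errors import ComputationError, ValidationError


@dataclass(frozen=True)
class SnpSimSpec:
    """Per-SNP simulation parameters.

    ``q`` is the control/population variant-allele frequency (HWE assumed);
    ``or_het``/``or_hom`` are disease odds ratios relative to the reference
    homozygote (causal mode).  ``case_probs``/``control_probs`` are explicit
    genotype distributions (marginal mode).
    """

    snp: SnpDef
    q: float = 0.0
    or_het: float = 1.0
    or_hom: float = 1.0
    case_probs: tuple[float, float, float] | None = None
    control_probs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValidationError(f"{self.snp.snp_id}: q must lie in [0, 1]")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValidationError(f"{self.snp.snp_id}: ORs must be positive")
        for probs in (self.case_probs, self.control_probs):
            if probs is not None and not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValidationError(f"{self.snp.snp_id}: genotype probs must sum to 1")

    @property
    def hwe_probs(self) -> tuple[float, float, float]:
        p = 1.0 - self.q
        return (p * p, 2 * p * self.q, self.q * self.q)


@dataclass(frozen=True)
class CovariateModel:
    """Category probabilities for the fixed covariate columns of one group
    (marginal mode) or of the source population (causal mode)."""

    sex: dict = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    smoking: dict = field(default_factory=lambda: {"never": 0.6, "ever": 0.4})
    # pack-years category conditional on being an ever smoker
    pack_years_ever: dict = field(
        default_factory=lambda: {"le_mean": 0.6, "gt_mean": 0.4}
    )
    drinking: dict = field(default_factory=lambda: {"never": 0.7, "ever": 0.3})
    bmi_cat: dict = field(
        default_factory=lambda: {"under": 0.05, "normal": 0.50, "high": 0.45}
    )
    age_mean: float = 60.0
    age_sd: float = 11.0
    age_range: tuple[int, int] = (25, 85)
    site: dict | None = None  # cases only
    stage: dict | None = None  # cases only


@dataclass(frozen=True)
class SimulationConfig:
    mode: str
    n_cases: int
    n_controls: int
    snps: tuple[SnpSimSpec, ...]
    covariates_case: CovariateModel = field(default_factory=CovariateModel)
    covariates_control: CovariateModel = field(default_factory=CovariateModel)
    population_covariates: CovariateModel = field(default_factory=CovariateModel)
    #: disease log-odds contributions in causal mode, keyed by indicator name
    #: (sex_male, smoking_ever, drinking_ever, bmi_under, bmi_high) or
    #: "age_per_year" (applied to age - population mean age).
    covariate_ors: dict = field(default_factory=dict)
    baseline_odds: float = 0.05
    #: (source snp_id, target snp_id, copy probability rho): the target SNP
    #: copies the source genotype index with probability rho.
    copy_pairs: tuple = ()
    #: (snp_id, indicator name, OR ratio): multiplies the carrier (dominant)
    #: genotype effect when the covariate indicator is 1.
    interactions: tuple = ()
    max_population: int = 5_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("marginal", "causal"):
            raise ValidationError("mode must be 'marginal' or 'causal'")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("group sizes must be non-negative")
        if self.baseline_odds <= 0:
            raise ValidationError("baseline_odds must be positive")
        ids = [s.snp.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp ids in simulation config")

    @property
    def snp_defs(self) -> dict[str, SnpDef]:
        return {s.snp.snp_id: s.snp for s in self.snps}

    @classmethod
    def from_margins(
        cls,
        snp_defs: dict[str, SnpDef],
        counts: dict[str, GenotypeCounts],
        margins: dict,
    ) -> "SimulationConfig":
        """Marginal-mode config from per-SNP count tables and per-group
        covariate category counts (see :func:`snpcc.datasets.covariate_margins`)."""

        def norm(d: dict) -> dict:
            total = sum(d.values())
            return {k: v / total for k, v in d.items()}

        def cov_model(group: dict, with_case_only: bool) -> CovariateModel:
            return CovariateModel(
                sex=norm(group["sex"]),
                smoking=norm(group["smoking"]),
                pack_years_ever=norm(group["pack_years_ever"]),
                drinking=norm(group["drinking"]),
                bmi_cat={
                    {"under": "under", "normal": "normal", "high": "high"}[k]: v
                    for k, v in norm(group["bmi_cat"]).items()
                },
                age_mean=group["age_mean"],
                age_sd=group["age_sd"],
                age_range=tuple(group["age_range"]),
                site=norm(group["site"]) if with_case_only and "site" in group else None,
                stage=norm(group["stage"]) if with_case_only and "stage" in group else None,
            )

        snps = tuple(
            SnpSimSpec(
                snp=snp_defs[snp_id],
                case_probs=tuple(c / sum(counts[snp_id].case) for c in counts[snp_id].case),
                control_probs=tuple(
                    c / sum(counts[snp_id].control) for c in counts[snp_id].control
                ),
            )
            for snp_id in snp_defs
        )
        return cls(
            mode="marginal",
            n_cases=margins["case"]["n"],
            n_controls=margins["control"]["n"],
            snps=snps,
            covariates_case=cov_model(margins["case"], True),
            covariates_control=cov_model(margins["control"], False),
        )

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "SimulationConfig":
        if isinstance(source, str):
            with open(source, "r", encoding="utf-8") as handle:
                raw = yaml.safe_load(handle)
        else:
            raw = yaml.safe_load(source)
        known = {
            "mode", "n_cases", "n_controls", "snps", "covariate_ors",
            "baseline_odds", "copy_pairs", "interactions", "max_population",
            "covariates_case", "covariates_control", "population_covariates",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"simulation config: unknown keys {sorted(unknown)}")
        snps = []
        for entry in raw["snps"]:
            snp = SnpDef.from_alleles(
                entry["id"],
                entry.get("gene", ""),
                entry["alleles"],
                entry.get("risk_genotypes") or [entry["alleles"].split(">")[1] * 2],
                entry.get("direction", "risk"),
            )
            snps.append(
                SnpSimSpec(
                    snp=snp,
                    q=entry.get("q", 0.0),
                    or_het=entry.get("or_het", 1.0),
                    or_hom=entry.get("or_hom", 1.0),
                    case_probs=tuple(entry["case_probs"]) if "case_probs" in entry else None,
                    control_probs=tuple(entry["control_probs"]) if "control_probs" in entry else None,
                )
            )
        cov_kwargs = {}
        for key in ("covariates_case", "covariates_control", "population_covariates"):
            if key in raw:
                spec = dict(raw[key])
                if "age_range" in spec:
                    spec["age_range"] = tuple(spec["age_range"])
                cov_kwargs[key] = CovariateModel(**spec)
        return cls(
            mode=raw["mode"],
            n_cases=raw["n_cases"],
            n_controls=raw["n_controls"],
            snps=tuple(snps),
            covariate_ors=raw.get("covariate_ors", {}),
            baseline_odds=raw.get("baseline_odds", 0.05),
            copy_pairs=tuple(tuple(p) for p in raw.get("copy_pairs", [])),
            interactions=tuple(tuple(i) for i in raw.get("interactions", [])),
            max_population=raw.get("max_population", 5_000_000),
            **cov_kwargs,
        )


# ---------------------------------------------------------------------------
# sampling helpers


def _exact_counts(probs: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder rounding of ``probs * n`` to integers summing to n."""
    raw = np.asarray(probs, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _categorical(
    rng: np.random.Generator, categories: Sequence[str], probs: Sequence[float], n: int,
    exact: bool = False,
) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=object)
    if exact:
        counts = _exact_counts(probs, n)
        column = np.repeat(np.array(categories, dtype=object), counts)
        return rng.permutation(column)
    idx = rng.choice(len(categories), size=n, p=np.asarray(probs) / np.sum(probs))
    return np.array(categories, dtype=object)[idx]


def _ages(rng: np.random.Generator, model: CovariateModel, n: int) -> np.ndarray:
    ages = rng.normal(model.age_mean, model.age_sd, size=n)
    lo, hi = model.age_range
    return np.clip(np.round(ages), lo, hi).astype(int)


def _covariate_frame(
    rng: np.random.Generator, model: CovariateModel, n: int, status: str,
    exact: bool = False,
) -> pd.DataFrame:
    sex = _categorical(rng, list(model.sex), list(model.sex.values()), n, exact)
    smoking = _categorical(rng, list(model.smoking), list(model.smoking.values()), n, exact)
    pack = np.array(["none"] * n, dtype=object)
    ever = smoking == "ever"
    n_ever = int(ever.sum())
    if n_ever:
        pack[ever] = _categorical(
            rng, list(model.pack_years_ever), list(model.pack_years_ever.values()), n_ever, exact
        )
    drinking = _categorical(rng, list(model.drinking), list(model.drinking.values()), n, exact)
    bmi = _categorical(rng, list(model.bmi_cat), list(model.bmi_cat.values()), n, exact)
    site = np.array(["not_applicable"] * n, dtype=object)
    stage = np.array(["not_applicable"] * n, dtype=object)
    if status == "case":
        if model.site:
            site = _categorical(rng, list(model.site), list(model.site.values()), n, exact)
        if model.stage:
            stage = _categorical(rng, list(model.stage), list(model.stage.values()), n, exact)
    return pd.DataFrame(
        {
            "status": status,
            "age": _ages(rng, model, n),
            "sex": sex,
            "smoking": smoking,
            "pack_years_cat": pack,
            "drinking": drinking,
            "bmi_cat": bmi,
            "site": site,
            "stage": stage,
        }
    )


def _finalize(frames: list[pd.DataFrame], cfg: SimulationConfig) -> CohortTable:
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in list(FIXED_COLUMNS[1:]) + list(cfg.snp_defs)}
    )
    df.insert(0, "subject_id", [f"S{i + 1:06d}" for i in range(len(df))])
    df = df[list(FIXED_COLUMNS) + list(cfg.snp_defs)]
    if len(df):
        df["age"] = df["age"].astype(int)
    return CohortTable(df, cfg.snp_defs)


# ---------------------------------------------------------------------------
# marginal mode


def simulate_marginal(
    cfg: SimulationConfig, seed: int, exact: bool = False
) -> CohortTable:
    """Sample genotypes and covariates independently from group-specific
    distributions.  With ``exact=True`` genotype (and categorical covariate)
    counts hit their targets exactly via deterministic rounding; columns are
    still independently permuted so no artificial joint structure appears.
    """
    if cfg.mode != "marginal":
        raise ValidationError("config mode is not 'marginal'")
    rng = np.random.default_rng(seed)
    frames = []
    for status, n, cov_model in (
        ("case", cfg.n_cases, cfg.covariates_case),
        ("control", cfg.n_controls, cfg.covariates_control),
    ):
        frame = _covariate_frame(rng, cov_model, n, status, exact)
        for spec in cfg.snps:
            probs = spec.case_probs if status == "case" else spec.control_probs
            if probs is None:
                probs = spec.hwe_probs
            frame[spec.snp.snp_id] = _categorical(
                rng, list(spec.snp.genotypes), probs, n, exact
            )
        frames.append(frame)
    return _finalize(frames, cfg)


# ---------------------------------------------------------------------------
# causal mode

_INDICATOR_COLUMNS = {
    "sex_male": ("sex", "male"),
    "smoking_ever": ("smoking", "ever"),
    "drinking_ever": ("drinking", "ever"),
    "bmi_under": ("bmi_cat", "under"),
    "bmi_high": ("bmi_cat", "high"),
    "pack_years_le": ("pack_years_cat", "le_mean"),
    "pack_years_gt": ("pack_years_cat", "gt_mean"),
}


def _indicator(frame: pd.DataFrame, key: str, pop: CovariateModel) -> np.ndarray:
    if key == "age_per_year":
        return frame["age"].to_numpy(dtype=float) - pop.age_mean
    if key not in _INDICATOR_COLUMNS:
        raise ValidationError(f"unknown covariate indicator {key!r}")
    col, value = _INDICATOR_COLUMNS[key]
    return (frame[col] == value).to_numpy(dtype=float)


def simulate_causal(
    cfg: SimulationConfig, seed: int
) -> tuple[CohortTable, dict]:
    """Draw a population, assign disease by a logistic model, and sample the
    requested numbers of cases and controls.

    Returns the cohort together with a truth record (all generating
    parameters) sufficient to predict the expected genotype margins.
    """
    if cfg.mode != "causal":
        raise ValidationError("config mode is not 'causal'")
    rng = np.random.default_rng(seed)
    pop = cfg.population_covariates
    snp_ids = list(cfg.snp_defs)
    spec_by_id = {s.snp.snp_id: s for s in cfg.snps}

    case_frames: list[pd.DataFrame] = []
    control_frames: list[pd.DataFrame] = []
    got_cases = got_controls = drawn = 0
    chunk = max(20_000, 4 * (cfg.n_cases + cfg.n_controls))

    while got_cases < cfg.n_cases or got_controls < cfg.n_controls:
        if drawn >= cfg.max_population:
            raise ComputationError(
                f"drew {drawn} individuals without reaching "
                f"{cfg.n_cases} cases / {cfg.n_controls} controls; "
                "increase max_population or baseline_odds"
            )
        n = min(chunk, cfg.max_population - drawn)
        drawn += n
        frame = _covariate_frame(rng, pop, n, "control")  # site/stage filled later
        geno_idx: dict[str, np.ndarray] = {}
        for spec in cfg.snps:
            geno_idx[spec.snp.snp_id] = rng.choice(3, size=n, p=spec.hwe_probs)
        for src, dst, rho in cfg.copy_pairs:
            copy = rng.random(n) < rho
            geno_idx[dst] = np.where(copy, geno_idx[src], geno_idx[dst])

        logit = np.full(n, math.log(cfg.baseline_odds))
        for snp_id, idx in geno_idx.items():
            spec = spec_by_id[snp_id]
            effects = np.array([0.0, math.log(spec.or_het), math.log(spec.or_hom)])
            logit += effects[idx]
        for key, or_value in cfg.covariate_ors.items():
            logit += math.log(or_value) * _indicator(frame, key, pop)
        for snp_id, key, or_ratio in cfg.interactions:
            carrier = (geno_idx[snp_id] > 0).astype(float)
            logit += math.log(or_ratio) * carrier * _indicator(frame, key, pop)

        disease = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        for snp_id, idx in geno_idx.items():
            genotypes = np.array(spec_by_id[snp_id].snp.genotypes, dtype=object)
            frame[snp_id] = genotypes[idx]

        need_cases = cfg.n_cases - got_cases
        cases = frame[disease].head(need_cases).copy()
        got_cases += len(cases)
        if len(cases):
            cases["status"] = "case"
            if pop.site:
                cases["site"] = _categorical(rng, list(pop.site), list(pop.site.values()), len(cases))
            if pop.stage:
                cases["stage"] = _categorical(rng, list(pop.stage), list(pop.stage.values()), len(cases))
            case_frames.append(cases)
        need_controls = cfg.n_controls - got_controls
        controls = frame[~disease].head(need_controls)
        got_controls += len(controls)
        if len(controls):
            control_frames.append(controls)

    cohort = _finalize(case_frames + control_frames, cfg)
    truth = {
        "mode": "causal",
        "seed": seed,
        "generator": "numpy.random.default_rng(PCG64)",
        "baseline_odds": cfg.baseline_odds,
        "n_cases": cfg.n_cases,
        "n_controls": cfg.n_controls,
        "snps": {
            s.snp.snp_id: {"q": s.q, "or_het": s.or_het, "or_hom": s.or_hom}
            for s in cfg.snps
        },
        "covariate_ors": dict(cfg.covariate_ors),
        "copy_pairs": [list(p) for p in cfg.copy_pairs],
        "interactions": [list(i) for i in cfg.interactions],
        "population_drawn": drawn,
    }
    return cohort, truth


def expected_case_genotype_probs(spec: SnpSimSpec) -> tuple[float, float, float]:
    """Rare-disease approximation of the case genotype distribution implied
    by a causal truth record: P(g | case) proportional to HWE(q) * OR_g."""
    weights = np.array(spec.hwe_probs) * np.array([1.0, spec.or_het, spec.or_hom])
    weights /= weights.sum()
    return tuple(float(w) for w in weights)


def null_dominant_pvalues(
    n_cases: int, n_controls: int, q: float, n_reps: int, seed: int
) -> np.ndarray:
    """Vectorized null calibration: chi-square p-values of the dominant 2x2
    contrast across replicate cohorts drawn under no association.

    Under the null, causal-mode genotype margins in each group reduce to iid
    HWE multinomials, which is what is drawn here (this is the fast path for
    type-I-error studies; subject-level simulation gives the same law).
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    p = 1.0 - q
    probs = (p * p, 2 * p * q, q * q)
    case = rng.multinomial(n_cases, probs, size=n_reps)
    ctrl = rng.multinomial(n_controls, probs, size=n_reps)
    a = case[:, 1] + case[:, 2]
    b = case[:, 0]
    c = ctrl[:, 1] + ctrl[:, 2]
    d = ctrl[:, 0]
    n = a + b + c + d
    num = n * (a * d - b * c).astype(float) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)
    return stats.chi2.sf(chi2, df=1)
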