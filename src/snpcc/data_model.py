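"""Domain types and subject-table I/O for case-control SNP studies.

The subject table is a one-row-per-participant TSV with a fixed covariate
header followed by one column per SNP holding a two-letter genotype or
``NA``.  Heterozygotes are canonicalized to alphabetical allele order
(``CT``, never ``TC``), matching how published genotype tables label them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ValidationError

STATUS_VALUES = ("case", "control")
SEX_VALUES = ("male", "female")
SMOKING_VALUES = ("never", "ever")
PACK_YEARS_VALUES = ("none", "le_mean", "gt_mean")
DRINKING_VALUES = ("never", "ever")
BMI_VALUES = ("under", "normal", "high")
SITE_VALUES = ("cardia", "non_cardia", "not_applicable")
STAGE_VALUES = ("I_II", "III_IV", "not_applicable")

#: Fixed leading columns of the subject TSV, in order.
FIXED_COLUMNS = (
    "subject_id",
    "status",
    "age",
    "sex",
    "smoking",
    "pack_years_cat",
    "drinking",
    "bmi_cat",
    "site",
    "stage",
)

_CATEGORY_DOMAINS = {
    "status": STATUS_VALUES,
    "sex": SEX_VALUES,
    "smoking": SMOKING_VALUES,
    "pack_years_cat": PACK_YEARS_VALUES,
    "drinking": DRINKING_VALUES,
    "bmi_cat": BMI_VALUES,
    "site": SITE_VALUES,
    "stage": STAGE_VALUES,
}

MISSING = "NA"

#: Genetic-model contrast names accepted by :func:`make_contrast`.
MODELS = ("het_vs_ref", "hom_vs_ref", "dominant", "recessive")


@dataclass(frozen=True)
class SnpDef:
    """A SNP's identity, alleles, and which genotypes count as "risk".

    Parameters
    ----------
    snp_id:
        dbSNP-style identifier, e.g. ``"rs2294008"``.
    gene:
        Gene label for reporting.
    allele_ref, allele_var:
        Single-character alleles; the reference homozygote is
        ``allele_ref * 2``.
    risk_genotypes:
        Non-empty subset of the three genotypes counted as "risk" when
        profiling subjects.
    direction:
        ``"risk"`` or ``"protective"``; selects the target odds ratio
        (1.50 vs 0.67) in FPRP power calculations.
    """

    snp_id: str
    gene: str
    allele_ref: str
    allele_var: str
    risk_genotypes: frozenset = field(default_factory=frozenset)
    direction: str = "risk"

    def __post_init__(self) -> None:
        for allele in (self.allele_ref, self.allele_var):
            if len(allele) != 1 or not allele.isalpha():
                raise ValidationError(
                    f"{self.snp_id}: allele {allele!r} must be one letter"
                )
        if self.allele_ref == self.allele_var:
            raise ValidationError(f"{self.snp_id}: alleles must differ")
        if self.direction not in ("risk", "protective"):
            raise ValidationError(
                f"{self.snp_id}: direction must be 'risk' or 'protective'"
            )
        object.__setattr__(self, "risk_genotypes", frozenset(self.risk_genotypes))
        if not self.risk_genotypes:
            raise ValidationError(f"{self.snp_id}: risk_genotypes is empty")
        bad = self.risk_genotypes - set(self.genotypes)
        if bad:
            raise ValidationError(
                f"{self.snp_id}: risk genotypes {sorted(bad)} are not among "
                f"{list(self.genotypes)}"
            )

    @property
    def reference_genotype(self) -> str:
        return self.allele_ref * 2

    @property
    def het_genotype(self) -> str:
        # alphabetical, matching printed table row labels (AG for G>A, CT for T>C)
        return "".join(sorted((self.allele_ref, self.allele_var)))

    @property
    def variant_genotype(self) -> str:
        return self.allele_var * 2

    @property
    def genotypes(self) -> tuple[str, str, str]:
        """(reference homozygote, heterozygote, variant homozygote)."""
        return (self.reference_genotype, self.het_genotype, self.variant_genotype)

    def canonical_genotype(self, raw: str) -> str:
        """Normalize a two-letter genotype string (``TC`` -> ``CT``).

        Raises :class:`ValidationError` naming the offending allele if the
        string contains a letter that is not one of this SNP's alleles.
        """
        if len(raw) != 2:
            raise ValidationError(
                f"{self.snp_id}: genotype {raw!r} must be two letters"
            )
        valid = {self.allele_ref, self.allele_var}
        for allele in raw:
            if allele not in valid:
                raise ValidationError(
                    f"{self.snp_id}: allele {allele!r} in genotype {raw!r} is not "
                    f"one of {sorted(valid)}"
                )
        if raw[0] == raw[1]:
            return raw
        return self.het_genotype

    @classmethod
    def from_alleles(
        cls,
        snp_id: str,
        gene: str,
        alleles: str,
        risk_genotypes: Sequence[str],
        direction: str = "risk",
    ) -> "SnpDef":
        """Build from a ``"C>T"``-style allele string."""
        parts = alleles.split(">")
        if len(parts) != 2:
            raise ValidationError(f"{snp_id}: alleles {alleles!r} must look like 'C>T'")
        ref, var = (p.strip() for p in parts)
        return cls(snp_id, gene, ref, var, frozenset(risk_genotypes), direction)


def load_snp_config(source: str | IO[str]) -> dict[str, SnpDef]:
    """Read a YAML/JSON SNP configuration into an ordered mapping.

    Each entry needs ``id``, ``gene``, ``alleles`` ("C>T"), ``risk_genotypes``
    and optionally ``direction`` (default "risk").
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, list):
        raise ValidationError("SNP config must be a list of SNP entries")
    defs: dict[str, SnpDef] = {}
    for entry in raw:
        unknown = set(entry) - {"id", "gene", "alleles", "risk_genotypes", "direction"}
        if unknown:
            raise ValidationError(f"SNP config: unknown keys {sorted(unknown)}")
        snp = SnpDef.from_alleles(
            entry["id"],
            entry.get("gene", ""),
            entry["alleles"],
            entry["risk_genotypes"],
            entry.get("direction", "risk"),
        )
        if snp.snp_id in defs:
            raise ValidationError(f"SNP config: duplicate id {snp.snp_id}")
        defs[snp.snp_id] = snp
    return defs


def dump_snp_config(snp_defs: Mapping[str, SnpDef], stream: IO[str]) -> None:
    """Inverse of :func:`load_snp_config`."""
    entries = [
        {
            "id": snp.snp_id,
            "gene": snp.gene,
            "alleles": f"{snp.allele_ref}>{snp.allele_var}",
            "risk_genotypes": sorted(snp.risk_genotypes),
            "direction": snp.direction,
        }
        for snp in snp_defs.values()
    ]
    yaml.safe_dump(entries, stream, sort_keys=False)


@dataclass(frozen=True)
class Subject:
    """One study participant."""

    subject_id: str
    status: str
    age: int
    sex: str
    smoking: str
    pack_years_cat: str
    drinking: str
    bmi_cat: str
    site: str
    stage: str
    genotypes: Mapping[str, str | None] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class CohortTable:
    """Subject-level records backed by a validated DataFrame.

    Columns are :data:`FIXED_COLUMNS` followed by one column per SNP id in
    ``snp_defs`` order; missing genotypes are ``None``.
    """

    df: pd.DataFrame
    snp_defs: dict[str, SnpDef]

    def __post_init__(self) -> None:
        expected = list(FIXED_COLUMNS) + list(self.snp_defs)
        if list(self.df.columns) != expected:
            raise ValidationError(
                f"cohort columns {list(self.df.columns)} != expected {expected}"
            )
        ids = self.df["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == "control").sum())

    def subjects(self) -> Iterator[Subject]:
        snp_ids = list(self.snp_defs)
        for row in self.df.itertuples(index=False):
            record = row._asdict()
            genotypes = {s: record.pop(s) for s in snp_ids}
            yield Subject(genotypes=genotypes, **record)

    def write_tsv(self, stream: IO[str]) -> None:
        out = self.df.copy()
        for snp_id in self.snp_defs:
            out[snp_id] = out[snp_id].fillna(MISSING)
        out.to_csv(stream, sep="\t", index=False, lineterminator="\n")


def read_subject_table(source: str | IO[str], snp_defs: Mapping[str, SnpDef]) -> CohortTable:
    """Parse a subject TSV, validating every cell.

    Missing genotypes (``NA``) are kept as missing, not dropped.  Errors name
    the offending data row (1-based, excluding the header).
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as handle:
            return read_subject_table(handle, snp_defs)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    expected = list(FIXED_COLUMNS) + list(snp_defs)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValidationError(f"unknown column(s): {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing column(s): {missing_cols}")
    df = df[expected]

    seen: set[str] = set()
    rows: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        record = row._asdict()
        sid = record["subject_id"]
        if sid in seen:
            raise ValidationError(f"row {i}: duplicate subject_id {sid!r}")
        seen.add(sid)
        for col, domain in _CATEGORY_DOMAINS.items():
            if record[col] not in domain:
                raise ValidationError(
                    f"row {i}: {col}={record[col]!r} not in {list(domain)}"
                )
        try:
            record["age"] = int(record["age"])
        except ValueError:
            raise ValidationError(f"row {i}: age {record['age']!r} is not an integer")
        if record["status"] == "control" and (
            record["site"] != "not_applicable" or record["stage"] != "not_applicable"
        ):
            raise ValidationError(f"row {i}: controls must have site/stage not_applicable")
        for snp_id, snp in snp_defs.items():
            raw = record[snp_id]
            if raw == MISSING or raw == "":
                record[snp_id] = None
            else:
                try:
                    record[snp_id] = snp.canonical_genotype(raw)
                except ValidationError as exc:
                    raise ValidationError(f"row {i}: {exc}") from None
        rows.append(record)

    clean = pd.DataFrame(rows, columns=expected) if rows else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in expected}
    )
    if rows:
        clean["age"] = clean["age"].astype(int)
    return CohortTable(clean, dict(snp_defs))


def write_subject_table(cohort: CohortTable, stream: IO[str]) -> None:
    cohort.write_tsv(stream)


@dataclass(frozen=True)
class GenotypeCounts:
    """2x3 genotype count table for one SNP (case/control x ref-hom, het, var-hom)."""

    snp_id: str
    case: tuple[int, int, int]
    control: tuple[int, int, int]
    labels: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        for triple in (self.case, self.control):
            if len(triple) != 3 or any(
                (not float(x).is_integer()) or x < 0 for x in triple
            ):
                raise ValidationError(f"{self.snp_id}: counts must be 3 non-negative integers")

    @property
    def n_cases(self) -> int:
        return int(sum(self.case))

    @property
    def n_controls(self) -> int:
        return int(sum(self.control))

    @property
    def grand_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-status table behind every printed odds ratio.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls.
    """

    a: int
    b: int
    c: int
    d: int
    exposed_label: str = "exposed"
    unexposed_label: str = "unexposed"

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise ValidationError("2x2 cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def swapped(self) -> "TwoByTwo":
        """Exchange the exposed and unexposed categories."""
        return TwoByTwo(
            self.b, self.a, self.d, self.c, self.unexposed_label, self.exposed_label
        )


def tabulate_genotypes(cohort: CohortTable, snp_id: str) -> GenotypeCounts:
    """Complete-case 2x3 genotype counts for one SNP.

    Subjects missing this SNP's genotype are excluded from both margins.
    """
    if snp_id not in cohort.snp_defs:
        raise ValidationError(f"unknown snp_id {snp_id!r}")
    snp = cohort.snp_defs[snp_id]
    sub = cohort.df[["status", snp_id]].dropna(subset=[snp_id])

    def triple(status: str) -> tuple[int, int, int]:
        col = sub.loc[sub["status"] == status, snp_id]
        return tuple(int((col == g).sum()) for g in snp.genotypes)

    return GenotypeCounts(snp_id, triple("case"), triple("control"), snp.genotypes)


def counts_from_percentages(
    total: int, percentages: Sequence[float]
) -> tuple[int, ...]:
    """Recover integer counts from a printed total and percentage column.

    Each count is ``round(pct/100 * total)`` (half away from zero).  If the
    rounded counts do not add back to ``total`` the call fails, listing
    single-cell corrections that would fix the sum — this is the tool used
    to resolve internally inconsistent printed tables.
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    raw = [pct / 100.0 * total for pct in percentages]
    counts = tuple(int(math.floor(x + 0.5)) for x in raw)
    diff = total - sum(counts)
    if diff != 0:
        candidates = [
            f"{counts[i]}->{counts[i] + diff} in cell {i}" for i in range(len(counts))
        ]
        raise ValidationError(
            f"rounded counts {counts} sum to {sum(counts)} != total {total}; "
            f"candidate corrections: {candidates}"
        )
    return counts


def make_contrast(counts: GenotypeCounts, model: str) -> TwoByTwo:
    """Collapse a 2x3 genotype table into the 2x2 behind a genetic-model OR.

    ``dominant`` pools het + variant homozygote as exposed; ``recessive``
    pools reference homozygote + het as unexposed; ``het_vs_ref`` and
    ``hom_vs_ref`` drop the third genotype.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    labels = counts.labels or ("ref", "het", "hom")
    (r1, h1, v1), (r0, h0, v0) = counts.case, counts.control
    if model == "het_vs_ref":
        return TwoByTwo(h1, r1, h0, r0, labels[1], labels[0])
    if model == "hom_vs_ref":
        return TwoByTwo(v1, r1, v0, r0, labels[2], labels[0])
    if model == "dominant":
        return TwoByTwo(
            h1 + v1, r1, h0 + v0, r0, f"{labels[1]}/{labels[2]}", labels[0]
        )
    return TwoByTwo(v1, r1 + h1, v0, r0 + h0, labels[2], f"{labels[0]}/{labels[1]}")
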