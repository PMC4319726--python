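"""Hardy-Weinberg equilibrium goodness-of-fit testing.

The default test is the 1-df chi-square comparing observed genotype counts
with (p^2, 2pq, q^2) expectations at the estimated variant-allele frequency,
with no continuity correction.  An exact (conditional on allele counts) test
is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class HweResult:
    snp_id: str
    q: float
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float


def allele_frequency(counts: Sequence[int]) -> float:
    """Variant-allele frequency q = (het + 2*var-hom) / (2*total)."""
    _validate_triple(counts)
    n = sum(counts)
    if n == 0:
        raise ValidationError("allele frequency undefined for an empty group")
    return (counts[1] + 2 * counts[2]) / (2 * n)


def hwe_chisq(counts: Sequence[int], snp_id: str = "") -> HweResult:
    """1-df chi-square goodness-of-fit test against HWE expectations.

    Degenerate monomorphic tables (q in {0, 1}) return chi2 = 0, p = 1 by
    convention.
    """
    _validate_triple(counts)
    n = sum(counts)
    if n == 0:
        raise ValidationError("HWE test undefined for an empty group")
    q = allele_frequency(counts)
    p_allele = 1.0 - q
    expected = (n * p_allele**2, n * 2 * p_allele * q, n * q**2)
    if q == 0.0 or q == 1.0:
        return HweResult(snp_id, q, expected, 0.0, 1, 1.0)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, q, expected, float(chi2), 1, p)


def hwe_exact(counts: Sequence[int]) -> float:
    """Exact HWE p-value conditional on the observed allele counts.

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one (the standard exact formulation; not the default —
    the chi-square form is what published p-values use).
    """
    _validate_triple(counts)
    n = sum(counts)
    if n == 0:
        raise ValidationError("HWE test undefined for an empty group")
    n_var = counts[1] + 2 * counts[2]  # variant allele count
    n_het_obs = counts[1]

    def log_prob(n_het: int) -> float:
        n_hom_var = (n_var - n_het) // 2
        n_hom_ref = n - n_het - n_hom_var
        return (
            math.lgamma(n + 1)
            - math.lgamma(n_hom_ref + 1)
            - math.lgamma(n_het + 1)
            - math.lgamma(n_hom_var + 1)
            + n_het * math.log(2)
            + math.lgamma(n_var + 1)
            + math.lgamma(2 * n - n_var + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_var % 2, min(n_var, 2 * n - n_var) + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_het_obs]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))))


def _validate_triple(counts: Sequence[int]) -> None:
    if len(counts) != 3:
        raise ValidationError("expected a (ref-hom, het, var-hom) triple")
    if any(c < 0 for c in counts):
        raise ValidationError("genotype counts must be non-negative")
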