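"""Qualifying-variant selection and exact carrier-burden enrichment.

The gene-burden question asked here: is the fraction of kindreds in a
disease cohort carrying at least one ultra-rare, protein-altering,
predicted-damaging allele of a gene higher than expected from the carrier
frequency of equally qualifying alleles in a population reference
(gnomAD)?  The unit of counting is the kindred — a family counts once no
matter how many qualifying alleles, variants or affected members it has.

The test is the exact one-sided binomial: with ``k`` carrier kindreds out
of ``n`` and a background carrier probability ``p0``,

    p = P(X >= k | X ~ Binomial(n, p0))

computed by direct summation of the point masses on the log scale.  A
Fisher-exact alternative against raw reference carrier counts is provided
for situations where ``p0`` itself comes from a finite sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CONSEQUENCES",
    "PROTEIN_ALTERING",
    "VariantRecord",
    "FilterCriteria",
    "BurdenResult",
    "allele_frequency",
    "format_scientific",
    "select_qualifying",
    "cohort_carrier_count",
    "background_carrier_frequency",
    "burden_test",
    "fisher_burden_test",
]

#: Recognised consequence classes for a coding (or near-coding) variant.
PROTEIN_ALTERING = frozenset({"missense", "inframe_indel", "frameshift", "stop_gain"})
CONSEQUENCES = PROTEIN_ALTERING | {"synonymous", "non_coding"}


@dataclass(frozen=True)
class VariantRecord:
    """One observed coding variant with its population-reference counts.

    ``allele_count``/``allele_number`` are the reference (gnomAD-style)
    alternate-allele count and total called alleles; a variant absent from
    the reference is encoded as ``allele_count=0`` with a valid
    ``allele_number``, giving frequency 0.
    """

    gene: str
    coding_change: str
    protein_change: str
    consequence: str
    allele_count: int
    allele_number: int
    homozygote_count: int = 0

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; "
                f"expected one of {sorted(CONSEQUENCES)}"
            )
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("require 0 <= allele_count <= allele_number")
        if self.homozygote_count < 0 or 2 * self.homozygote_count > self.allele_count:
            raise ValueError("require 0 <= 2*homozygote_count <= allele_count")

    @property
    def frequency(self) -> float:
        return allele_frequency(self.allele_count, self.allele_number)


@dataclass(frozen=True)
class FilterCriteria:
    """Qualifying-variant filter: ultra-rare, protein-altering, damaging.

    ``max_maf`` is a strict upper bound (a variant at exactly the
    threshold does not qualify).  ``min_damage_score`` is inclusive and
    only applied when damage scores are supplied to
    :func:`select_qualifying`.
    """

    max_maf: float = 1e-5
    qualifying_consequences: frozenset = field(default=PROTEIN_ALTERING)
    min_damage_score: float | None = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.max_maf < 1:
            raise ValueError("max_maf must lie in (0, 1)")
        unknown = set(self.qualifying_consequences) - CONSEQUENCES
        if unknown:
            raise ValueError(f"unknown consequences in filter: {sorted(unknown)}")


@dataclass(frozen=True)
class BurdenResult:
    carriers_cohort: int
    units_cohort: int
    carrier_freq_cohort: float
    carrier_freq_background: float
    fold_enrichment: float
    p_value: float


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """Population alternate-allele frequency AC/AN.

    ``allele_number == 0`` is an error — absence from the reference must be
    encoded as count 0 over a valid total, which yields frequency 0.
    """
    if allele_number <= 0:
        raise ValueError("allele frequency undefined for allele_number <= 0")
    if allele_count < 0 or allele_count > allele_number:
        raise ValueError("require 0 <= allele_count <= allele_number")
    return allele_count / allele_number


def format_scientific(value: float, sig: int = 1) -> str:
    """Render a frequency the way cohort papers print it, e.g. ``5 × 10^-6``."""
    if value == 0:
        return "0"
    exponent = math.floor(math.log10(abs(value)))
    mantissa = round(value / 10**exponent, sig - 1)
    if abs(mantissa) >= 10:  # rounding pushed us up an order of magnitude
        mantissa /= 10
        exponent += 1
    mantissa_str = f"{mantissa:.{max(sig - 1, 0)}f}".rstrip("0").rstrip(".")
    return f"{mantissa_str} × 10^{exponent}"


def select_qualifying(
    variants: Sequence[VariantRecord],
    criteria: FilterCriteria | None = None,
    damage_scores: Mapping[tuple[str, str], float] | None = None,
) -> list[VariantRecord]:
    """Apply the qualifying filter, preserving input order.

    A variant is kept iff its reference allele frequency is strictly below
    ``criteria.max_maf``, its consequence is in the qualifying set, and —
    when ``damage_scores`` is provided and ``min_damage_score`` set — its
    combined damage score (keyed by ``(gene, protein_change)``) is at
    least the threshold.  A requested-but-missing damage annotation is an
    error, never a silent pass.
    """
    criteria = criteria or FilterCriteria()
    kept: list[VariantRecord] = []
    for v in variants:
        if v.frequency >= criteria.max_maf:
            continue
        if v.consequence not in criteria.qualifying_consequences:
            continue
        if damage_scores is not None and criteria.min_damage_score is not None:
            key = (v.gene, v.protein_change)
            if key not in damage_scores:
                raise KeyError(
                    f"damage score missing for variant {v.gene} {v.protein_change}"
                )
            if damage_scores[key] < criteria.min_damage_score:
                continue
        kept.append(v)
    return kept


def cohort_carrier_count(genotypes: pd.DataFrame) -> tuple[int, int]:
    """Count carrier kindreds.

    ``genotypes`` is a kindred × variant matrix of qualifying-allele
    counts (0 = none in the kindred, 1 = at least one heterozygote,
    2 = homozygote).  A kindred is a carrier if any entry is positive; it
    is counted once regardless of zygosity or how many distinct
    qualifying variants it holds.
    """
    if genotypes.shape[0] == 0:
        raise ValueError("kindred set is empty")
    mat = genotypes.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("negative allele counts in genotype matrix")
    k = int((mat > 0).any(axis=1).sum())
    return k, int(genotypes.shape[0])


def background_carrier_frequency(
    variants: Sequence[VariantRecord],
    criteria: FilterCriteria | None = None,
    damage_scores: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Cumulative carrier probability of the qualifying reference alleles.

    Each qualifying variant at allele frequency p contributes a
    Hardy–Weinberg carrier probability c = 2p(1-p) + p²; assuming
    independent loci the probability of carrying at least one is
    1 - Π(1 - cᵢ), computed through log1p for numerical robustness.  For
    ultra-rare alleles this is ≈ Σ 2pᵢ.
    """
    qualifying = select_qualifying(variants, criteria, damage_scores)
    if not qualifying:
        warnings.warn("no qualifying reference variants; background frequency is 0")
        return 0.0
    p = np.array([v.frequency for v in qualifying], dtype=float)
    carrier = 2.0 * p * (1.0 - p) + p**2
    return float(-np.expm1(np.sum(np.log1p(-carrier))))


def _log_binom_tail(k: int, n: int, p0: float) -> float:
    """log P(X >= k) for X ~ Binomial(n, p0), by direct summation."""
    if k <= 0:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(logsumexp(stats.binom.logpmf(ks, n, p0)))


def burden_test(k: int, n: int, p0: float) -> BurdenResult:
    """Exact one-sided binomial carrier-burden test.

    Parameters
    ----------
    k, n : int
        Carrier kindreds and total kindreds in the cohort.
    p0 : float
        Background carrier probability, strictly inside (0, 1).
    """
    if not 0 < p0 < 1:
        raise ValueError("background carrier probability must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    p_value = float(np.exp(_log_binom_tail(k, n, p0)))
    p_value = min(p_value, 1.0)
    freq = k / n
    return BurdenResult(
        carriers_cohort=k,
        units_cohort=n,
        carrier_freq_cohort=freq,
        carrier_freq_background=p0,
        fold_enrichment=freq / p0,
        p_value=p_value,
    )


def fisher_burden_test(
    k: int, n: int, background_carriers: int, background_total: int
) -> tuple[float, float]:
    """One-sided Fisher exact alternative against reference carrier counts.

    Returns ``(odds_ratio, p_value)``.  Useful when the background carrier
    frequency is itself an estimate from a finite reference sample rather
    than a fixed probability.
    """
    table = [
        [k, n - k],
        [background_carriers, background_total - background_carriers],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)
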