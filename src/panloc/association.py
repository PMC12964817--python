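"""Carrier/phenotype tabulation, exact association testing, dominance checks.

The association between a structural-variant allele and a binary phenotype
(here: white vs. colored head) is quantified with Fisher's exact test on
the 2x2 carrier-by-phenotype table, computed by exact integer enumeration
over the hypergeometric support, plus a dominance-concordance statistic:
the fraction of samples where carrying at least one copy coincides with
the dominant phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "BreedSummary",
    "breed_carrier_summary",
    "fisher_exact_two_sided",
    "dominance_concordance",
    "carrier_phenotype_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d — rows are one factor, columns the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    p_value: float
    odds_ratio: float
    haldane_corrected: bool
    table: ContingencyTable2x2


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    (a, b), (c, d) = table
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


@lru_cache(maxsize=100_000)
def _support_numerators(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...]]:
    """Hypergeometric numerators C(r1,k)·C(r2,c1−k) over the support.

    Returns ``(kmin, numerators)``; the common denominator is C(r1+r2, c1).
    Computed with an exact integer recurrence, so probability comparisons
    between tables reduce to integer comparisons with no floating point.
    """
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    nums = []
    v = comb(r1, kmin) * comb(r2, c1 - kmin)
    for k in range(kmin, kmax + 1):
        nums.append(v)
        if k < kmax:
            v = v * (r1 - k) * (c1 - k) // ((k + 1) * (r2 - c1 + k + 1))
    return kmin, tuple(nums)


def fisher_exact_two_sided(table) -> AssociationResult:
    """Two-sided Fisher exact test by full enumeration over the support.

    The p-value sums the probabilities of all tables (with the observed
    margins) whose point probability does not exceed the observed table's —
    the standard minimum-likelihood two-sided rule, with probabilities
    within a 1e-7 relative tolerance of the observed one counted as ties
    (so near-equal probabilities are handled identically everywhere). All
    arithmetic is exact integer/rational, so the result is bit-identical
    across platforms.

    The odds ratio is ad/bc, with the Haldane–Anscombe +0.5 correction
    applied (and flagged) when any cell is zero.
    """
    t = _as_table(table)
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    kmin, nums = _support_numerators(r1, r2, c1)
    obs = nums[t.a - kmin]
    # num <= obs * (1 + 1e-7), evaluated in exact integer arithmetic
    p = Fraction(
        sum(n for n in nums if n * 10_000_000 <= obs * 10_000_001),
        comb(r1 + r2, c1),
    )
    if 0 in (t.a, t.b, t.c, t.d):
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        odds, haldane = (a * d) / (b * c), True
    else:
        odds, haldane = (t.a * t.d) / (t.b * t.c), False
    return AssociationResult(
        p_value=min(1.0, float(p)),
        odds_ratio=odds,
        haldane_corrected=haldane,
        table=t,
    )


@dataclass
class BreedSummary:
    """Per-breed carrier counts plus totals per phenotype group."""

    per_breed: pd.DataFrame  # breed, phenotype, n_assemblies, n_carriers
    totals: pd.DataFrame  # phenotype, n_assemblies, n_carriers

    def group_total(self, phenotype: str) -> tuple[int, int]:
        row = self.totals.loc[self.totals["phenotype"] == phenotype]
        if row.empty:
            return 0, 0
        return int(row["n_assemblies"].iloc[0]), int(row["n_carriers"].iloc[0])


def breed_carrier_summary(
    carriers: Mapping[str, bool],
    phenotypes: pd.DataFrame,
) -> BreedSummary:
    """Tabulate carriers per breed and per phenotype group.

    ``phenotypes`` must hold one row per sample with columns ``sample``,
    ``breed`` and ``phenotype``; every sample in ``carriers`` must appear
    there. Each assembly/sample counts once.
    """
    pheno = phenotypes.set_index("sample")
    missing = sorted(set(carriers) - set(pheno.index))
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing}")
    if not carriers:
        empty = pd.DataFrame(columns=["breed", "phenotype", "n_assemblies", "n_carriers"])
        totals = pd.DataFrame(columns=["phenotype", "n_assemblies", "n_carriers"])
        return BreedSummary(per_breed=empty, totals=totals)
    df = pd.DataFrame(
        {
            "sample": list(carriers),
            "carrier": [bool(carriers[s]) for s in carriers],
        }
    )
    df["breed"] = df["sample"].map(pheno["breed"])
    df["phenotype"] = df["sample"].map(pheno["phenotype"])
    per_breed = (
        df.groupby(["breed", "phenotype"], as_index=False)
        .agg(n_assemblies=("sample", "size"), n_carriers=("carrier", "sum"))
        .sort_values(["phenotype", "breed"], ignore_index=True)
    )
    totals = (
        df.groupby("phenotype", as_index=False)
        .agg(n_assemblies=("sample", "size"), n_carriers=("carrier", "sum"))
        .sort_values("phenotype", ignore_index=True)
    )
    return BreedSummary(per_breed=per_breed, totals=totals)


def carrier_phenotype_table(
    carriers: Mapping[str, bool],
    phenotypes: Mapping[str, str],
    positive_phenotype: str = "white",
) -> ContingencyTable2x2:
    """Build the carrier-by-phenotype 2x2 table (a = carrier & positive)."""
    a = b = c = d = 0
    for sample, is_carrier in carriers.items():
        positive = phenotypes[sample] == positive_phenotype
        if is_carrier and positive:
            a += 1
        elif is_carrier:
            b += 1
        elif positive:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def dominance_concordance(
    genotypes: Mapping[str, str],
    phenotypes: Mapping[str, str],
    positive_phenotype: str = "white",
) -> tuple[float, list[str]]:
    """Fraction of samples where (genotype != absent) <=> (phenotype positive).

    Under a dominant allele a single carried copy suffices for the
    phenotype, so carriers should be exactly the positive-phenotype
    samples. Returns the concordant fraction and the discordant sample
    names. An empty cohort is an error (the fraction is undefined).
    """
    if not genotypes:
        raise ValueError("empty cohort: dominance concordance undefined")
    missing = sorted(set(genotypes) - set(phenotypes))
    if missing:
        raise ValueError(f"samples missing phenotypes: {missing}")
    discordant = [
        s
        for s, g in genotypes.items()
        if (g != "absent") != (phenotypes[s] == positive_phenotype)
    ]
    return 1.0 - len(discordant) / len(genotypes), discordant
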