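"""Published worked-example data: the five-proband UNC93B1 cohort.

Encodes the five rare missense substitutions reported across 63 SLE/CBL
kindreds — their gnomAD v4 allele counts, combined VEP damage scores and
per-kindred zygosities — as a small interface fixture.  Only L330R is
present in gnomAD (8/1,552,226 alleles); the other four are absent and
encoded as count 0 over the same allele number.  The background carrier
frequency of qualifying gnomAD alleles (0.4%) enters as a given
probability.
"""

from __future__ import annotations

import pandas as pd

from .variant_burden import VariantRecord

__all__ = [
    "GNOMAD_AN",
    "BACKGROUND_CARRIER_FREQ",
    "N_KINDREDS",
    "proband_variants",
    "proband_damage_scores",
    "cohort_genotypes",
]

GNOMAD_AN = 1_552_226
#: Cumulative carrier frequency of qualifying alleles in gnomAD v4.
BACKGROUND_CARRIER_FREQ = 0.004
N_KINDREDS = 63

_PROBANDS = [
    # (kindred, coding, protein, zygosity, gnomad AC)
    ("AGS1861", "c.1574_1575delinsCT", "p.(Arg525Pro)", 1, 0),
    ("AGS2568", "c.989T>G", "p.(Leu330Arg)", 1, 8),
    ("AGS2650", "c.951C>G", "p.(Ile317Met)", 2, 0),
    ("AGS2672", "c.1398A>C", "p.(Arg466Ser)", 1, 0),
    ("AGS2898", "c.973G>T", "p.(Gly325Cys)", 1, 0),
]

_DAMAGE = {
    "p.(Arg525Pro)": 0.81,
    "p.(Leu330Arg)": 0.93,
    "p.(Ile317Met)": 0.70,
    "p.(Arg466Ser)": 0.86,
    "p.(Gly325Cys)": 0.93,
}


def proband_variants() -> list[VariantRecord]:
    """The five proband variants with their reference counts."""
    return [
        VariantRecord(
            gene="UNC93B1",
            coding_change=coding,
            protein_change=protein,
            consequence="missense",
            allele_count=ac,
            allele_number=GNOMAD_AN,
            homozygote_count=0,
        )
        for _, coding, protein, _, ac in _PROBANDS
    ]


def proband_damage_scores() -> dict[tuple[str, str], float]:
    """Combined VEP damage scores keyed by (gene, protein_change)."""
    return {("UNC93B1", p): s for p, s in _DAMAGE.items()}


def cohort_genotypes() -> pd.DataFrame:
    """Kindred × variant qualifying-allele counts for the 63-kindred cohort.

    Five kindreds each carry one variant (one of them homozygous); the
    remaining 58 carry none.
    """
    kindreds = [k for k, *_ in _PROBANDS] + [f"K{i + 1:03d}" for i in range(N_KINDREDS - 5)]
    variants = [protein for _, _, protein, _, _ in _PROBANDS]
    geno = pd.DataFrame(0, index=pd.Index(kindreds, name="kindred"), columns=variants)
    for kindred, _, protein, zygosity, _ in _PROBANDS:
        geno.loc[kindred, protein] = zygosity
    return geno
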