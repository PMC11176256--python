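"""File-format glue: minimal VCF, TSV tables, ground-truth sidecars.

Variant tables travel as minimal VCF v4.2 (1-based positions, INFO keys
AC/AN/nhomalt plus GENE/CSQ/HGVSC/HGVSP annotations) or as tidy TSV;
everything else is TSV with documented headers.  Ground-truth sidecars
from the simulators are YAML.
"""

from __future__ import annotations

from pathlib import Path
import pandas as pd
import yaml

from .variant_burden import VariantRecord

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">
##INFO=<ID=nhomalt,Number=1,Type=Integer,Description="Homozygous-alternate individuals">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="Coding HGVS">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein HGVS">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as minimal VCF v4.2.

    Expects columns chrom, pos, variant_id, ref, alt, gene, coding_change,
    protein_change, consequence, allele_count, allele_number,
    homozygote_count.
    """
    lines = [VCF_HEADER]
    for row in variants.itertuples(index=False):
        info = (
            f"AC={row.allele_count};AN={row.allele_number};"
            f"nhomalt={row.homozygote_count};GENE={row.gene};CSQ={row.consequence};"
            f"HGVSC={row.coding_change};HGVSP={row.protein_change}"
        )
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF back into the tidy variant-table layout."""
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "variant_id": rec.ID,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "gene": rec.INFO.get("GENE"),
                "coding_change": rec.INFO.get("HGVSC"),
                "protein_change": rec.INFO.get("HGVSP"),
                "consequence": rec.INFO.get("CSQ"),
                "allele_count": int(rec.INFO.get("AC", 0)),
                "allele_number": int(rec.INFO.get("AN", 0)),
                "homozygote_count": int(rec.INFO.get("nhomalt", 0)),
            }
        )
    return pd.DataFrame(rows)


def variant_records(table: pd.DataFrame) -> list[VariantRecord]:
    """Convert a tidy variant table into validated VariantRecord objects."""
    return [
        VariantRecord(
            gene=row.gene,
            coding_change=row.coding_change,
            protein_change=row.protein_change,
            consequence=row.consequence,
            allele_count=int(row.allele_count),
            allele_number=int(row.allele_number),
            homozygote_count=int(row.homozygote_count),
        )
        for row in table.itertuples(index=False)
    ]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix in {".vcf"}:
        return read_vcf(p)
    return pd.read_csv(p, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
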