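"""Machine-readable fixtures transcribed from the study's printed tables.

Three packaged TSVs accompany the library: the 62-gene inflammasome
regulation panel, the 29 "selected" variants (rare + high-CADD corner, with
per-cohort allele counts), and the 15 additional "MS enriched" variants
(Fisher-significant against the reference database; bracketed
homozygote-contributed allele counts stored as separate ``*_hom`` columns).
They let every downstream statistic be exercised on real printed numbers
without any sequencing data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .types import Consequence, GenePanel, VariantRecord

__all__ = [
    "load_panel_fixture",
    "load_selected_fixture",
    "load_enriched_fixture",
    "selected_fixture_records",
    "make_paper_fixtures",
    "MS_COMBINED_N",
    "CTRL_N",
]

#: Cohort sizes the fixture allele counts refer to.
MS_COMBINED_N = 175
CTRL_N = 144

_FIXTURES = {
    "panel": "panel_62_genes.tsv",
    "selected": "selected_variants.tsv",
    "enriched": "enriched_variants.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("rava.data").joinpath(_FIXTURES[name]).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_panel_fixture() -> GenePanel:
    """The 62-gene inflammasome regulation panel."""
    df = _read("panel")
    genes = list(df["gene"])
    if len(set(genes)) != len(genes):
        raise ValueError("panel fixture contains duplicate symbols")
    return GenePanel("inflammasome_62", frozenset(genes))


def load_selected_fixture() -> pd.DataFrame:
    """The 29 selected variants with cohort allele counts (MS n=175, CTRL n=144)."""
    return _read("selected")


def load_enriched_fixture() -> pd.DataFrame:
    """The 15 additional enriched variants (total and homozygote-bracket counts)."""
    return _read("enriched")


def _row_to_record(row: pd.Series) -> VariantRecord:
    ref_ac = None if pd.isna(row.get("ref_ac")) else int(row["ref_ac"])
    ref_af = None if pd.isna(row.get("ref_af")) else float(row["ref_af"])
    if not ref_ac:
        ref_ac, ref_af = None, None
    cadd = None if pd.isna(row.get("cadd_phred")) else float(row["cadd_phred"])
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=row["gene"],
        consequence=Consequence(row["consequence"]),
        protein_change=row["protein_change"],
        cadd_phred=cadd,
        ref_af=ref_af,
        ref_ac=ref_ac,
    )


def selected_fixture_records() -> list[VariantRecord]:
    """The selected-variant fixture as annotated :class:`VariantRecord` objects."""
    return [_row_to_record(row) for _, row in load_selected_fixture().iterrows()]


def enriched_fixture_records() -> list[VariantRecord]:
    return [_row_to_record(row) for _, row in load_enriched_fixture().iterrows()]


def make_paper_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the packaged fixture TSVs to ``out_dir``; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for key, fname in _FIXTURES.items():
        target = out / fname
        with resources.files("rava.data").joinpath(fname).open() as fh:
            target.write_text(fh.read())
        written[key] = target
    return written
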