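"""Matrisome category and blood-protein annotation from a bundled table.

The mapping ships with the package (no live web queries): accession →
extracellular-matrix category (collagen, proteoglycan, glycoprotein, ECM
regulator, ECM-affiliated, secreted factor) plus a blood/plasma/amyloid
flag approximating the gene-ontology term set used for vascular-protein
screening. Accessions absent from the table are non-matrisome by rule,
never an error.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .model import MATRISOME_CATEGORIES


def load_annotation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the accession → (category, blood_related) mapping.

    Bundled table by default; a caller-supplied TSV with the same columns
    (``accession, gene, description, category, blood_related``) overrides.
    """
    if path is None:
        with resources.files("matriquant.data").joinpath("matrisome.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    table["blood_related"] = table["blood_related"].astype(bool)
    bad = set(table["category"]) - set(MATRISOME_CATEGORIES)
    if bad:
        raise ValueError(f"unknown matrisome categories {sorted(bad)!r}")
    return table.set_index("accession")


def annotate_proteins(accessions, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate every accession; unknowns become non-matrisome, not errors.

    Idempotent: annotating an already-annotated accession list gives the
    same result.
    """
    if table is None:
        table = load_annotation_table()
    idx = pd.Index(pd.unique(pd.Series(list(accessions))), name="accession")
    out = table.reindex(idx)
    out["category"] = out["category"].fillna("non_matrisome")
    out["blood_related"] = out["blood_related"].map(
        lambda v: bool(v) if pd.notna(v) else False)
    out["gene"] = out["gene"].fillna("")
    if "description" in out.columns:
        out["description"] = out["description"].fillna("")
    return out


def category_tally(annotated: pd.DataFrame) -> pd.Series:
    """Exhaustive per-category protein counts (zero-filled, sums to length)."""
    counts = annotated["category"].value_counts()
    return counts.reindex(MATRISOME_CATEGORIES, fill_value=0).astype(int)


def tissue_tallies(annotated_by_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-tissue category counts plus the shared-protein column."""
    out = {tissue: category_tally(frame)
           for tissue, frame in annotated_by_tissue.items()}
    frames = list(annotated_by_tissue.values())
    if len(frames) >= 2:
        shared = set(frames[0].index)
        for f in frames[1:]:
            shared &= set(f.index)
        out["shared"] = category_tally(frames[0].loc[sorted(shared)])
    return pd.DataFrame(out)
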