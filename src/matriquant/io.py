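"""Reading and writing the delimited-text and FASTA formats the pipeline consumes.

The interchange format is long/tidy delimited text (tab by default), one
peptide observation per row; wide matrices are always derived in memory and
never stored as interchange. Lines starting with ``#`` are treated as
comments (the pipeline stamps a config hash and seed there).
"""

from __future__ import annotations

from collections import namedtuple
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

from .model import (
    PEPTIDE_KEY,
    PEPTIDE_TABLE_COLUMNS,
    SAMPLE_TABLE_COLUMNS,
    FormatError,
    ProteinInfo,
    ValidationError,
)

_REQUIRED = ("sample_id", "fraction", "peptide", "accession", "intensity")


def read_peptide_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a peptide record table from delimited text.

    The header must name ``sample_id, fraction, peptide, accession,
    intensity``; ``score`` and ``is_decoy`` default to 0 / False when
    absent. Unknown columns are preserved untouched.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        if any intensity is negative (the offending row number is named).
    """
    frame = pd.read_csv(path, sep=sep, comment="#")
    for col in _REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"peptide table {path} lacks required column {col!r}")
    if "score" not in frame.columns:
        frame["score"] = 0.0
    if "is_decoy" not in frame.columns:
        frame["is_decoy"] = False
    frame["is_decoy"] = frame["is_decoy"].astype(bool)
    frame["fraction"] = frame["fraction"].astype(int)
    frame["intensity"] = frame["intensity"].astype(float)
    bad = np.flatnonzero(frame["intensity"].to_numpy() < 0)
    if bad.size:
        raise ValidationError(f"negative intensity at data row {bad[0] + 1} of {path}")
    if (frame["peptide"].astype(str).str.len() == 0).any():
        raise ValidationError(f"empty peptide sequence in {path}")
    return frame


def write_peptide_table(records: pd.DataFrame, path: str | Path, sep: str = "\t",
                        header_comment: str | None = None) -> None:
    """Write a peptide record table, deterministically ordered.

    Rows are sorted by (sample_id, fraction, peptide, accession) and the
    canonical columns come first, so identical data always produce an
    identical file (round-trip through :func:`read_peptide_table` is the
    identity).
    """
    cols = [c for c in PEPTIDE_TABLE_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    out = records[cols + extra]
    if not out.empty:
        out = out.sort_values(["sample_id", "fraction", "peptide", "accession"],
                              kind="mergesort").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep=sep, index=False, float_format="%.10g")


def read_sample_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read run-level sample metadata, indexed by ``sample_id``."""
    frame = pd.read_csv(path, sep=sep, comment="#")
    for col in SAMPLE_TABLE_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"sample table {path} lacks required column {col!r}")
    frame["donor"] = frame["donor"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    return frame.set_index("sample_id").sort_index()


def write_sample_table(meta: pd.DataFrame, path: str | Path, sep: str = "\t",
                       header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        meta.sort_index().to_csv(fh, sep=sep, float_format="%.10g")


MergeResult = namedtuple("MergeResult", ["matrix", "n_decoy_records", "decoy_intensity"])


def merge_fractions(records: pd.DataFrame) -> MergeResult:
    """Collapse per-fraction peptide observations to one intensity per run.

    Peptide quantities are summed across fractions for peptides detected in
    more than one fraction (a minority in a well-behaved 2D separation).
    Peptide identity is (sequence including modifications, accession); decoy
    records are excluded from the matrix but tallied so total intensity is
    conserved: ``matrix.sum() + decoy_intensity`` equals the input total.

    Summing is idempotent, so tables whose intensities are already
    fraction-merged pass through unchanged.

    Returns a :class:`MergeResult` whose ``matrix`` is a (peptide,
    accession) × sample_id frame with NaN for unobserved cells.
    """
    if records.empty:
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=PEPTIDE_KEY)
        )
        return MergeResult(empty, 0, 0.0)
    decoys = records[records["is_decoy"]]
    targets = records[~records["is_decoy"]]
    matrix = (
        targets.groupby(PEPTIDE_KEY + ["sample_id"], sort=True)["intensity"]
        .sum()
        .unstack("sample_id")
    )
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    return MergeResult(matrix, len(decoys), float(decoys["intensity"].sum()))


def read_fasta(path: str | Path) -> list[ProteinInfo]:
    """Read protein sequences; average molecular weight is computed per entry.

    The mass is the sum of average residue masses plus one water — the
    convention used to convert Hi3 molar amounts to nanograms. Header
    format: ``>ACCESSION GENE=SYM description`` (GENE tag optional).
    """
    out: list[ProteinInfo] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"FASTA entry with empty header in {path}")
        try:
            mw = molecular_weight(seq, seq_type="protein") if seq else float("nan")
        except ValueError as exc:  # non-amino-acid characters
            raise FormatError(f"bad sequence for {rec.id}: {exc}") from exc
        gene = ""
        desc_parts = []
        for token in rec.description.split()[1:]:
            if token.startswith("GENE="):
                gene = token[5:]
            else:
                desc_parts.append(token)
        out.append(
            ProteinInfo(
                accession=rec.id,
                sequence=seq,
                gene=gene,
                description=" ".join(desc_parts),
                mol_weight_da=mw,
            )
        )
    return out


def write_fasta(proteins: Iterable[ProteinInfo], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for p in sorted(proteins, key=lambda p: p.accession):
            gene = f" GENE={p.gene}" if p.gene else ""
            desc = f" {p.description}" if p.description else ""
            fh.write(f">{p.accession}{gene}{desc}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


def molecular_weights(proteins: Iterable[ProteinInfo]) -> pd.Series:
    """Accession → average molecular weight (Da)."""
    return pd.Series({p.accession: p.mol_weight_da for p in proteins}, name="mol_weight_da")
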