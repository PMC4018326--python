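"""Shared data model for the tendon/ligament label-free quantitation pipeline.

The in-memory currency of the package is the pandas DataFrame:

* a *peptide record table* — one row per quantified peptide observation
  (``sample_id, fraction, peptide, accession, intensity, score, is_decoy``),
  the long format in which raw results arrive;
* a *sample table* — one row per analytical run (``sample_id`` index with
  ``tissue, sex, donor, replicate, injected_mass_ug, spike_fmol_per_ug``);
* a *peptide matrix* — (peptide, accession) × sample_id intensities after
  fraction merging, with missing cells as NaN (never 0: zero means
  "observed at zero area", NaN means "not observed");
* a *protein matrix* — accession × sample_id summed intensities.

Lightweight dataclasses mirror single rows where an object view is more
convenient than a frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

TISSUES = ("ACL", "PT")
SEXES = ("M", "F")

MATRISOME_CATEGORIES = (
    "collagen",
    "proteoglycan",
    "glycoprotein",
    "ECM_regulator",
    "ECM_affiliated",
    "secreted_factor",
    "non_matrisome",
)

#: accession of the spiked surrogate standard used for Hi3 calibration
STANDARD_ACCESSION = "ADH1_YEAST"
#: accession of the abundant blood protein used as the enrichment reference
ALBUMIN_ACCESSION = "ALBU_HUMAN"

#: columns every peptide record table must provide
PEPTIDE_TABLE_COLUMNS = (
    "sample_id",
    "fraction",
    "peptide",
    "accession",
    "intensity",
    "score",
    "is_decoy",
)

#: the identity used when merging fractions and building matrices; modified
#: forms of the same sequence are distinct peptides
PEPTIDE_KEY = ["peptide", "accession"]

SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "tissue",
    "sex",
    "donor",
    "replicate",
    "injected_mass_ug",
    "spike_fmol_per_ug",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular/FASTA layout."""


class ValidationError(ValueError):
    """Well-formed input violates a domain invariant (e.g. negative intensity)."""


class MissingStandardError(KeyError):
    """The spiked surrogate standard is absent where calibration needs it."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and loading of one analytical run.

    ``injected_mass_ug`` is the protein digest mass loaded on column (µg);
    ``spike_fmol_per_ug`` the surrogate-standard spike level, so the known
    on-column standard amount is the product of the two (default 25 × 3 =
    75 fmol).
    """

    sample_id: str
    tissue: str
    sex: str
    donor: int
    replicate: int = 1
    injected_mass_ug: float = 3.0
    spike_fmol_per_ug: float = 25.0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if self.injected_mass_ug <= 0:
            raise ValidationError("injected_mass_ug must be positive")
        if self.spike_fmol_per_ug < 0:
            raise ValidationError("spike_fmol_per_ug must be >= 0")

    @property
    def subject_id(self) -> str:
        """Donor-level identifier shared by duplicate runs of one digest."""
        return f"{self.tissue}_{self.sex}{self.donor}"


@dataclass(frozen=True)
class PeptideRecord:
    """One quantified peptide observation in one fraction of one run."""

    sample_id: str
    fraction: int
    peptide: str
    accession: str
    intensity: float
    score: float = 0.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValidationError("peptide sequence must be non-empty")
        if self.intensity < 0:
            raise ValidationError(f"negative intensity for {self.peptide}")
        if self.fraction < 1:
            raise ValidationError("fraction index must be >= 1")


@dataclass
class ProteinInfo:
    """Sequence-level information about one protein entry."""

    accession: str
    sequence: str = ""
    gene: str = ""
    description: str = ""
    mol_weight_da: float = float("nan")
    matrisome_category: str = "non_matrisome"
    blood_related: bool = False


def samples_to_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabulate sample metadata, indexed by ``sample_id``.

    Raises :class:`ValidationError` if two runs share the same
    (tissue, sex, donor, replicate) identity.
    """
    rows = [vars(s).copy() for s in samples]
    frame = pd.DataFrame(rows, columns=list(SAMPLE_TABLE_COLUMNS))
    if frame.empty:
        return frame.set_index("sample_id")
    ident = frame[["tissue", "sex", "donor", "replicate"]]
    if ident.duplicated().any():
        raise ValidationError("duplicate (tissue, sex, donor, replicate) identity")
    if frame["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id")
    return frame.set_index("sample_id").sort_index()


def frame_to_samples(frame: pd.DataFrame) -> list[SampleMeta]:
    """Inverse of :func:`samples_to_frame`."""
    out = []
    for sample_id, row in frame.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(sample_id),
                tissue=str(row["tissue"]),
                sex=str(row["sex"]),
                donor=int(row["donor"]),
                replicate=int(row["replicate"]),
                injected_mass_ug=float(row["injected_mass_ug"]),
                spike_fmol_per_ug=float(row["spike_fmol_per_ug"]),
            )
        )
    return out


def subject_of(meta: pd.DataFrame) -> pd.Series:
    """Map each run to its subject (donor digest) identifier."""
    return meta["tissue"].astype(str) + "_" + meta["sex"].astype(str) + meta["donor"].astype(str)
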