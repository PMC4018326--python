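"""Synthetic peptide-level datasets with known ground truth.

The generator emulates the structure of a two-tissue (ACL / patellar
tendon), two-sex, three-donor label-free 2DLC-MSE experiment: eight LC
fractions, one duplicate run per tissue, a collagen-dominated log-normal
abundance profile, programmed tissue and sex fold changes, a yeast alcohol
dehydrogenase surrogate standard spiked at a known level (25 fmol/µg by
default) into every sample, and reversed-sequence decoy identifications.

Model
-----
For protein ``A`` with programmed group concentration ``c(tissue, sex)``
(fmol per µg digest) the true on-column amount in subject ``s`` is

    fmol(A, s) = c · injected_µg · exp(ε_bio),   ε_bio ~ N(0, bio_sigma²)

shared by duplicate runs of the same digest. A peptide ``p`` of ``A``
observed in run ``r`` gets intensity

    I = fmol(A, s(r)) · eff(p) · scale(r) · exp(ε),   ε ~ N(0, sigma²)

``eff(p)`` is a per-peptide ionization efficiency drawn once (log-normal)
and shared across samples — the "flier" structure — rescaled per protein so
that the mean efficiency of its top-min(3, n) peptides is exactly 1. That
makes the Hi3 assumption (the mean response of the best flier peptides is
protein-independent) hold exactly, so absolute quantification is exact when
all noise terms are zero. ``scale(r)`` is a per-run global intensity factor
that calibration must cancel.

Sequences are synthetic: each accession deterministically hashes to a
random amino-acid sequence of the panel's stated length, so peptide
catalogs, molecular weights and fraction assignments are reproducible
without bundling any real database.
"""

from __future__ import annotations

import hashlib
import re
from collections import namedtuple
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SampleMeta, ValidationError, samples_to_frame
from .io import write_peptide_table, write_sample_table

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def digest_protein(sequence: str, max_missed: int = 2,
                   min_len: int = 1, max_len: int = 10**9) -> list[str]:
    """In-silico tryptic digest: cleave after K or R, not before P.

    Returns all peptides with 0..``max_missed`` missed cleavages whose
    length is within [min_len, max_len], in N→C order (fully cleaved first).
    """
    if not sequence:
        raise ValidationError("empty sequence")
    sequence = sequence.upper()
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"non-amino-acid characters {sorted(bad)!r} in sequence")
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    base = _TRYPSIN.split(sequence)
    out = []
    for missed in range(max_missed + 1):
        for i in range(len(base) - missed):
            pep = "".join(base[i:i + missed + 1])
            if min_len <= len(pep) <= max_len:
                out.append(pep)
    return out


def _accession_rng(accession: str, salt: str = "") -> np.random.Generator:
    digest = hashlib.md5((accession + "|" + salt).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def synthetic_sequence(accession: str, length: int) -> str:
    """Deterministic pseudo-random protein sequence for one accession.

    Lysine/arginine are enriched so tryptic peptides average ~10 residues.
    A fixed property of the accession, independent of the dataset seed.
    """
    rng = _accession_rng(accession, "seq")
    weights = np.ones(len(AMINO_ACIDS))
    weights[AMINO_ACIDS.index("K")] = 2.2
    weights[AMINO_ACIDS.index("R")] = 2.2
    weights /= weights.sum()
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=weights)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _peptide_fraction(peptide: str, n_fractions: int, multi_rate: float):
    """Deterministic fraction assignment; a minority splits over 2 adjacent fractions."""
    digest = hashlib.md5(peptide.encode()).digest()
    frac = 1 + digest[0] % n_fractions
    if digest[1] / 256.0 < multi_rate and n_fractions > 1:
        second = frac % n_fractions + 1
        return [(frac, 0.7), (second, 0.3)]
    return [(frac, 1.0)]


def default_panel() -> pd.DataFrame:
    """The bundled ~55-protein panel (collagen-dominated, both tissues)."""
    with resources.files("matriquant.data").joinpath("panel.tsv").open() as fh:
        panel = pd.read_csv(fh, sep="\t")
    panel["is_standard"] = panel["is_standard"].astype(bool)
    return panel.set_index("accession")


def panel_proteins(panel: pd.DataFrame) -> list:
    """Synthetic :class:`~matriquant.model.ProteinInfo` entries for a panel."""
    from .model import ProteinInfo
    from Bio.SeqUtils import molecular_weight

    out = []
    for acc, row in panel.iterrows():
        seq = synthetic_sequence(str(acc), int(row["length"]))
        out.append(ProteinInfo(accession=str(acc), sequence=seq,
                               mol_weight_da=molecular_weight(seq, seq_type="protein")))
    return out


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the stated experimental design.

    ``sigma`` is the technical (per-record) log-normal sigma on the natural
    log scale; ``bio_sigma`` the biological per (protein, donor) sigma;
    ``run_scale_sigma`` the per-run global intensity drift. ``dropout`` is
    the overall missing-at-random rate, applied preferentially to
    low-intensity peptides (logistic in log intensity).
    """

    panel: pd.DataFrame | None = None
    n_donors: int = 3
    n_fractions: int = 8
    sigma: float = 0.15
    bio_sigma: float = 0.25
    run_scale_sigma: float = 0.10
    dropout: float = 0.05
    multi_fraction_rate: float = 0.15
    decoy_rate: float = 0.05
    score_separation: float = 3.0
    spike_fmol_per_ug: float = 25.0
    injected_mass_ug: float = 3.0
    min_peptide_len: int = 6
    max_peptide_len: int = 30
    duplicate_donor: tuple[str, int] = ("M", 3)  # one duplicate run per tissue

    def resolved_panel(self) -> pd.DataFrame:
        if self.panel is None:
            return default_panel()
        if self.panel.empty:
            raise ValidationError("empty protein panel")
        return self.panel


@dataclass
class GroundTruth:
    """The generator's ledger: what the estimators should recover."""

    seed: int
    proteins: pd.DataFrame      # per (accession, tissue, sex): conc, fold changes
    sample_fmol: pd.DataFrame   # accession × subject true on-column fmol
    peptides: pd.DataFrame      # peptide, accession, efficiency, fraction, weight
    sigma: float = 0.0
    bio_sigma: float = 0.0

    def write(self, outdir: str | Path, header_comment: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# {header_comment or f'ground truth seed={self.seed}'}\n"
        for name, frame in (("truth_proteins", self.proteins),
                            ("truth_sample_fmol", self.sample_fmol),
                            ("truth_peptides", self.peptides)):
            with open(outdir / f"{name}.tsv", "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", float_format="%.10g")


SimulatedDataset = namedtuple("SimulatedDataset", ["records", "meta", "truth"])


def _build_samples(config: SimulationConfig) -> list[SampleMeta]:
    samples = []
    dup_sex, dup_donor = config.duplicate_donor
    for tissue in ("ACL", "PT"):
        for sex in ("M", "F"):
            for donor in range(1, config.n_donors + 1):
                reps = 2 if (sex, donor) == (dup_sex, dup_donor) else 1
                for rep in range(1, reps + 1):
                    samples.append(SampleMeta(
                        sample_id=f"{tissue}_{sex}{donor}_r{rep}",
                        tissue=tissue, sex=sex, donor=donor, replicate=rep,
                        injected_mass_ug=config.injected_mass_ug,
                        spike_fmol_per_ug=config.spike_fmol_per_ug,
                    ))
    return samples


def _peptide_catalog(panel: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-protein tryptic peptides with efficiencies and fraction weights.

    Efficiencies are log-normal (sigma 1) per peptide, then rescaled per
    protein so its top-min(3, n) efficiencies average to exactly 1.
    """
    rows = []
    for acc, prow in panel.iterrows():
        seq = synthetic_sequence(str(acc), int(prow["length"]))
        peps = sorted(set(digest_protein(seq, max_missed=0,
                                         min_len=config.min_peptide_len,
                                         max_len=config.max_peptide_len)))
        if not peps:
            continue
        rng = _accession_rng(str(acc), "eff")
        eff = rng.lognormal(mean=0.0, sigma=1.0, size=len(peps))
        k = min(3, len(peps))
        top_mean = np.sort(eff)[::-1][:k].mean()
        eff = eff / top_mean
        for pep, e in zip(peps, eff):
            for frac, w in _peptide_fraction(pep, config.n_fractions,
                                             config.multi_fraction_rate):
                rows.append((pep, acc, e, frac, w))
    cat = pd.DataFrame(rows, columns=["peptide", "accession", "efficiency",
                                      "fraction", "weight"])
    return cat.sort_values(["accession", "peptide", "fraction"]).reset_index(drop=True)


def _group_concentration(prow: pd.Series, tissue: str, sex: str,
                         config: SimulationConfig) -> float:
    """Programmed fmol/µg for one (protein, tissue, sex) group.

    The panel stores per-tissue baseline concentrations and M/F sex fold
    changes; the two sexes sit symmetrically (×√fc and ÷√fc) around the
    baseline so the tissue value is the geometric group mean. The spiked
    standard is added post-digest and is identical everywhere.
    """
    if bool(prow["is_standard"]):
        return config.spike_fmol_per_ug
    base = float(prow["conc_acl"] if tissue == "ACL" else prow["conc_pt"])
    fc = float(prow["sex_fc_acl"] if tissue == "ACL" else prow["sex_fc_pt"])
    if base <= 0:
        return 0.0
    return base * np.sqrt(fc) if sex == "M" else base / np.sqrt(fc)


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Generate one full experiment: peptide records, metadata, ground truth.

    Deterministic: identical config and seed give byte-identical tables.
    """
    config = config or SimulationConfig()
    panel = config.resolved_panel()
    rng = np.random.default_rng(seed)
    samples = _build_samples(config)
    meta = samples_to_frame(samples)
    catalog = _peptide_catalog(panel, config)

    accs = list(panel.index)
    subjects = sorted({s.subject_id for s in samples})
    subj_info = {s.subject_id: s for s in samples}

    # --- programmed concentrations and per-subject biological factors
    conc_rows = []
    for acc in accs:
        prow = panel.loc[acc]
        for tissue in ("ACL", "PT"):
            for sex in ("M", "F"):
                conc_rows.append((acc, tissue, sex,
                                  _group_concentration(prow, tissue, sex, config)))
    conc = pd.DataFrame(conc_rows, columns=["accession", "tissue", "sex",
                                            "conc_fmol_per_ug"])

    bio = rng.normal(0.0, 1.0, size=(len(accs), len(subjects))) * config.bio_sigma
    fmol = pd.DataFrame(index=pd.Index(accs, name="accession"),
                        columns=pd.Index(subjects, name="subject"), dtype=float)
    conc_lookup = conc.set_index(["accession", "tissue", "sex"])["conc_fmol_per_ug"]
    for j, subj in enumerate(subjects):
        s = subj_info[subj]
        for i, acc in enumerate(accs):
            c = conc_lookup.loc[(acc, s.tissue, s.sex)]
            if c <= 0:
                fmol.loc[acc, subj] = np.nan
                continue
            factor = 1.0 if bool(panel.loc[acc, "is_standard"]) else np.exp(bio[i, j])
            fmol.loc[acc, subj] = c * config.injected_mass_ug * factor

    run_scale = pd.Series(
        np.exp(rng.normal(0.0, 1.0, size=len(meta)) * config.run_scale_sigma),
        index=meta.index)

    # --- expand catalog × runs into records
    n_pep = len(catalog)
    frames = []
    for sample_id, mrow in meta.iterrows():
        subj = f"{mrow['tissue']}_{mrow['sex']}{mrow['donor']}"
        amounts = fmol[subj].reindex(catalog["accession"]).to_numpy()
        base = amounts * catalog["efficiency"].to_numpy() * catalog["weight"].to_numpy()
        noise = np.exp(rng.normal(0.0, 1.0, size=n_pep) * config.sigma)
        intensity = base * run_scale[sample_id] * noise
        frame = catalog[["peptide", "accession", "fraction"]].copy()
        frame["sample_id"] = sample_id
        frame["intensity"] = intensity
        frames.append(frame)
    records = pd.concat(frames, ignore_index=True)
    records = records.dropna(subset=["intensity"]).reset_index(drop=True)

    # --- intensity-dependent dropout (standard exempt: the spike is abundant
    #     and calibration must exist in every run)
    if config.dropout > 0 and len(records):
        x = np.log(records["intensity"].to_numpy())
        raw = 1.0 / (1.0 + np.exp((x - np.median(x)) / 1.5))
        p = np.clip(config.dropout * raw / raw.mean(), 0.0, 0.95)
        std_mask = records["accession"].eq(
            panel.index[panel["is_standard"]][0]) if panel["is_standard"].any() \
            else np.zeros(len(records), bool)
        drop = (rng.random(len(records)) < p) & ~np.asarray(std_mask)
        records = records[~drop].reset_index(drop=True)

    records["score"] = config.score_separation + rng.normal(0.0, 1.0, size=len(records))
    records["is_decoy"] = False

    # --- decoy identifications from the null score distribution
    n_decoys = int(round(config.decoy_rate * len(records)))
    if n_decoys:
        lengths = rng.integers(config.min_peptide_len,
                               config.max_peptide_len + 1, size=n_decoys)
        pep_idx = [rng.integers(0, len(AMINO_ACIDS), size=int(n)) for n in lengths]
        decoys = pd.DataFrame({
            "peptide": ["".join(AMINO_ACIDS[i] for i in idx) for idx in pep_idx],
            "accession": ["DECOY_" + str(accs[i]) for i in
                          rng.integers(0, len(accs), size=n_decoys)],
            "fraction": rng.integers(1, config.n_fractions + 1, size=n_decoys),
            "sample_id": [meta.index[i] for i in
                          rng.integers(0, len(meta), size=n_decoys)],
            "intensity": np.exp(rng.normal(np.log(records["intensity"].median()) - 2.0,
                                           1.0, size=n_decoys)),
            "score": rng.normal(0.0, 1.0, size=n_decoys),
            "is_decoy": True,
        })
        records = pd.concat([records, decoys], ignore_index=True)

    records = records[["sample_id", "fraction", "peptide", "accession",
                       "intensity", "score", "is_decoy"]]
    records = records.sort_values(["sample_id", "fraction", "peptide", "accession"],
                                  kind="mergesort").reset_index(drop=True)

    # --- ground-truth ledger with programmed fold changes
    tconc = conc.pivot_table(index="accession", columns=["tissue", "sex"],
                             values="conc_fmol_per_ug")
    truth_proteins = conc.copy()
    truth = GroundTruth(
        seed=seed,
        proteins=truth_proteins.set_index(["accession", "tissue", "sex"]),
        sample_fmol=fmol,
        peptides=catalog.set_index(["peptide", "accession"]),
        sigma=config.sigma,
        bio_sigma=config.bio_sigma,
    )
    truth.tissue_fc = np.sqrt(tconc[("ACL", "M")] * tconc[("ACL", "F")]) / \
        np.sqrt(tconc[("PT", "M")] * tconc[("PT", "F")])
    truth.sex_fc = pd.DataFrame({
        t: tconc[(t, "M")] / tconc[(t, "F")] for t in ("ACL", "PT")})
    return SimulatedDataset(records, meta, truth)


def simulate_scores(n_targets: int, n_decoys: int, separation: float,
                    seed: int = 0) -> pd.DataFrame:
    """Scored identifications for exercising target-decoy FDR estimation.

    ``n_targets`` correct target matches score N(separation, 1). Incorrect
    matches score N(0, 1) and land in target and decoy space with equal
    probability, so ``n_decoys`` decoy records are accompanied by
    ``n_decoys`` *incorrect target* records — the assumption that makes the
    decoy count estimate the incorrect-target count. The hidden
    ``is_correct`` label supports Monte-Carlo calibration checks.
    """
    if n_targets < 0 or n_decoys < 0:
        raise ValidationError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    parts = [
        pd.DataFrame({"score": separation + rng.normal(size=n_targets),
                      "is_decoy": False, "is_correct": True}),
        pd.DataFrame({"score": rng.normal(size=n_decoys),
                      "is_decoy": False, "is_correct": False}),
        pd.DataFrame({"score": rng.normal(size=n_decoys),
                      "is_decoy": True, "is_correct": False}),
    ]
    return pd.concat(parts, ignore_index=True)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path,
                  header_comment: str | None = None) -> None:
    """Write records, metadata and the ground-truth ledger as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_peptide_table(dataset.records, outdir / "peptides.tsv",
                        header_comment=header_comment)
    write_sample_table(dataset.meta, outdir / "samples.tsv",
                       header_comment=header_comment)
    dataset.truth.write(outdir)
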