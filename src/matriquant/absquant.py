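"""Hi3 (top-3 "best flier") absolute quantification and derived comparisons.

The absolute arm of the pipeline: for every protein with at least two
peptides, the mean intensity of its three most intense peptides is compared
with the same quantity for the spiked surrogate standard of known amount
(spike level × injected digest mass, 25 fmol/µg × 3 µg = 75 fmol by
default) to yield femtomoles on column; molar amounts convert to nanograms
via the sequence-average molecular weight, and each protein is expressed as
a percent of the summed quantified protein mass in its sample ("% dry
weight"). Because the two tissue datasets are processed independently and
cannot be compared at the raw-intensity level, cross-tissue statistics are
computed on the dry-weight percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ALBUMIN_ACCESSION, MissingStandardError, STANDARD_ACCESSION
from .differential import cohens_d, signed_fold_change


def select_top_peptides(peptide_matrix: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Choose each protein's top-k flier peptides for one dataset.

    Ranking is by mean log intensity across the dataset's runs (missing and
    zero cells ignored), so the same peptide set serves every sample and the
    choice is invariant to a global per-sample intensity rescaling (which
    shifts every peptide's log mean equally); ties at the cut are broken by
    lexicographically smallest sequence. Proteins with fewer than two
    peptides are excluded; with exactly two, both are used and
    ``n_peptides_used`` records 2.

    Returns a frame indexed by (peptide, accession) with the chosen rows,
    plus an ``n_peptides_used`` column (constant per accession).
    """
    if peptide_matrix.empty:
        return peptide_matrix.assign(n_peptides_used=pd.Series(dtype=int))
    means = np.log(peptide_matrix.where(peptide_matrix > 0)).mean(axis=1)
    chosen = []
    for acc, sub in means.groupby(level="accession", sort=True):
        sub = sub.dropna()
        if len(sub) < 2:
            continue
        # rank by descending mean, peptide sequence as deterministic tie-break
        frame = sub.rename("mean").reset_index()
        frame = frame.sort_values("peptide", kind="mergesort")
        frame = frame.sort_values("mean", ascending=False, kind="mergesort")
        top = frame.head(k)
        for _, r in top.iterrows():
            chosen.append((r["peptide"], acc, len(top)))
    if not chosen:
        empty = peptide_matrix.iloc[0:0].copy()
        empty["n_peptides_used"] = pd.Series(dtype=int)
        return empty
    idx = pd.MultiIndex.from_tuples([(p, a) for p, a, _ in chosen],
                                    names=["peptide", "accession"])
    out = peptide_matrix.loc[idx].copy()
    out["n_peptides_used"] = [n for _, _, n in chosen]
    return out


def top_k_intensity(peptide_matrix: pd.DataFrame, k: int = 3):
    """Per-protein per-run mean intensity over the chosen top-k peptides.

    Returns ``(topk, n_used)``: an accession × run frame (mean over the
    chosen peptides that are present in that run; missing if none are) and
    the per-accession count of peptides used.
    """
    chosen = select_top_peptides(peptide_matrix, k)
    if chosen.empty:
        return (pd.DataFrame(columns=peptide_matrix.columns,
                             index=pd.Index([], name="accession")),
                pd.Series(dtype=int, name="n_peptides_used"))
    n_used = chosen.groupby(level="accession")["n_peptides_used"].first()
    topk = chosen.drop(columns="n_peptides_used").groupby(level="accession").mean()
    return topk, n_used


def calibrate(topk: pd.DataFrame, meta: pd.DataFrame,
              standard_accession: str = STANDARD_ACCESSION) -> pd.Series:
    """Per-run response factor (intensity per fmol) from the spiked standard.

    The known on-column amount is ``spike_fmol_per_ug × injected_mass_ug``
    for each run. Runs where the standard was not quantified are dropped
    with a hard warning via :class:`MissingStandardError` if that leaves
    nothing to calibrate.
    """
    if standard_accession not in topk.index:
        raise MissingStandardError(
            f"standard {standard_accession!r} not quantified in any run")
    std = topk.loc[standard_accession]
    known = (meta["spike_fmol_per_ug"] * meta["injected_mass_ug"]).reindex(std.index)
    response = std / known
    response = response.dropna()
    if response.empty:
        raise MissingStandardError("standard missing from every run")
    return response.rename("response_per_fmol")


@dataclass
class AbsoluteQuant:
    """Per-protein per-sample absolute quantities on three scales."""

    fmol: pd.DataFrame            # accession × run, on-column femtomoles
    ng: pd.DataFrame              # via molecular weight
    pct_dry_weight: pd.DataFrame  # percent of summed quantified protein mass
    n_peptides_used: pd.Series
    response: pd.Series           # per-run calibration factor


def quantify(peptide_matrix: pd.DataFrame, meta: pd.DataFrame,
             mol_weights: pd.Series, k: int = 3,
             standard_accession: str = STANDARD_ACCESSION) -> AbsoluteQuant:
    """Full Hi3 quantification of one dataset (one tissue).

    ``mol_weights`` maps accession → average molecular weight in Da;
    ``ng = fmol × MW × 1e-6``. The surrogate standard is excluded from the
    dry-weight normalization (numerator and denominator). Runs lacking the
    standard are excluded entirely.
    """
    topk, n_used = top_k_intensity(peptide_matrix, k)
    response = calibrate(topk, meta, standard_accession)
    fmol = topk[response.index].div(response, axis=1)
    native = fmol.drop(index=standard_accession, errors="ignore")
    mw = mol_weights.reindex(native.index)
    ng = native.mul(mw, axis=0) * 1e-6
    pct = to_dry_weight(ng)
    return AbsoluteQuant(fmol=fmol, ng=ng, pct_dry_weight=pct,
                         n_peptides_used=n_used, response=response)


def to_dry_weight(ng: pd.DataFrame) -> pd.DataFrame:
    """Percent of the summed quantified protein mass, per sample.

    Columns sum to 100 over the proteins quantified in that sample. The
    caller excludes the spiked standard before this step.
    """
    totals = ng.sum(axis=0, skipna=True)
    return 100.0 * ng.div(totals, axis=1)


def _sex_columns(meta: pd.DataFrame, tissue: str, sex: str | None = None):
    m = meta[(meta["tissue"] == tissue)]
    if sex is not None:
        m = m[m["sex"] == sex]
    return list(m.index)


def _subject_means(pct: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate runs so each donor contributes once."""
    from .differential import average_duplicates
    meta = meta.loc[[c for c in pct.columns if c in meta.index]]
    return average_duplicates(pct[list(meta.index)], meta)


def compare_tissues(pct_acl: pd.DataFrame, pct_pt: pd.DataFrame,
                    meta: pd.DataFrame,
                    counts_acl: pd.Series | None = None,
                    counts_pt: pd.Series | None = None) -> pd.DataFrame:
    """ACL-vs-PT comparison of dry-weight percentages, with sex strata.

    Only proteins quantified in both tissues appear. Fold changes use the
    signed convention on subject-mean percentages; p-values are two-sided
    pooled-variance t-tests; Cohen's d is computed on log2 percentages.
    Sex-stratified fold changes and p-values use the 3-vs-3 donor subsets.
    """
    a_subj = _subject_means(pct_acl, meta)
    p_subj = _subject_means(pct_pt, meta)
    subj_meta = meta.drop_duplicates(subset=["tissue", "sex", "donor"]).copy()
    subj_meta.index = (subj_meta["tissue"] + "_" + subj_meta["sex"]
                       + subj_meta["donor"].astype(str))
    shared = sorted(set(a_subj.index) & set(p_subj.index))

    def cols(frame, tissue, sex=None):
        sel = subj_meta[subj_meta["tissue"] == tissue]
        if sex is not None:
            sel = sel[sel["sex"] == sex]
        return [c for c in frame.columns if c in sel.index]

    rows = []
    for acc in shared:
        a = a_subj.loc[acc, cols(a_subj, "ACL")].dropna().astype(float)
        p = p_subj.loc[acc, cols(p_subj, "PT")].dropna().astype(float)
        if len(a) < 2 or len(p) < 2 or (a <= 0).any() or (p <= 0).any():
            continue
        t_p = stats.ttest_ind(a, p, equal_var=True).pvalue
        row = {
            "accession": acc,
            "fold_change": signed_fold_change(a.mean(), p.mean()),
            "p_value": float(t_p),
            "cohen_d": cohens_d(np.log2(a), np.log2(p)),
        }
        for sex in ("F", "M"):
            asx = a_subj.loc[acc, cols(a_subj, "ACL", sex)].dropna().astype(float)
            psx = p_subj.loc[acc, cols(p_subj, "PT", sex)].dropna().astype(float)
            key = "female" if sex == "F" else "male"
            if len(asx) >= 2 and len(psx) >= 2:
                row[f"{key}_fold_change"] = signed_fold_change(asx.mean(), psx.mean())
                row[f"{key}_p_value"] = float(
                    stats.ttest_ind(asx, psx, equal_var=True).pvalue)
            else:
                row[f"{key}_fold_change"] = float("nan")
                row[f"{key}_p_value"] = float("nan")
        if counts_acl is not None:
            row["acl_peptide_count"] = int(counts_acl.get(acc, 0))
        if counts_pt is not None:
            row["pt_peptide_count"] = int(counts_pt.get(acc, 0))
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["accession", "fold_change", "p_value",
                                     "cohen_d"]).set_index("accession")
    return pd.DataFrame(rows).set_index("accession").sort_index()


def curate_comparison(comparison: pd.DataFrame, alpha: float = 0.05,
                      min_d: float = 0.8) -> pd.DataFrame:
    """Tissue-difference curation: t-test p < alpha and |d| > min_d."""
    if comparison.empty:
        return comparison
    mask = (comparison["p_value"] < alpha) & (comparison["cohen_d"].abs() > min_d)
    return comparison[mask].sort_values("p_value", kind="mergesort")


def chain_ratio(fmol: pd.DataFrame, meta: pd.DataFrame, chains: list[str],
                reference: str, tissue: str | None = None) -> pd.DataFrame:
    """Molar chain stoichiometry normalized to a reference chain.

    Computes fmol ratios chain/reference per donor (duplicate runs
    averaged), then the group mean ± SD. Donors missing any chain are
    excluded. Rows: chains; columns: mean, sd, n_donors.
    """
    sub_meta = meta if tissue is None else meta[meta["tissue"] == tissue]
    subj = _subject_means(fmol, sub_meta)
    missing = [c for c in chains + [reference] if c not in subj.index]
    if missing:
        raise KeyError(f"chains not quantified: {missing}")
    block = subj.loc[sorted(set(chains + [reference]))].dropna(axis=1)
    ratios = block.div(block.loc[reference], axis=1)
    out = pd.DataFrame({
        "mean": ratios.mean(axis=1),
        "sd": ratios.std(axis=1, ddof=1),
        "n_donors": ratios.count(axis=1).astype(int),
    })
    return out.loc[chains]


def type_ratio(pct: pd.DataFrame, meta: pd.DataFrame, tissue: str,
               type_i: tuple[str, str] = ("CO1A1_HUMAN", "CO1A2_HUMAN"),
               type_iii: str = "CO3A1_HUMAN") -> dict:
    """Type III : type I collagen ratio ("1:x"), per donor then mean ± SD.

    x = (CO1A1% + CO1A2%) / CO3A1% for each donor of the tissue; donors
    with no type III signal are excluded.
    """
    subj = _subject_means(pct, meta[meta["tissue"] == tissue])
    have = [a for a in list(type_i) + [type_iii] if a in subj.index]
    if len(have) < len(type_i) + 1:
        raise KeyError("type I/III chains not all quantified")
    ti = subj.loc[list(type_i)].sum(axis=0, min_count=1)
    tiii = subj.loc[type_iii]
    x = (ti / tiii).replace([np.inf, -np.inf], np.nan).dropna()
    return {"ratios": x, "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)), "n_donors": int(len(x))}


def albumin_ratio(pct: pd.DataFrame,
                  reference: str = ALBUMIN_ACCESSION) -> pd.DataFrame:
    """Each protein's dry-weight fraction relative to albumin, per sample.

    Proteins whose mean ratio across samples is ≥ 1 sit at or above the
    dominant blood protein and are flagged as preferentially enriched in
    the tissue. Raises :class:`MissingStandardError` if albumin is absent.
    """
    if reference not in pct.index:
        raise MissingStandardError(f"{reference!r} not quantified; "
                                   "albumin-relative analysis unavailable")
    ratios = pct.div(pct.loc[reference], axis=1)
    out = ratios.copy()
    out["mean_ratio"] = ratios.mean(axis=1)
    out["enriched"] = out["mean_ratio"] >= 1.0
    return out
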