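"""Identification FDR control and dataset-level quality control.

Covers the checks run before trusting a label-free dataset: target-decoy
peptide FDR thresholding, precision of the spiked surrogate standard
(relative standard deviation across runs), fraction uniqueness of the 2D
separation, per-fraction column load, and a z-scored PCA of the
peptide-level quantitative data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import PEPTIDE_KEY, MissingStandardError, STANDARD_ACCESSION


@dataclass
class FdrResult:
    """Outcome of decoy-based thresholding.

    ``threshold`` is the lowest (most permissive) score cut whose estimated
    FDR is at or below target; ``fdr_pct`` the estimate realized there.
    ``threshold`` is ``inf`` and counts are zero when nothing passes — an
    explicit "no identifications" result rather than an exception.
    """

    threshold: float
    fdr_pct: float
    n_targets_passing: int
    n_decoys_passing: int

    @property
    def any_identifications(self) -> bool:
        return self.n_targets_passing > 0


def estimate_fdr_pct(records: pd.DataFrame, threshold: float,
                     formula: str = "simple") -> float:
    """Estimated peptide FDR (%) at a score threshold.

    ``simple`` is the plain target-decoy ratio d/t; ``combined`` the
    2d/(t+d) variant. Returns NaN when no targets pass.
    """
    passing = records[records["score"] >= threshold]
    t = int((~passing["is_decoy"]).sum())
    d = int(passing["is_decoy"].sum())
    if t == 0:
        return float("nan")
    if formula == "simple":
        return 100.0 * d / t
    if formula == "combined":
        return 100.0 * 2 * d / (t + d)
    raise ValueError(f"unknown FDR formula {formula!r}")


def peptide_fdr_threshold(records: pd.DataFrame, target_fdr_pct: float = 2.0,
                          formula: str = "simple") -> FdrResult:
    """Find the most permissive score threshold meeting a target FDR.

    Scans candidate thresholds (the observed scores, descending
    permissiveness) and keeps the lowest one whose estimated FDR —
    decoys passing / targets passing — is at or below ``target_fdr_pct``.
    The estimator is monotone only piecewise, so all candidates are checked.
    """
    if records.empty:
        return FdrResult(float("inf"), float("nan"), 0, 0)
    rec_scores = records["score"].to_numpy(dtype=float)
    order = np.argsort(-rec_scores, kind="stable")
    sorted_scores = rec_scores[order]
    sorted_decoy = records["is_decoy"].to_numpy()[order]
    cum_d = np.cumsum(sorted_decoy)
    cum_t = np.cumsum(~sorted_decoy)
    # candidate thresholds: each distinct score, counted through its last record
    last = np.flatnonzero(np.append(np.diff(sorted_scores) != 0, True))
    t, d = cum_t[last], cum_d[last]
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "simple":
            est = np.where(t > 0, 100.0 * d / np.maximum(t, 1), np.inf)
        else:
            est = np.where(t > 0, 100.0 * 2 * d / np.maximum(t + d, 1), np.inf)
    ok = np.flatnonzero((est <= target_fdr_pct) & (t > 0))
    if ok.size == 0:
        return FdrResult(float("inf"), float("nan"), 0, 0)
    k = ok[-1]  # lowest qualifying threshold = most identifications
    return FdrResult(float(sorted_scores[last[k]]), float(est[k]),
                     int(t[k]), int(d[k]))


def apply_score_threshold(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep target records scoring at or above the threshold (decoys dropped)."""
    keep = (records["score"] >= threshold) & ~records["is_decoy"]
    return records[keep].reset_index(drop=True)


def surrogate_rsd(protein_matrix: pd.DataFrame,
                  standard_accession: str = STANDARD_ACCESSION) -> float:
    """Relative standard deviation (%) of the spiked standard across runs.

    100 × sd / mean of the standard's per-run summed intensities, duplicate
    runs kept separate; sample (n−1) standard deviation. The headline
    precision figure for the whole label-free experiment.
    """
    if standard_accession not in protein_matrix.index:
        raise MissingStandardError(
            f"surrogate standard {standard_accession!r} absent from matrix")
    values = protein_matrix.loc[standard_accession].dropna().astype(float)
    if len(values) < 2:
        raise MissingStandardError(
            f"surrogate standard observed in {len(values)} run(s); need >= 2")
    return float(100.0 * values.std(ddof=1) / values.mean())


def fraction_uniqueness(records: pd.DataFrame) -> float:
    """Percent of distinct peptides observed in exactly one LC fraction.

    Measures how cleanly the first-dimension separation partitions the
    peptide population. Returns NaN on empty input.
    """
    if records.empty:
        return float("nan")
    n_fracs = records.groupby(PEPTIDE_KEY)["fraction"].nunique()
    return float(100.0 * (n_fracs == 1).sum() / len(n_fracs))


def per_fraction_load(records: pd.DataFrame, n_fractions: int = 8) -> pd.DataFrame:
    """Peptide count and total intensity per fraction, zero-filled."""
    idx = pd.RangeIndex(1, n_fractions + 1, name="fraction")
    if records.empty:
        return pd.DataFrame({"n_peptides": 0, "total_intensity": 0.0}, index=idx)
    grouped = records.groupby("fraction").agg(
        n_peptides=("peptide", "nunique"),
        total_intensity=("intensity", "sum"),
    )
    out = grouped.reindex(idx)
    out["n_peptides"] = out["n_peptides"].fillna(0).astype(int)
    out["total_intensity"] = out["total_intensity"].fillna(0.0)
    return out


def pca_scores(peptide_matrix: pd.DataFrame, n_components: int = 3):
    """PCA of analytical runs on row-z-scored peptide intensities.

    Each peptide row is z-scored (mean 0, sd 1) across runs after missing
    cells are imputed with the row mean (imputed cells thus become 0 and are
    uninformative). Zero-variance rows are dropped and counted. The sign of
    each component is fixed so its largest-magnitude peptide loading is
    positive, making coordinates invariant to row/column order.

    Returns ``(scores, explained_variance_ratio, n_dropped)`` with one score
    row per run.
    """
    if peptide_matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two runs")
    X = peptide_matrix.astype(float)
    X = X.apply(lambda row: row.fillna(row.mean()), axis=1)
    sd = X.std(axis=1, ddof=0)
    n_dropped = int((sd == 0).sum() + X.isna().any(axis=1).sum())
    X = X[(sd > 0) & X.notna().all(axis=1)]
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
    Z = Z.sort_index()  # order-invariance
    n_components = min(n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Z.T.to_numpy())
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1
    scores = pd.DataFrame(coords, index=Z.columns,
                          columns=[f"PC{i + 1}" for i in range(n_components)])
    scores = scores.sort_index()
    return scores, pca.explained_variance_ratio_.copy(), n_dropped


def qc_report(records: pd.DataFrame, protein_matrix: pd.DataFrame,
              peptide_matrix: pd.DataFrame, n_fractions: int = 8,
              standard_accession: str = STANDARD_ACCESSION,
              target_fdr_pct: float = 2.0) -> dict:
    """Assemble the dataset-level QC panel as a dict of tables/scalars."""
    fdr = peptide_fdr_threshold(records, target_fdr_pct)
    scores, evr, n_dropped = pca_scores(peptide_matrix)
    return {
        "surrogate_rsd_pct": surrogate_rsd(protein_matrix, standard_accession),
        "pct_single_fraction": fraction_uniqueness(records[~records["is_decoy"]]),
        "per_fraction_load": per_fraction_load(records, n_fractions),
        "pca_scores": scores,
        "pca_explained_variance_ratio": evr,
        "pca_dropped_rows": n_dropped,
        "peptide_fdr_pct": fdr.fdr_pct,
        "fdr_threshold": fdr.threshold,
    }
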