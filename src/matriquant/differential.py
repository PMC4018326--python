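"""Protein roll-up and within-tissue male-vs-female differential abundance.

The relative-quantitation arm of the pipeline: peptide intensities are
summed per protein per run, duplicate runs of the same digest are averaged
to subject level, and each protein is tested for a sex difference with a
one-way error-weighted ANOVA on log2 intensities, Benjamini-Hochberg FDR
correction across the tissue's protein list, and a Cohen's d effect-size
filter (the three-criterion curation: >1 peptide, adjusted p < 0.05,
|d| > 0.8).

The "error-weighted" part reconstructs common practice for instrument
software whose exact algorithm is unpublished: per-observation weights are
inverse variances predicted from an intensity-dependent error curve fitted
to duplicate-run pairs (log-variance linear in mean log2 intensity). With
unit weights the statistic reduces exactly to the textbook one-way ANOVA.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ValidationError, subject_of

RollupResult = namedtuple("RollupResult", ["intensity", "peptide_counts"])


def rollup(peptide_matrix: pd.DataFrame) -> RollupResult:
    """Sum peptide intensities per protein per run.

    Missing peptide cells contribute nothing; a protein with no observed
    peptide in a run gets a missing cell (absence, not zero). Also returns
    the per-(protein, run) count of contributing peptides.
    """
    if peptide_matrix.empty:
        empty = pd.DataFrame(index=pd.Index([], name="accession"),
                             columns=peptide_matrix.columns)
        return RollupResult(empty, empty)
    grouped = peptide_matrix.groupby(level="accession", sort=True)
    intensity = grouped.sum(min_count=1)
    counts = grouped.count()
    return RollupResult(intensity, counts)


def average_duplicates(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate-run columns to one column per subject (donor digest).

    The mean is over available values, so a cell missing in one duplicate
    falls back to the other run's value. Column names become subject ids
    (``TISSUE_SEXdonor``). More than two replicates are still averaged.
    """
    subjects = subject_of(meta)
    mapping = subjects.reindex(matrix.columns)
    if mapping.isna().any():
        missing = list(matrix.columns[mapping.isna()])
        raise ValidationError(f"runs absent from sample table: {missing}")
    out = matrix.T.groupby(mapping).mean().T
    return out.sort_index(axis=1)


def signed_fold_change(mean_num: float, mean_den: float) -> float:
    """Ratio of linear-scale means with the signed presentation convention.

    r = num/den reported as r when r ≥ 1 and as −1/r otherwise, so a halving
    prints as −2.0 rather than 0.5. NaN when either mean is missing or
    non-positive.
    """
    if not (mean_num > 0 and mean_den > 0):
        return float("nan")
    r = mean_num / mean_den
    return float(r) if r >= 1 else float(-1.0 / r)


def fit_error_curve(matrix: pd.DataFrame, meta: pd.DataFrame,
                    min_pairs: int = 8):
    """Fit an intensity-dependent variance model from duplicate-run pairs.

    For every protein observed in both runs of a duplicated digest the
    log2 difference ``d`` estimates technical spread: var ≈ d²/2 at mean
    log2 intensity ``m``. A line is fitted to log(var) vs ``m`` and returned
    as a callable ``var(log2_intensity)``; ``None`` when fewer than
    ``min_pairs`` usable pairs exist (callers then use unit weights).
    """
    subjects = subject_of(meta)
    ms, vs = [], []
    for subj, runs in meta.groupby(subjects).groups.items():
        if len(runs) < 2:
            continue
        cols = [c for c in runs if c in matrix.columns]
        for a, b in zip(cols[:-1], cols[1:]):
            pair = matrix[[a, b]].dropna()
            pair = pair[(pair > 0).all(axis=1)]
            la, lb = np.log2(pair[a]), np.log2(pair[b])
            d2 = (la - lb) ** 2 / 2.0
            keep = d2 > 0
            ms.extend(((la + lb) / 2.0)[keep])
            vs.extend(d2[keep])
    if len(vs) < min_pairs:
        return None
    ms, vs = np.asarray(ms), np.asarray(vs)
    slope, intercept = np.polyfit(ms, np.log(vs), 1)
    lo, hi = np.percentile(vs, [5, 95])

    def var_fn(m):
        return np.clip(np.exp(intercept + slope * np.asarray(m, dtype=float)),
                       max(lo, 1e-6), max(hi, 1e-6))

    return var_fn


def error_weighted_anova(groups: list[np.ndarray],
                         weights: list[np.ndarray] | None = None):
    """One-way fixed-effects ANOVA with per-observation inverse-variance weights.

    Operates on (log2-transformed) observations. F is the weighted
    between-group mean square over the weighted within-group mean square;
    with all weights equal it is exactly the textbook one-way ANOVA.

    Returns ``(F, p)``. If the within-group variance is zero in every group
    the p-value is floored at machine precision and F is infinite
    (degenerate, flagged to the caller by the inf).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 observations each")
    if weights is None:
        weights = [np.ones_like(g) for g in groups]
    weights = [np.asarray(w, dtype=float) for w in weights]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    group_w = np.array([w.sum() for w in weights])
    group_mean = np.array([np.sum(w * g) / w.sum()
                           for g, w in zip(groups, weights)])
    grand_mean = np.sum(group_w * group_mean) / group_w.sum()
    ss_between = np.sum(group_w * (group_mean - grand_mean) ** 2)
    ss_within = sum(np.sum(w * (g - m) ** 2)
                    for g, w, m in zip(groups, weights, group_mean))
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0:
        if ss_between <= 0:
            return 0.0, 1.0
        return float("inf"), float(np.finfo(float).tiny)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def bh_adjust(p_values, method: str = "benjamini-hochberg") -> np.ndarray:
    """Multiple-testing adjustment across one tissue's protein list.

    ``benjamini-hochberg`` (default) is the step-up FDR procedure;
    ``hochberg`` the Hochberg step-up FWER variant offered because both
    names circulate for curated tables of this kind.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"benjamini-hochberg": "fdr_bh", "bh": "fdr_bh",
           "hochberg": "simes-hochberg"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference with the pooled (n−1) standard deviation.

    Computed on the same log2 scale as the ANOVA so the sign agrees with
    the fold-change direction. Zero pooled SD returns a signed infinity.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Cohen's d needs >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    diff = a.mean() - b.mean()
    if pooled == 0:
        return float(np.copysign(np.inf, diff)) if diff != 0 else 0.0
    return float(diff / pooled)


def differential_analysis(protein_matrix: pd.DataFrame, meta: pd.DataFrame,
                          tissue: str, weight_model=None,
                          adjust_method: str = "benjamini-hochberg",
                          use_weights: bool = True) -> pd.DataFrame:
    """Male-vs-female differential abundance within one tissue.

    ``protein_matrix`` holds run-level summed intensities; duplicates are
    averaged to subject level internally. ``weight_model`` is the callable
    from :func:`fit_error_curve` (fitted on the run-level matrix); when
    ``None`` and ``use_weights`` is true it is fitted here, falling back to
    unit weights if the dataset has no duplicate runs.

    Returns one row per protein: group means (log2), signed fold change
    (M/F), raw and adjusted p, Cohen's d, peptide count.
    """
    tmeta = meta[meta["tissue"] == tissue]
    cols = [c for c in protein_matrix.columns if c in tmeta.index]
    matrix = protein_matrix[cols]
    if use_weights and weight_model is None:
        weight_model = fit_error_curve(matrix, tmeta)
    subj_matrix = average_duplicates(matrix, tmeta)
    subj_sex = {f"{r['tissue']}_{r['sex']}{r['donor']}": r["sex"]
                for _, r in tmeta.iterrows()}
    m_cols = sorted(c for c in subj_matrix.columns if subj_sex.get(c) == "M")
    f_cols = sorted(c for c in subj_matrix.columns if subj_sex.get(c) == "F")

    rows = []
    for acc, row in subj_matrix.iterrows():
        a = row[m_cols].dropna().astype(float)
        b = row[f_cols].dropna().astype(float)
        if len(a) < 2 or len(b) < 2 or (a <= 0).any() or (b <= 0).any():
            continue
        la, lb = np.log2(a.to_numpy()), np.log2(b.to_numpy())
        if use_weights and weight_model is not None:
            wa, wb = 1.0 / weight_model(la), 1.0 / weight_model(lb)
        else:
            wa, wb = np.ones_like(la), np.ones_like(lb)
        _, p = error_weighted_anova([la, lb], [wa, wb])
        rows.append({
            "accession": acc,
            "mean_log2_m": la.mean(),
            "mean_log2_f": lb.mean(),
            "fold_change": signed_fold_change(a.mean(), b.mean()),
            "p_raw": p,
            "cohen_d": cohens_d(la, lb),
            "n_m": len(a),
            "n_f": len(b),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=["accession", "mean_log2_m", "mean_log2_f",
                                     "fold_change", "p_raw", "p_adj", "cohen_d",
                                     "n_m", "n_f"]).set_index("accession")
    result = result.set_index("accession").sort_index()
    result["p_adj"] = bh_adjust(result["p_raw"], method=adjust_method)
    return result


def curate(results: pd.DataFrame, peptide_counts: pd.Series,
           min_peptides: int = 2, alpha: float = 0.05,
           min_d: float = 0.8) -> pd.DataFrame:
    """Apply the three-criterion curation and sort by adjusted p.

    Keeps proteins with more than one matched peptide (``min_peptides`` ≥ 2
    by default), adjusted p below ``alpha`` and |Cohen's d| above ``min_d``.
    A ``curated`` column is added to a copy of ``results``; the returned
    frame is the curated subset ordered by (p_adj, accession).
    """
    if results.empty:
        out = results.copy()
        out["curated"] = pd.Series(dtype=bool)
        return out
    counts = peptide_counts.reindex(results.index).fillna(0)
    mask = ((counts >= min_peptides)
            & (results["p_adj"] < alpha)
            & (results["cohen_d"].abs() > min_d))
    out = results.copy()
    out["peptide_count"] = counts.astype(int)
    out["curated"] = mask
    return out[mask].sort_index(kind="mergesort").sort_values("p_adj", kind="mergesort")
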