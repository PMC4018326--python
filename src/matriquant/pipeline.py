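"""End-to-end orchestration: simulate/read → QC → differential → Hi3 → report.

Each stage writes its tables as TSV into the output directory so any stage
can be rerun or inspected in isolation. Every output starts with a comment
line carrying the config hash and seed; rerunning with an identical config
and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import absquant, annotation, differential, qc
from .io import (merge_fractions, molecular_weights, read_fasta,
                 read_peptide_table, read_sample_table, write_peptide_table,
                 write_sample_table)
from .model import STANDARD_ACCESSION, TISSUES
from .simulate import SimulationConfig, panel_proteins, simulate_dataset

log = logging.getLogger("matriquant")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one serializable object."""

    peptide_table: str | None = None    # input TSV; None → simulate
    sample_table: str | None = None
    fasta: str | None = None            # protein sequences for MW; None → panel
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    target_fdr_pct: float = 2.0
    alpha: float = 0.05
    min_d: float = 0.8
    min_peptides: int = 2
    top_k: int = 3
    standard_accession: str = STANDARD_ACCESSION
    annotation_table: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        sim = payload.pop("simulation")
        sim.pop("panel", None)  # frames are not hashable; panel is part of code/data
        payload["simulation"] = sim
        return hashlib.md5(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _stamp(config: PipelineConfig) -> str:
    return f"matriquant config={config.config_hash()} seed={config.seed}"


def _write(frame: pd.DataFrame, path: Path, stamp: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns the in-memory results keyed like the files.

    On stage failure the partially written outputs are removed and the
    error is re-raised naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stamp = _stamp(config)
    results: dict = {}
    stage = "setup"

    def write(frame, name, index=True):
        path = outdir / name
        _write(frame, path, stamp, index=index)
        written.append(path)

    try:
        # ------------------------------------------------ input / simulation
        stage = "input"
        truth = None
        if config.peptide_table is None:
            sim = simulate_dataset(config.simulation, seed=config.seed)
            records, meta, truth = sim
            write_peptide_table(records, outdir / "peptides.tsv", header_comment=stamp)
            write_sample_table(meta, outdir / "samples.tsv", header_comment=stamp)
            written += [outdir / "peptides.tsv", outdir / "samples.tsv"]
            truth.write(outdir, header_comment=stamp)
            written += [outdir / f"truth_{n}.tsv"
                        for n in ("proteins", "sample_fmol", "peptides")]
            proteins = panel_proteins(config.simulation.resolved_panel())
        else:
            records = read_peptide_table(config.peptide_table)
            if config.sample_table is None:
                raise ValueError("sample_table is required with peptide_table input")
            meta = read_sample_table(config.sample_table)
            if config.fasta is None:
                raise ValueError("fasta is required with peptide_table input")
            proteins = read_fasta(config.fasta)
        mw = molecular_weights(proteins)
        log.info("input: %d peptide records, %d runs", len(records), len(meta))
        results["records"], results["meta"], results["truth"] = records, meta, truth

        # ------------------------------------------------ per-tissue processing
        quants, pcts, counts, matrices, diffs = {}, {}, {}, {}, {}
        annotated = {}
        qc_rows = []
        for tissue in TISSUES:
            stage = f"fdr_filter[{tissue}]"
            t_meta = meta[meta["tissue"] == tissue]
            t_records = records[records["sample_id"].isin(t_meta.index)]
            fdr = qc.peptide_fdr_threshold(t_records, config.target_fdr_pct)
            filtered = qc.apply_score_threshold(t_records, fdr.threshold)
            log.info("%s: FDR threshold %.3f → %d of %d target records kept",
                     tissue, fdr.threshold, len(filtered),
                     int((~t_records["is_decoy"]).sum()))

            stage = f"merge_fractions[{tissue}]"
            merged = merge_fractions(filtered)
            pep_matrix = merged.matrix

            stage = f"rollup[{tissue}]"
            rolled = differential.rollup(pep_matrix)
            matrices[tissue] = rolled
            write(rolled.intensity, f"protein_matrix_{tissue}.tsv")

            stage = f"qc[{tissue}]"
            report = qc.qc_report(t_records, rolled.intensity, pep_matrix,
                                  n_fractions=config.simulation.n_fractions,
                                  standard_accession=config.standard_accession,
                                  target_fdr_pct=config.target_fdr_pct)
            qc_rows.append({
                "tissue": tissue,
                "surrogate_rsd_pct": report["surrogate_rsd_pct"],
                "pct_single_fraction": report["pct_single_fraction"],
                "peptide_fdr_pct": report["peptide_fdr_pct"],
                "fdr_threshold": report["fdr_threshold"],
                "n_peptides": pep_matrix.shape[0],
                "n_proteins": rolled.intensity.shape[0],
            })
            write(report["per_fraction_load"], f"fraction_load_{tissue}.tsv")
            write(report["pca_scores"], f"pca_scores_{tissue}.tsv")

            stage = f"differential[{tissue}]"
            diff = differential.differential_analysis(rolled.intensity, meta, tissue)
            total_counts = rolled.peptide_counts.max(axis=1)
            curated = differential.curate(diff, total_counts,
                                          min_peptides=config.min_peptides,
                                          alpha=config.alpha, min_d=config.min_d)
            diffs[tissue] = (diff, curated)
            write(diff, f"differential_{tissue}.tsv")
            write(curated, f"differential_curated_{tissue}.tsv")
            log.info("%s: %d proteins tested, %d curated", tissue,
                     len(diff), len(curated))

            stage = f"absolute_quant[{tissue}]"
            quant = absquant.quantify(pep_matrix, t_meta, mw, k=config.top_k,
                                      standard_accession=config.standard_accession)
            quants[tissue] = quant
            pcts[tissue] = quant.pct_dry_weight
            counts[tissue] = total_counts
            long = pd.concat({"fmol": quant.fmol.drop(index=config.standard_accession,
                                                      errors="ignore"),
                              "ng": quant.ng,
                              "pct_dry_weight": quant.pct_dry_weight},
                             names=["quantity"])
            write(long, f"absolute_quant_{tissue}.tsv")

            stage = f"annotation[{tissue}]"
            annotated[tissue] = annotation.annotate_proteins(
                rolled.intensity.index,
                annotation.load_annotation_table(config.annotation_table))

        stage = "qc_summary"
        write(pd.DataFrame(qc_rows).set_index("tissue"), "qc_summary.tsv")

        # ------------------------------------------------ cross-tissue analyses
        stage = "compare_tissues"
        comparison = absquant.compare_tissues(
            pcts["ACL"], pcts["PT"], meta,
            counts_acl=counts["ACL"], counts_pt=counts["PT"])
        comp_curated = absquant.curate_comparison(comparison, alpha=config.alpha,
                                                  min_d=config.min_d)
        write(comparison, "tissue_comparison.tsv")
        write(comp_curated, "tissue_comparison_curated.tsv")
        log.info("tissue comparison: %d shared proteins, %d curated",
                 len(comparison), len(comp_curated))

        stage = "ratios"
        ratio_rows = []
        for tissue in TISSUES:
            try:
                tr = absquant.type_ratio(pcts[tissue], meta, tissue)
                ratio_rows.append({"tissue": tissue, "ratio": "typeI:typeIII",
                                   "mean": tr["mean"], "sd": tr["sd"],
                                   "n_donors": tr["n_donors"]})
            except KeyError:
                pass
            try:
                cr = absquant.chain_ratio(
                    quants[tissue].fmol, meta,
                    ["CO6A1_HUMAN", "CO6A2_HUMAN", "CO6A3_HUMAN"],
                    reference="CO6A2_HUMAN", tissue=tissue)
                for acc, row in cr.iterrows():
                    ratio_rows.append({"tissue": tissue,
                                       "ratio": f"{acc}:CO6A2_HUMAN",
                                       "mean": row["mean"], "sd": row["sd"],
                                       "n_donors": row["n_donors"]})
            except KeyError:
                pass
        write(pd.DataFrame(ratio_rows), "ratios.tsv", index=False)

        stage = "albumin"
        alb = {}
        for tissue in TISSUES:
            try:
                alb[tissue] = absquant.albumin_ratio(pcts[tissue])
                write(alb[tissue], f"albumin_ratio_{tissue}.tsv")
            except KeyError:
                log.warning("%s: albumin not quantified; ratio table skipped", tissue)

        stage = "annotation_tally"
        tally = annotation.tissue_tallies(annotated)
        write(tally, "category_tally.tsv")

        stage = "report"
        table1 = _table1_style(diffs, annotated)
        table2 = _table2_style(comp_curated, annotated)
        write(table1, "table1_differential.tsv")
        write(table2, "table2_tissue_comparison.tsv")
        _write_summary(outdir / "summary.txt", stamp, qc_rows, diffs,
                       comparison, comp_curated)
        written.append(outdir / "summary.txt")

        results.update(matrices=matrices, diffs=diffs, quants=quants,
                       comparison=comparison, comparison_curated=comp_curated,
                       tally=tally, qc=qc_rows, table1=table1, table2=table2)
        return results
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _table1_style(diffs: dict, annotated: dict) -> pd.DataFrame:
    """Curated male/female differential table with ACL and PT side by side."""
    cols = {}
    curated_union: set = set()
    for tissue in TISSUES:
        diff, curated = diffs[tissue]
        curated_union |= set(curated.index)
        cols[tissue] = diff
    rows = []
    for acc in sorted(curated_union):
        ann_source = next(iter(annotated.values()))
        row = {"accession": acc,
               "gene": ann_source["gene"].get(acc, ""),
               "description": ann_source.get("description", pd.Series()).get(acc, "")}
        for tissue in TISSUES:
            diff, _ = diffs[tissue]
            if acc in diff.index:
                d = diff.loc[acc]
                row[f"{tissue}_peptide_count"] = int(
                    diffs[tissue][1]["peptide_count"].get(acc, 0)) or ""
                row[f"{tissue}_fold_change_mf"] = d["fold_change"]
                row[f"{tissue}_p_adj"] = d["p_adj"]
                row[f"{tissue}_cohen_d"] = d["cohen_d"]
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.set_index("accession") if not frame.empty else pd.DataFrame(
        columns=["accession"]).set_index("accession")


def _table2_style(comp_curated: pd.DataFrame, annotated: dict) -> pd.DataFrame:
    ann = pd.concat(annotated.values())
    ann = ann[~ann.index.duplicated()]
    out = comp_curated.copy()
    if out.empty:
        return out
    out.insert(0, "gene", ann["gene"].reindex(out.index).fillna(""))
    out.insert(1, "description",
               ann.get("description", pd.Series(dtype=object))
               .reindex(out.index).fillna(""))
    order = ["gene", "description", "acl_peptide_count", "pt_peptide_count",
             "fold_change", "p_value", "cohen_d", "female_fold_change",
             "female_p_value", "male_fold_change", "male_p_value"]
    return out[[c for c in order if c in out.columns]]


def _write_summary(path: Path, stamp: str, qc_rows, diffs, comparison,
                   comp_curated) -> None:
    lines = [f"# {stamp}", ""]
    for row in qc_rows:
        lines.append(
            f"{row['tissue']}: {row['n_peptides']} peptides, "
            f"{row['n_proteins']} proteins, surrogate RSD "
            f"{row['surrogate_rsd_pct']:.1f}%, single-fraction "
            f"{row['pct_single_fraction']:.1f}%, peptide FDR "
            f"{row['peptide_fdr_pct']:.2f}%")
    for tissue in TISSUES:
        diff, curated = diffs[tissue]
        lines.append(f"{tissue}: {len(curated)} of {len(diff)} proteins "
                     "pass male/female curation")
    lines.append(f"tissue comparison: {len(comp_curated)} of {len(comparison)} "
                 "shared proteins differentially abundant")
    path.write_text("\n".join(lines) + "\n")
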