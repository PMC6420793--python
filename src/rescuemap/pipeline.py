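"""End-to-end orchestration: simulate or load, preprocess, test, classify.

``run_pipeline`` realizes the whole knockdown/rescue workflow: count
filtering, size factors, batch adjustment, the endogenous profile
(iLuc vs iEF) plus one DE table per rescue construct, response-element
discovery and gene classification, rescue status / fidelity / strength /
overlap summaries, and profile-level clustering and PCA.  Every output is
written with deterministic formatting and a manifest records inputs,
parameters, per-stage row counts and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .diff_expr import Contrast, differential_expression, estimate_dispersion
from .elements import ScanParams, assign_response_classes, find_ggaa_microsatellites, scan_ets_motif
from .preprocess import (adjusted_pseudocounts, combat_adjust, condition_design,
                         estimate_size_factors, filter_low_counts, normalized_log2)
from .rescue import (AnalysisParams, classify_rescue_status, direction_fidelity,
                     rescue_strength, strata_rescue_summary, twofold_gene_sets,
                     venn_overlap_test)
from .simulate import SimConfig, simulate_annotation, simulate_experiment
from .summaries import hierarchical_cluster, linkage_to_newick, pca_scores, top_variable_genes

__all__ = ["PipelineConfig", "run_pipeline", "rescue_tables"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Where the inputs come from and how the stages are parameterized.

    Either ``sim`` is given (synthetic inputs are generated in memory) or
    the explicit paths are; ``constructs`` defaults to every condition other
    than the endogenous label and the control.
    """

    out_dir: str = "rescuemap_out"
    sim: SimConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    fasta_path: str | None = None
    genes_path: str | None = None
    elements_path: str | None = None
    constructs: list[str] | None = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    scan: ScanParams = field(default_factory=ScanParams)
    top_n_variable: int = 100
    seed: int = 0
    write_fasta: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def rescue_tables(counts: pd.DataFrame, samples: pd.DataFrame,
                  constructs: list[str], params: AnalysisParams,
                  adjust_batches: bool = True):
    """Preprocess and produce the endogenous + per-construct DE tables.

    Returns (endo_table, {construct: table}, adjusted_log2, filtered_counts).
    Batch adjustment is skipped when only one batch is present.
    """
    filtered = filter_low_counts(counts)
    sf = estimate_size_factors(filtered)
    logexpr = normalized_log2(filtered, sf)
    n_batches = samples["batch"].nunique()
    if adjust_batches and n_batches > 1:
        design = condition_design(samples)
        adjusted_log = combat_adjust(logexpr, samples, design)
        de_counts = adjusted_pseudocounts(adjusted_log)
    else:
        adjusted_log = logexpr
        de_counts = filtered
    # one size-factor set and one pooled dispersion per gene, shared by all
    # contrasts of the experiment
    sf_de = estimate_size_factors(de_counts)
    meta = samples.set_index("sample")
    alphas, _, nu = estimate_dispersion(
        de_counts, sf_de, conditions=meta.loc[de_counts.columns, "condition"])
    endo = differential_expression(
        de_counts, samples, Contrast(params.endo_label, params.control),
        size_factors=sf_de, alphas=alphas, nu=nu)
    tables = {
        c: differential_expression(de_counts, samples, Contrast(c, params.control),
                                   size_factors=sf_de, alphas=alphas, nu=nu)
        for c in constructs
    }
    return endo, tables, adjusted_log, filtered


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure aborts with the stage named; stages completed so far are listed
    in the manifest written next to the partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "analysis": dataclasses.asdict(config.analysis),
            "scan": dataclasses.asdict(config.scan),
            "top_n_variable": config.top_n_variable,
        },
        "stages": {},
        "outputs": {},
        "complete": False,
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    stage = "inputs"
    try:
        truth = None
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            counts, samples, truth = simulate_experiment(sim)
            chroms, genes, elements_truth = simulate_annotation(sim)
            io.write_counts(counts, out / "counts.tsv")
            io.write_tsv(samples, out / "samples.tsv")
            io.write_tsv(truth.table, out / "sim_truth.tsv")
            io.genes_to_bed(genes, out / "genes.bed")
            if config.write_fasta:
                io.write_fasta(chroms, out / "genome.fa")
        else:
            counts = io.read_counts(config.counts_path)
            samples = io.read_samples(config.samples_path)
            genes = io.bed_to_genes(io.read_bed(config.genes_path)) if config.genes_path else None
            chroms = io.read_fasta(config.fasta_path) if config.fasta_path else None
        conditions = set(samples["condition"])
        params = config.analysis
        if params.control not in conditions:
            raise ValueError(f"control condition {params.control!r} absent from samples")
        if params.endo_label not in conditions:
            raise ValueError(f"endogenous condition {params.endo_label!r} absent from samples")
        constructs = config.constructs or sorted(
            conditions - {params.control, params.endo_label})
        if not constructs:
            raise ValueError("no rescue constructs found in the sample sheet")
        manifest["stages"][stage] = {"genes": int(counts.shape[0]),
                                     "samples": int(counts.shape[1]),
                                     "constructs": constructs}

        stage = "preprocess_and_de"
        endo, tables, adjusted_log, filtered = rescue_tables(
            counts, samples, constructs, params)
        io.write_tsv(endo, out / "de_endo.tsv")
        for c, t in tables.items():
            io.write_tsv(t, out / f"de_{c}.tsv")
        io.write_tsv(adjusted_log.rename_axis("gene"), out / "adjusted_log2.tsv", index=True)
        manifest["stages"][stage] = {
            "genes_tested": int(len(endo)),
            "endo_significant": int(((endo["padj"] < params.alpha)).sum()),
        }

        stage = "response_elements"
        classes = None
        if config.sim is not None or (chroms and genes is not None):
            parts = []
            for chrom, seq in chroms.items():
                parts.append(find_ggaa_microsatellites(seq, config.scan, chrom=chrom))
                parts.append(scan_ets_motif(seq, config.scan, chrom=chrom))
            elements = pd.concat(parts, ignore_index=True)
            elements.insert(4, "element_id", [f"e{i:05d}" for i in range(len(elements))])
            if config.elements_path:
                extra = io.read_bed(config.elements_path)
                extra_df = pd.DataFrame({
                    "chrom": extra["chrom"], "start": extra["start"], "end": extra["end"],
                    "strand": extra["strand"], "element_id": extra["name"],
                    "type": "other_fli", "max_consecutive": 0, "total_repeats": 0,
                    "fli_enrichment": float("nan"),
                })
                elements = pd.concat([elements, extra_df], ignore_index=True)
            classes = assign_response_classes(genes, elements, endo, config.scan)
            io.write_bed(elements, out / "elements.bed",
                         extra_cols=("type", "max_consecutive", "total_repeats"))
            io.write_tsv(classes, out / "gene_classes.tsv")
            manifest["stages"][stage] = {
                "elements": int(len(elements)),
                "classified": int((classes["element_class"] != "none").sum()),
            }
        else:
            manifest["stages"][stage] = {"skipped": "no sequence/annotation inputs"}

        stage = "rescue_analysis"
        calls = {c: classify_rescue_status(endo, tables[c], params) for c in constructs}
        for c, df in calls.items():
            io.write_tsv(df, out / f"rescue_calls_{c}.tsv")
        fidelity = direction_fidelity(calls, classes, params)
        io.write_tsv(fidelity, out / "fidelity.tsv")
        strengths = pd.DataFrame(
            [dict(construct=c, **dataclasses.asdict(
                rescue_strength(endo, tables[c], calls[c], params)))
             for c in constructs])
        io.write_tsv(strengths, out / "rescue_strength.tsv")
        strata = strata_rescue_summary(calls, classes, endo, tables, params)
        io.write_tsv(strata, out / "strata_summary.tsv")

        endo_act, endo_rep = twofold_gene_sets(endo, params)
        universe = set(endo["gene"])
        venn = {}
        for c in constructs:
            act, rep = twofold_gene_sets(tables[c], params)
            shared = universe & set(tables[c]["gene"])
            venn[c] = {
                "activated": dataclasses.asdict(
                    venn_overlap_test(endo_act & shared, act & shared, shared)),
                "repressed": dataclasses.asdict(
                    venn_overlap_test(endo_rep & shared, rep & shared, shared)),
            }
        (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
        manifest["stages"][stage] = {
            c: int((calls[c]["status"] == "both_significant").sum()) for c in constructs}

        stage = "profile_summaries"
        top = top_variable_genes(adjusted_log, min(config.top_n_variable, len(adjusted_log)))
        Z, labels = hierarchical_cluster(adjusted_log.loc[top])
        (out / "cluster_top_genes.nwk").write_text(linkage_to_newick(Z, labels) + "\n")
        scores, fractions = pca_scores(adjusted_log)
        pca = scores.rename_axis("sample").reset_index()
        io.write_tsv(pca, out / "pca_scores.tsv")
        io.write_tsv(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(fractions))],
                                   "variance_fraction": fractions}),
                     out / "pca_variance.tsv")
        manifest["stages"][stage] = {"top_variable": len(top)}

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    _write_manifest()
    return manifest
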