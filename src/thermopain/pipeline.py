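"""End-to-end orchestration of the genotype-phenotype association analysis.

The pipeline runs in two main steps: first the pain phenotype is constructed
without supervision (UV-B effect derivation, decorrelation, self-organizing
map projection, U-matrix watershed clustering, rule-based explanation,
cluster statistics); then the genotype matrix is filtered through the fixed
funnel and submitted to the random-forest association harness with its
permutation and negative-control checks.  Every stage writes its outputs to
the run directory and can be re-run individually.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CohortSpec, generate_cohort, read_phenotypes,
                     write_phenotypes, write_vcf)
from .esom import compute_umatrix, extract_clusters, train_esom
from .forest import AssocConfig, run_association
from .genotypes import (GenotypeMatrix, cluster_allele_frequencies,
                        preprocess_genotypes, read_genotype_table, read_vcf,
                        variant_class_summary)
from .phenotype import cluster_stats, derive_uvb_effects, feature_matrix
from .phenotype import silhouette_index
from .rules import induce_rules
from .scores import compare_score_sets, read_score_table

__all__ = ["PipelineConfig", "run_pipeline", "phenotype_stage",
           "prepare_stage", "associate_stage", "simulate_stage",
           "packaged_selected_variants"]

log = logging.getLogger("thermopain")


@dataclass
class PipelineConfig:
    """Structured configuration of a pipeline run.

    Defaults equal the study settings: a 50×80 toroidal map trained for 20
    epochs, two clusters, HWE exclusion at alpha 0.05, ABC retention of set
    "A" at every filter stage, and 10 repetitions of 1500-tree forests with
    0.2*sqrt(d) features on stratified 2/3 Monte-Carlo splits.
    """

    outdir: Path
    phenotype_csv: Path | None = None
    genotype_vcf: Path | None = None
    genotype_tsv: Path | None = None   # codes TSV; requires locus_tsv
    locus_tsv: Path | None = None
    score_tsv: Path | None = None
    esom_rows: int = 50
    esom_cols: int = 80
    esom_epochs: int = 20
    n_clusters: int = 2
    min_cluster_size: int | None = None   # default: 10% of subjects
    umatrix_smooth: int = 5
    correlation_threshold: float = 0.8
    hwe_alpha: float = 0.05
    abc_retain: str = "A"
    shannon_mode: str = "carrier"
    assoc: AssocConfig = field(default_factory=AssocConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        assoc = AssocConfig(**raw.pop("assoc", {}))
        paths = {k: Path(v) for k, v in raw.items()
                 if k.endswith(("csv", "vcf", "tsv", "outdir")) and v}
        raw.update(paths)
        return cls(assoc=assoc, **raw)


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.FileHandler(outdir / "pipeline.log"),
                logging.StreamHandler(sys.stderr)]
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(message)s")
    log.info("thermopain %s (numpy %s, pandas %s)", __version__,
             np.__version__, pd.__version__)


def simulate_stage(config: PipelineConfig, spec: CohortSpec | None = None):
    """Generate a synthetic cohort and write its files into the run dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or CohortSpec(seed=config.seed)
    table, labels, matrix = generate_cohort(spec)
    write_phenotypes(table, outdir / "phenotypes.csv")
    write_vcf(matrix, outdir / "genotypes.vcf")
    matrix.to_tsv(outdir / "genotype_codes.tsv", outdir / "locus_info.tsv")
    pd.Series(labels, index=table.index, name="planted_cluster").to_csv(
        outdir / "planted_labels.tsv", sep="\t")
    log.info("simulated cohort: %d subjects, %d loci", len(table),
             matrix.n_loci)
    return table, labels, matrix


def phenotype_stage(config: PipelineConfig, table: pd.DataFrame):
    """Construct the pain phenotype: derive, decorrelate, project, cluster."""
    outdir = Path(config.outdir)
    table = derive_uvb_effects(table)
    features, blocks = feature_matrix(
        table, threshold=config.correlation_threshold)
    for blk in blocks:
        log.info("decorrelated block %s -> eigenvalues %s, retained %s",
                 blk.variables, np.round(blk.eigenvalues, 3), blk.retained)
    model = train_esom(features.to_numpy(), rows=config.esom_rows,
                       cols=config.esom_cols, epochs=config.esom_epochs,
                       seed=config.seed)
    umatrix = compute_umatrix(model, features.to_numpy())
    min_size = config.min_cluster_size
    if min_size is None:
        min_size = max(2, round(0.1 * len(table)))
    labels = extract_clusters(umatrix, config.n_clusters, min_size=min_size,
                              smooth=config.umatrix_smooth) + 1
    sil = silhouette_index(features.to_numpy(), labels)
    ruleset = induce_rules(table[[c for c in table.columns if c != "sex"]],
                           labels, seed=config.seed)
    sex = table["sex"] if "sex" in table.columns else None
    stats_ = cluster_stats(table, labels, sex=sex)

    pd.DataFrame(umatrix.heights).to_csv(outdir / "umatrix.tsv", sep="\t",
                                         header=False, index=False)
    pd.Series(labels, index=table.index, name="cluster").to_csv(
        outdir / "cluster_labels.tsv", sep="\t")
    (outdir / "rules.txt").write_text(ruleset.to_text() + "\n")
    (outdir / "rules.json").write_text(json.dumps(ruleset.to_json(), indent=2))
    stats_.anova.to_csv(outdir / "cluster_anova.tsv", sep="\t", index=False)
    stats_.t_tests.to_csv(outdir / "cluster_ttests.tsv", sep="\t", index=False)
    sizes = pd.Series(labels).value_counts().sort_index()
    log.info("clusters: sizes %s, silhouette %.3f", sizes.to_dict(), sil)
    return {
        "table": table, "features": features, "blocks": blocks,
        "model": model, "umatrix": umatrix, "labels": labels,
        "silhouette": sil, "rules": ruleset, "stats": stats_,
    }


def prepare_stage(config: PipelineConfig, matrix: GenotypeMatrix, labels):
    """Run the genotype filter funnel against the phenotype clusters."""
    outdir = Path(config.outdir)
    summary = variant_class_summary(matrix.info)
    filtered, funnel = preprocess_genotypes(
        matrix, labels, hwe_alpha=config.hwe_alpha,
        shannon_mode=config.shannon_mode, retain=config.abc_retain)
    funnel.hwe_report.to_csv(outdir / "filter_hwe.tsv", sep="\t")
    funnel.shannon_report.to_csv(outdir / "filter_shannon.tsv", sep="\t")
    funnel.chi2_report.to_csv(outdir / "filter_chi2.tsv", sep="\t")
    freqs = cluster_allele_frequencies(filtered, labels)
    freqs.to_csv(outdir / "cluster_allele_frequencies.tsv", sep="\t")
    log.info("variant classes [%%]: %s",
             {k: round(v, 1) for k, v in summary.items()})
    log.info("filter funnel: %s", funnel.summary())
    return filtered, funnel


def associate_stage(config: PipelineConfig, filtered: GenotypeMatrix, labels):
    """Random-forest association with permutation and negative controls."""
    outdir = Path(config.outdir)
    report = run_association(filtered, labels, config.assoc)
    (outdir / "association_report.json").write_text(report.to_json())
    report.importances.sort_values(ascending=False).to_csv(
        outdir / "importances.tsv", sep="\t")
    pd.Series(report.final_set, name="locus").to_csv(
        outdir / "final_set_A.tsv", sep="\t", index=False)
    if report.gene_tallies is not None:
        report.gene_tallies.to_csv(outdir / "gene_tallies.tsv", sep="\t")
    log.info("association: %s", report.metrics["balanced_accuracy"])
    log.info("final set A: %d of %d loci", len(report.final_set),
             len(report.initial_set))
    return report


def scores_stage(config: PipelineConfig, sets: dict):
    outdir = Path(config.outdir)
    result = compare_score_sets(sets)
    result["moments"].to_csv(outdir / "score_moments.tsv", sep="\t", index=False)
    result["tests"].to_csv(outdir / "score_tests.tsv", sep="\t", index=False)
    return result


def run_pipeline(config: PipelineConfig,
                 spec: CohortSpec | None = None) -> dict:
    """Execute the full analysis and write a report bundle.

    With no input paths configured, a synthetic cohort is generated first.
    Returns a dict with every stage's in-memory results.
    """
    outdir = Path(config.outdir)
    _setup_logging(outdir)

    if config.phenotype_csv is None:
        table, planted, matrix = simulate_stage(config, spec)
    else:
        table = read_phenotypes(config.phenotype_csv)
        planted = None
        if config.genotype_vcf is not None:
            matrix = read_vcf(config.genotype_vcf)
        elif config.genotype_tsv is not None and config.locus_tsv is not None:
            matrix = read_genotype_table(config.genotype_tsv, config.locus_tsv)
        else:
            raise ValueError("no genotype source configured")

    pheno = phenotype_stage(config, table)
    filtered, funnel = prepare_stage(config, matrix, pheno["labels"])
    report = associate_stage(config, filtered, pheno["labels"])
    scores = None
    if config.score_tsv is not None:
        score_values = read_score_table(config.score_tsv)
        sets = {
            "set_A": score_values.reindex(report.final_set).dropna().to_numpy(),
            "all": score_values.to_numpy(),
        }
        scores = scores_stage(config, sets)

    summary = {
        "n_subjects": int(len(table)),
        "cluster_sizes": pd.Series(pheno["labels"]).value_counts()
        .sort_index().to_dict(),
        "silhouette": pheno["silhouette"],
        "funnel": funnel.summary(),
        "metrics": report.metrics,
        "n_final_set": len(report.final_set),
        "control_audit": report.control_audit,
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=str))
    log.info("pipeline complete: %s", outdir / "summary.json")
    return {"table": table, "planted": planted, "phenotype": pheno,
            "matrix": matrix, "filtered": filtered, "funnel": funnel,
            "association": report, "scores": scores, "summary": summary}


def packaged_selected_variants() -> pd.DataFrame:
    """The published final set "A" of selected variants, as a DataFrame.

    38 variants with gene, rank, locus id, molecular consequence, dbSNP id
    and per-cluster allelic frequencies (percent; missing entries are NaN).
    """
    from importlib.resources import files

    path = files("thermopain.data").joinpath("selected_variants.tsv")
    frame = pd.read_csv(path, sep="\t", na_values=["-"])
    return frame
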