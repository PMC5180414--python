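"""Single-patient orchestration of the three layers.

``run_patient`` reads the mutation profile, scores every variant (layer 1),
aggregates and ranks genes (layer 2), searches and ranks drugs (layer 3),
and writes the three CSV tables plus the JSON mirror. Given fixed inputs,
models, and resources the run is deterministic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .drug_layer import DrugResources, InteractionRecord, NeighborLink, rank_drugs, find_drug_candidates
from .errors import ConfigurationError, EmptyInputError
from .formats_io import (
    Category,
    PatientProfile,
    SvKind,
    VariantRecord,
    read_annovar_input,
    read_bed_structural,
    read_vcf,
    write_outputs,
)
from .gene_layer import (
    GeneAnnotationResources,
    GeneEvidence,
    LogisticDriverModel,
    assign_closest_gene,
    categorize_gene,
    category_label,
    rank_genes,
)
from .tds import TdsDatabase
from .variant_layer import (
    Category as _C,  # noqa: F401  (re-exported for callers)
    CnvSignalRegion,
    EnsembleSvmModel,
    ScoreCategory,
    VariantScore,
    annotate_coding,
    score_coding,
    score_indel,
    score_noncoding,
    score_structural,
)

logger = logging.getLogger(__name__)

_CATEGORY_LABEL = {
    Category.CODING_POINT: "Point coding mutation",
    Category.NONCODING_POINT: "Point non-coding mutation",
    Category.INDEL: "Structural variation",
    Category.STRUCTURAL: "Structural variation",
}

_SCORE_LABEL = {
    ScoreCategory.RADIAL_SVM: "Radial SVM",
    ScoreCategory.FUNSEQ2: "FunSeq2",
    ScoreCategory.CNV_SIGNAL: "Normalized CNV signal",
}


@dataclass
class RunConfig:
    input_path: str | Path
    resource_dir: str | Path
    variant_model: str | Path
    gene_model: str | Path
    out_prefix: str | Path
    input_format: str = "annovar"  # annovar | vcf
    sample: str | None = None
    bed_sv: str | Path | None = None
    subtype: str | None = None
    genome_build: str = "hg19"
    cutoff: float = 0.11
    germline_tags: frozenset[str] = frozenset({"GERMLINE"})
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("input_path", "resource_dir", "variant_model", "gene_model"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"{name} does not exist: {p}")
        if self.bed_sv is not None and not Path(self.bed_sv).exists():
            raise ConfigurationError(f"bed_sv does not exist: {self.bed_sv}")
        if self.input_format not in ("annovar", "vcf"):
            raise ConfigurationError(f"unknown input format {self.input_format!r}")
        if self.genome_build not in ("hg18", "hg19", "hg38"):
            raise ConfigurationError(f"unknown genome build {self.genome_build!r}")


@dataclass
class LoadedResources:
    gene: GeneAnnotationResources
    regions: list[CnvSignalRegion]
    drug: DrugResources
    predictor_db: TdsDatabase
    funseq2_db: TdsDatabase


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "subtype": str})


def load_resources(resource_dir: str | Path) -> LoadedResources:
    """Load the annotation resource bundle from its directory layout."""
    d = Path(resource_dir)
    missing = [n for n in (
        "predictor_db.tsv", "funseq2_db.tsv", "gene_models.tsv", "suppressors.txt",
        "oncogenes.txt", "census.txt", "kegg.txt", "prior_scores.tsv",
        "cnv_regions.tsv", "interactions.tsv", "activity.tsv", "fda_drugs.tsv",
        "trials.tsv", "neighbors.tsv",
    ) if not (d / n).exists()]
    if missing:
        raise ConfigurationError(f"missing resources in {d}: {', '.join(missing)}")

    gm = _read_tsv(d / "gene_models.tsv")
    gene_models: dict[str, list[tuple[str, int, int]]] = {}
    for row in gm.itertuples(index=False):
        gene_models.setdefault(row.gene, []).append(
            (str(row.chrom), int(row.start), int(row.end))
        )

    def read_set(name: str) -> set[str]:
        return {line.strip() for line in open(d / name) if line.strip()}

    priors: dict[str, dict[str, float]] = {}
    for row in _read_tsv(d / "prior_scores.tsv").itertuples(index=False):
        priors.setdefault(str(row.subtype), {})[row.gene] = float(row.score)

    regions = [
        CnvSignalRegion(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                        signal=float(r.signal), kind=SvKind(r.kind), gene=r.gene)
        for r in _read_tsv(d / "cnv_regions.tsv").itertuples(index=False)
    ]

    interactions = [
        InteractionRecord(drug=r.drug, gene=r.gene, interaction_term=r.term,
                          source=r.source)
        for r in _read_tsv(d / "interactions.tsv").itertuples(index=False)
    ]
    links = [
        NeighborLink(source=r.source, neighbor=r.neighbor,
                     relatedness=float(r.relatedness))
        for r in _read_tsv(d / "neighbors.tsv").itertuples(index=False)
    ]
    from .drug_layer import normalize_activity

    raw_activity: dict[str, list[float]] = {}
    for r in _read_tsv(d / "activity.tsv").itertuples(index=False):
        raw_activity.setdefault(r.drug, []).append(float(r.assay_score))
    fda = {
        r.drug: {"brand": r.brand, "subtypes": str(r.subtypes).split(";")}
        for r in _read_tsv(d / "fda_drugs.tsv").itertuples(index=False)
    }
    trials = {
        r.drug: {"name": r.name, "organization": r.organization,
                 "phase": str(r.phase), "url": r.url}
        for r in _read_tsv(d / "trials.tsv").itertuples(index=False)
    }

    gene = GeneAnnotationResources(
        gene_models=gene_models,
        census_set=read_set("census.txt"),
        kegg_set=read_set("kegg.txt"),
        prior_scores=priors,
    )
    drug = DrugResources(
        interactions=interactions,
        neighbor_links=links,
        activity=normalize_activity(raw_activity),
        fda=fda,
        trials=trials,
        suppressor_set=read_set("suppressors.txt"),
        oncogene_set=read_set("oncogenes.txt"),
    )
    return LoadedResources(
        gene=gene, regions=regions, drug=drug,
        predictor_db=TdsDatabase(d / "predictor_db.tsv"),
        funseq2_db=TdsDatabase(d / "funseq2_db.tsv"),
    )


def score_variants(
    profile: PatientProfile,
    res: LoadedResources,
    variant_model: EnsembleSvmModel,
) -> list[VariantScore]:
    """Layer 1: one score per variant, with coding/non-coding routing."""
    scores: list[VariantScore] = []
    for v in profile.variants:
        if v.is_point:
            vector = annotate_coding(v, res.predictor_db)
            if vector is not None:
                v = v.reclassified(Category.CODING_POINT)
                scores.append(VariantScore(
                    variant=v, score_category=ScoreCategory.RADIAL_SVM,
                    value=score_coding(vector, variant_model),
                ))
            else:
                v = v.reclassified(Category.NONCODING_POINT)
                scores.append(score_noncoding(v, res.funseq2_db))
        elif v.category is Category.INDEL:
            scores.append(score_indel(v, res.regions, res.drug.suppressor_set,
                                      res.drug.oncogene_set))
        else:
            effect = ("loss_of_function" if v.sv_kind is SvKind.DELETION
                      else "gain_of_function")
            scores.append(score_structural(v, effect, res.regions,
                                           res.drug.suppressor_set,
                                           res.drug.oncogene_set))
    return scores


def _build_tables(
    scores: list[VariantScore],
    res: LoadedResources,
    gene_model: LogisticDriverModel,
    subtype: str | None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    # gene assignment + mutation table
    by_gene: dict[str, list[VariantScore]] = {}
    mut_rows = []
    for s in scores:
        assignment = assign_closest_gene(s.variant, res.gene.gene_models)
        gene = assignment[0] if assignment else None
        s.variant.gene = gene
        if gene is not None:
            by_gene.setdefault(gene, []).append(s)
        mut_rows.append({
            "Gene name": gene,
            "Chromosome number": s.variant.chrom,
            "Coordinate": s.variant.pos,
            "Reference allele": s.variant.ref,
            "Alternative allele": s.variant.alt,
            "Mutation category": _CATEGORY_LABEL[s.variant.category],
            "Mutation context": None,
            "Protein context": None,
            "Score category": _SCORE_LABEL[s.score_category],
            "Driver mutation score": round(s.value, 3),
        })

    from .gene_layer import aggregate_gene

    evidences = []
    for gene, gene_scores in by_gene.items():
        ev = aggregate_gene(gene_scores)
        ev.phenolyzer = res.gene.prior(gene, subtype)
        ev.gene_category = categorize_gene(gene, res.gene.census_set, res.gene.kegg_set)
        evidences.append(ev)
    ranked = rank_genes(evidences, gene_model)
    gene_rows = [{
        "Gene name": ev.gene,
        "Gene category": category_label(ev.gene_category),
        "Maximum radial SVM score": round(ev.max_radial_svm, 3),
        "Maximum FunSeq2 Score": round(ev.max_funseq2, 3),
        "Maximum normalized CNV Signal score": round(ev.max_cnv_signal, 3),
        "Phenolyzer score": round(ev.phenolyzer, 3),
        "iCAGES gene score": round(score, 3),
    } for ev, score, _ in ranked]

    driver_scores = {ev.gene: score for ev, score, is_driver in ranked if is_driver}
    candidates = find_drug_candidates(driver_scores, res.drug,
                                      patient_subtype=subtype)
    drug_rows = [{
        "Drug name": c.drug,
        "Final target gene": c.final_target,
        "Direct target gene": c.direct_target,
        "iCAGES gene score": round(c.gene_score, 3),
        "BioSystems normalized Relatedness probability": round(c.relatedness, 3),
        "PubChem normalized drug active probability": round(c.activity, 3),
        "iCAGES drug score": round(c.drug_score, 3),
        "Tier": c.tier,
        "Brand name": c.brand_name,
        "FDA approved subtype": "; ".join(c.approved_subtypes) or None,
        "Clinical trial name": c.trial.get("name") if c.trial else None,
        "Clinical trial organization": c.trial.get("organization") if c.trial else None,
        "Clinical trial phase": c.trial.get("phase") if c.trial else None,
        "Clinical trial URL": c.trial.get("url") if c.trial else None,
    } for c in rank_drugs(candidates)]

    return pd.DataFrame(mut_rows), pd.DataFrame(gene_rows), pd.DataFrame(drug_rows)


def run_patient(config: RunConfig):
    """Execute all three layers for one patient and write the outputs.

    Returns (mutation_table, gene_table, drug_table, written_paths).
    """
    config.validate()
    t0 = time.monotonic()
    res = load_resources(config.resource_dir)
    variant_model = EnsembleSvmModel.from_json(config.variant_model)
    gene_model = LogisticDriverModel.from_json(config.gene_model)
    gene_model.cutoff = config.cutoff

    if config.input_format == "vcf":
        profile = read_vcf(config.input_path, sample=config.sample,
                           germline_tags=config.germline_tags)
    else:
        profile = read_annovar_input(config.input_path)
    profile.cancer_subtype = config.subtype
    profile.genome_build = config.genome_build
    if config.bed_sv is not None:
        profile.variants.extend(read_bed_structural(config.bed_sv))
    logger.info("loaded %d variants in %.2fs", len(profile.variants),
                time.monotonic() - t0)

    scores = score_variants(profile, res, variant_model)
    if all(s.value == 0.0 for s in scores):
        logger.warning("no variant obtained a non-zero score")
    mut, gene, drug = _build_tables(scores, res, gene_model, config.subtype)
    paths = write_outputs(mut, gene, drug, config.out_prefix)
    logger.info("run complete in %.2fs (%d mutations, %d genes, %d drugs)",
                time.monotonic() - t0, len(mut), len(gene), len(drug))
    return mut, gene, drug, paths
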