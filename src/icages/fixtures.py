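"""Synthetic miniature resources: annotation databases, gene/drug tables,
labeled training sets, and toy patients.

Everything is generated from a seeded RNG and written as plain text in the
exact formats the production readers consume, so the whole pipeline can be
built and tested end-to-end with no external download. Predictor scores are
driven by a shared latent deleteriousness factor plus independent noise,
which induces the mutually positive cross-predictor correlation seen in
real pathogenicity scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .drug_layer import DrugResources, InteractionRecord, NeighborLink
from .formats_io import SvKind
from .gene_layer import GeneAnnotationResources
from .variant_layer import CnvSignalRegion, FEATURE_ORDER

_BASES = "ACGT"

#: Native-scale (offset, spread) of the five wide predictors, in
#: FEATURE_ORDER positions 6..10.
_WIDE_SCALES = ((2.0, 2.0), (0.0, 1.5), (15.0, 8.0), (0.5, 0.18), (10.0, 4.0))


@dataclass
class FixtureSpec:
    """Knobs of the synthetic data generator (fixed seed => identical bytes)."""

    seed: int = 0
    n_genes: int = 200
    n_variants_per_patient: int = 129
    n_training_tp: int = 1000
    n_training_tn: int = 1000
    class_separation: float = 2.5
    planted_lr_weights: tuple[float, float, float, float] = (2.0, 1.0, 1.0, 3.0)
    planted_lr_bias: float = -2.0

    def __post_init__(self):
        if min(self.n_genes, self.n_variants_per_patient,
               self.n_training_tp, self.n_training_tn) < 1:
            raise ValueError("fixture sizes must be >= 1")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def draw_predictors(rng: np.random.Generator, z: np.ndarray) -> np.ndarray:
    """Raw 11-predictor matrix given per-row latent deleteriousness z."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    out = np.empty((n, len(FEATURE_ORDER)))
    for j in range(6):
        out[:, j] = _sigmoid(z + 0.6 * rng.standard_normal(n))
    for j, (off, spread) in enumerate(_WIDE_SCALES):
        out[:, 6 + j] = off + spread * (z + 0.6 * rng.standard_normal(n))
    # keep VEST-like column (index 9) on a 0-1 native scale
    out[:, 9] = np.clip(out[:, 9], 0.0, 1.0)
    return out


def draw_class_predictors(
    rng: np.random.Generator, n: int, positive: bool, separation: float
) -> np.ndarray:
    mu = separation / 2.0 if positive else -separation / 2.0
    return draw_predictors(rng, mu + rng.standard_normal(n))


# ---------------------------------------------------------------------------
# gene resources


@dataclass
class GeneResourcesFixture:
    resources: GeneAnnotationResources
    regions: list[CnvSignalRegion]
    suppressor_set: set[str]
    oncogene_set: set[str]
    genes: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def gene_name(i: int) -> str:
    return f"GN{i:03d}"


def make_gene_resources(spec: FixtureSpec, outdir: str | Path) -> GeneResourcesFixture:
    """Non-overlapping gene spans over 5 chromosomes, role/category sets,
    phenotype priors, and CNV signal regions nested in role-matched spans."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    genes = [gene_name(i) for i in range(spec.n_genes)]
    spans: dict[str, list[tuple[str, int, int]]] = {}
    for i, g in enumerate(genes):
        chrom = str(i % 5 + 1)
        start = (i // 5) * 10_000 + 1_001
        spans[g] = [(chrom, start, start + 1_999)]

    suppressors = {g for i, g in enumerate(genes) if i % 4 == 1}
    oncogenes = {g for i, g in enumerate(genes) if i % 4 == 2}
    census = {g for i, g in enumerate(genes) if i % 7 == 3}
    kegg = {g for i, g in enumerate(genes) if i % 5 == 0}

    priors = {"default": {g: round(float(rng.uniform(0.0, 0.4)), 6) for g in genes}}

    regions: list[CnvSignalRegion] = []
    for g in sorted(suppressors | oncogenes):
        chrom, start, end = spans[g][0]
        kind = SvKind.DELETION if g in suppressors else SvKind.DUPLICATION
        regions.append(CnvSignalRegion(
            chrom=chrom, start=start + 100, end=end - 100,
            signal=round(float(rng.uniform(0.05, 1.0)), 6), kind=kind, gene=g,
        ))

    paths = {
        "gene_models": outdir / "gene_models.tsv",
        "suppressors": outdir / "suppressors.txt",
        "oncogenes": outdir / "oncogenes.txt",
        "census": outdir / "census.txt",
        "kegg": outdir / "kegg.txt",
        "prior_scores": outdir / "prior_scores.tsv",
        "cnv_regions": outdir / "cnv_regions.tsv",
    }
    with open(paths["gene_models"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for g in genes:
            for chrom, s, e in spans[g]:
                fh.write(f"{g}\t{chrom}\t{s}\t{e}\n")
    for key, gset in (("suppressors", suppressors), ("oncogenes", oncogenes),
                      ("census", census), ("kegg", kegg)):
        with open(paths[key], "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(gset))
    with open(paths["prior_scores"], "w") as fh:
        fh.write("subtype\tgene\tscore\n")
        for subtype, table in priors.items():
            for g in genes:
                fh.write(f"{subtype}\t{g}\t{table[g]:.6f}\n")
    with open(paths["cnv_regions"], "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tkind\tsignal\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{r.kind.value}\t{r.signal:.6f}\n")

    resources = GeneAnnotationResources(
        gene_models=spans, census_set=census, kegg_set=kegg, prior_scores=priors,
    )
    return GeneResourcesFixture(
        resources=resources, regions=regions, suppressor_set=suppressors,
        oncogene_set=oncogenes, genes=genes, paths=paths,
    )


# ---------------------------------------------------------------------------
# predictor / non-coding databases and training tables


@dataclass
class PredictorDbFixture:
    db_path: Path
    training_path: Path
    X: np.ndarray
    y: np.ndarray


def _format_row(chrom, pos, ref, alt, values, mmaf) -> str:
    cells = "\t".join(f"{v:.6f}" for v in values)
    return f"{chrom}\t{pos}\t{ref}\t{alt}\t{cells}\t{mmaf:.6f}\n"


def make_predictor_db(
    spec: FixtureSpec,
    outdir: str | Path,
    extra_sites: list[tuple[str, int, str, str, float]] | None = None,
) -> PredictorDbFixture:
    """Sorted 11-predictor site table (+ MMAF) and the matching labeled
    training table.

    ``extra_sites`` entries are (chrom, pos, ref, alt, latent_z) rows to
    plant at fixed coordinates (e.g. a patient's coding mutations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 2)

    n_tp, n_tn = spec.n_training_tp, spec.n_training_tn
    X = np.vstack([
        draw_class_predictors(rng, n_tp, True, spec.class_separation),
        draw_class_predictors(rng, n_tn, False, spec.class_separation),
    ])
    y = np.concatenate([np.ones(n_tp, dtype=int), np.zeros(n_tn, dtype=int)])

    rows: list[tuple[str, int, str, str, np.ndarray, float]] = []
    # background db sites reuse the training draws at random coordinates
    n_bg = min(len(X), 400)
    bg_idx = rng.choice(len(X), size=n_bg, replace=False)
    for i in bg_idx:
        chrom = str(rng.integers(1, 6))
        pos = int(rng.integers(1, 500_000))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        mmaf = float(rng.uniform(0, 0.01)) if y[i] else float(rng.uniform(0.2, 0.5))
        rows.append((chrom, pos, str(ref), str(alt), X[i], mmaf))
    for chrom, pos, ref, alt, z in extra_sites or ():
        values = draw_predictors(rng, np.array([z]))[0]
        mmaf = float(rng.uniform(0, 0.01))
        rows.append((chrom, int(pos), ref, alt, values, mmaf))
    rows.sort(key=lambda r: (r[0], r[1]))

    db_path = outdir / "predictor_db.tsv"
    with open(db_path, "w") as fh:
        for chrom, pos, ref, alt, values, mmaf in rows:
            fh.write(_format_row(chrom, pos, ref, alt, values, mmaf))

    training_path = outdir / "training_variants.tsv"
    with open(training_path, "w") as fh:
        fh.write("label\t" + "\t".join(FEATURE_ORDER) + "\n")
        for label, values in zip(y, X):
            cells = "\t".join(f"{v:.6f}" for v in values)
            fh.write(f"{label}\t{cells}\n")
    return PredictorDbFixture(db_path=db_path, training_path=training_path, X=X, y=y)


def make_funseq2_db(
    spec: FixtureSpec,
    outdir: str | Path,
    extra_sites: list[tuple[str, int, float]] | None = None,
    n_background: int = 300,
) -> Path:
    """Sorted non-coding score table: chrom, pos, score."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 3)
    rows = [
        (str(rng.integers(1, 6)), int(rng.integers(1, 500_000)),
         float(rng.uniform(0, 1)))
        for _ in range(n_background)
    ]
    rows.extend((c, int(p), float(s)) for c, p, s in extra_sites or ())
    rows.sort(key=lambda r: (r[0], r[1]))
    path = outdir / "funseq2_db.tsv"
    with open(path, "w") as fh:
        for chrom, pos, score in rows:
            fh.write(f"{chrom}\t{pos}\t{score:.6f}\n")
    return path


def make_labeled_gene_set(
    spec: FixtureSpec, n: int = 5000
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-layer training set: x ~ U(0,1)^4, y ~ Bernoulli(h(x)) under the
    planted weights."""
    rng = np.random.default_rng(spec.seed + 4)
    w = np.asarray(spec.planted_lr_weights, dtype=float)
    X = rng.uniform(0.0, 1.0, size=(n, 4))
    p = _sigmoid(X @ w + spec.planted_lr_bias)
    y = (rng.uniform(size=n) < p).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# drug resources


@dataclass
class DrugResourcesFixture:
    resources: DrugResources
    planted_drug: str | None
    paths: dict[str, Path] = field(default_factory=dict)


def make_drug_resources(
    spec: FixtureSpec,
    outdir: str | Path,
    genes: list[str],
    suppressor_set: set[str],
    oncogene_set: set[str],
    planted_gene: str | None = None,
) -> DrugResourcesFixture:
    """Interaction, neighbor, activity, FDA, and trial tables.

    When ``planted_gene`` is given, one tier-1 drug is planted that directly
    inhibits it with the strictly highest assay activity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 5)

    drugs = [f"DRUG{i:02d}" for i in range(30)]
    terms = ["inhibitor", "activator", "antagonist", "stimulator", "binder",
             "vaccine", "inducer", "blocker", "modulator"]
    interactions: list[InteractionRecord] = []
    for d in drugs:
        for g in rng.choice(genes, size=3, replace=False):
            if g == planted_gene:
                continue
            interactions.append(InteractionRecord(
                drug=d, gene=str(g), interaction_term=str(rng.choice(terms)),
                source="curated-db",
            ))

    activity_raw: dict[str, list[float]] = {
        d: [float(v) for v in rng.uniform(0, 80, size=int(rng.integers(3, 8)))]
        for d in drugs
    }
    fda = {d: {"brand": f"BRAND-{d}", "subtypes": ["fixture carcinoma"]}
           for d in drugs[:6]}
    trials = {
        d: {"name": f"trial of {d}", "organization": "FIXTURE ORG",
            "phase": "2", "url": f"https://example.org/{d.lower()}"}
        for d in drugs[4:12]
    }

    planted_drug = None
    if planted_gene is not None:
        planted_drug = "DRUGTOP"
        interactions.append(InteractionRecord(
            drug=planted_drug, gene=planted_gene,
            interaction_term="inhibitor", source="curated-db",
        ))
        activity_raw[planted_drug] = [100.0, 100.0, 100.0]  # strict max
        fda[planted_drug] = {"brand": "BRAND-TOP", "subtypes": ["fixture carcinoma"]}
        trials[planted_drug] = {"name": "planted trial", "organization": "FIXTURE ORG",
                                "phase": "2", "url": "https://example.org/top"}

    links = []
    for g in genes:
        others = [x for x in genes if x != g]
        for nb in rng.choice(others, size=4, replace=False):
            links.append(NeighborLink(source=g, neighbor=str(nb),
                                      relatedness=round(float(rng.uniform(0, 0.9)), 6)))

    paths = {
        "interactions": outdir / "interactions.tsv",
        "activity": outdir / "activity.tsv",
        "fda_drugs": outdir / "fda_drugs.tsv",
        "trials": outdir / "trials.tsv",
        "neighbors": outdir / "neighbors.tsv",
    }
    with open(paths["interactions"], "w") as fh:
        fh.write("drug\tgene\tterm\tsource\n")
        for r in interactions:
            fh.write(f"{r.drug}\t{r.gene}\t{r.interaction_term}\t{r.source}\n")
    with open(paths["activity"], "w") as fh:
        fh.write("drug\tassay_score\n")
        for d in sorted(activity_raw):
            for v in activity_raw[d]:
                fh.write(f"{d}\t{v:.6f}\n")
    with open(paths["fda_drugs"], "w") as fh:
        fh.write("drug\tbrand\tsubtypes\n")
        for d in sorted(fda):
            fh.write(f"{d}\t{fda[d]['brand']}\t{';'.join(fda[d]['subtypes'])}\n")
    with open(paths["trials"], "w") as fh:
        fh.write("drug\tname\torganization\tphase\turl\n")
        for d in sorted(trials):
            t = trials[d]
            fh.write(f"{d}\t{t['name']}\t{t['organization']}\t{t['phase']}\t{t['url']}\n")
    with open(paths["neighbors"], "w") as fh:
        fh.write("source\tneighbor\trelatedness\n")
        for l in links:
            fh.write(f"{l.source}\t{l.neighbor}\t{l.relatedness:.6f}\n")

    from .drug_layer import normalize_activity

    resources = DrugResources(
        interactions=interactions,
        neighbor_links=links,
        activity=normalize_activity(activity_raw),
        fda=fda,
        trials=trials,
        suppressor_set=suppressor_set,
        oncogene_set=oncogene_set,
    )
    return DrugResourcesFixture(resources=resources, planted_drug=planted_drug,
                                paths=paths)


# ---------------------------------------------------------------------------
# patients and the full fixture tree


@dataclass
class PatientFixture:
    annovar_path: Path
    bed_path: Path | None
    resource_dir: Path
    planted_gene: str | None
    planted_drug: str | None
    n_variants: int
    gene_fixture: GeneResourcesFixture
    predictor_fixture: PredictorDbFixture
    drug_fixture: DrugResourcesFixture
    funseq2_path: Path


def make_patient(
    spec: FixtureSpec,
    scenario: str,
    outdir: str | Path,
) -> PatientFixture:
    """Write a toy patient plus every resource its analysis needs.

    scenario "araf_like" plants one gene carrying a high-scoring coding
    mutation, a high phenotype prior, and one on-target tier-1 drug, among
    ``n_variants_per_patient`` mutated genes; "generic" draws uniformly.
    """
    if scenario not in ("araf_like", "generic"):
        raise ValueError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir)
    resource_dir = outdir / "resources"
    resource_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 6)

    gf = make_gene_resources(spec, resource_dir)
    n_var = spec.n_variants_per_patient
    if n_var > len(gf.genes):
        raise ValueError("need at least as many genes as patient variants")
    target_genes = gf.genes[:n_var]

    planted_gene = None
    if scenario == "araf_like":
        # oncogene outside the census so its category reads KEGG/other and
        # the planted inhibitor passes the role-term filter
        planted_gene = next(g for g in target_genes
                            if g in gf.oncogene_set and g not in gf.suppressor_set)
        gf.resources.prior_scores["default"][planted_gene] = 0.95
        with open(gf.paths["prior_scores"], "a") as fh:
            fh.write(f"default\t{planted_gene}\t0.950000\n")

    # variant placement: one variant per gene, inside the gene span
    coding_sites: list[tuple[str, int, str, str, float]] = []
    noncoding_sites: list[tuple[str, int, float]] = []
    annovar_lines: list[str] = []
    bed_lines: list[str] = []
    for i, g in enumerate(target_genes):
        chrom, start, end = gf.resources.gene_models[g][0]
        pos = int(rng.integers(start + 10, end - 10))
        ref, alt = (str(b) for b in rng.choice(list(_BASES), size=2, replace=False))
        if g == planted_gene:
            coding_sites.append((chrom, pos, ref, alt, spec.class_separation / 2 + 3.0))
            annovar_lines.append(f"{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\n")
        elif scenario == "araf_like" and i % 11 == 7:
            score = float(rng.uniform(0, 0.5))
            noncoding_sites.append((chrom, pos, score))
            annovar_lines.append(f"{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\n")
        elif scenario == "araf_like" and i % 17 == 5:
            annovar_lines.append(f"{chrom}\t{pos}\t{pos}\t{ref}\t-\n")  # indel
        elif scenario == "araf_like" and i % 29 == 11:
            kind = "deletion" if g in gf.suppressor_set else "duplication"
            bed_lines.append(f"{chrom}\t{pos - 1}\t{min(pos + 500, end)}\t{kind}\n")
        else:
            z = float(rng.normal(-spec.class_separation / 2, 1.0))
            coding_sites.append((chrom, pos, ref, alt, z))
            annovar_lines.append(f"{chrom}\t{pos}\t{pos}\t{ref}\t{alt}\n")

    pf = make_predictor_db(spec, resource_dir, extra_sites=coding_sites)
    funseq2_path = make_funseq2_db(spec, resource_dir, extra_sites=noncoding_sites)
    df = make_drug_resources(spec, resource_dir, gf.genes, gf.suppressor_set,
                             gf.oncogene_set, planted_gene=planted_gene)

    annovar_path = outdir / "patient.annovar"
    with open(annovar_path, "w") as fh:
        fh.writelines(annovar_lines)
    bed_path = None
    if bed_lines:
        bed_path = outdir / "patient.sv.bed"
        with open(bed_path, "w") as fh:
            fh.writelines(bed_lines)

    return PatientFixture(
        annovar_path=annovar_path, bed_path=bed_path, resource_dir=resource_dir,
        planted_gene=planted_gene, planted_drug=df.planted_drug,
        n_variants=len(annovar_lines) + len(bed_lines),
        gene_fixture=gf, predictor_fixture=pf, drug_fixture=df,
        funseq2_path=funseq2_path,
    )


def train_fixture_models(
    spec: FixtureSpec,
    patient: PatientFixture,
    outdir: str | Path,
    replicates: int = 200,
) -> tuple[Path, Path]:
    """Fit the fixture-trained variant and gene models and persist them.

    These are fixture-trained weights for testing and demonstration, not
    published fits.
    """
    from .gene_layer import LogisticDriverModel
    from .training import train_ensemble, train_logistic
    from .variant_layer import SvmHyperparams

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, _ = train_ensemble(
        patient.predictor_fixture.X, patient.predictor_fixture.y,
        grid=(SvmHyperparams(c=10.0, gamma=0.001),),
        folds=5, seed=spec.seed, replicates=replicates,
    )
    variant_path = outdir / "variant_model.json"
    model.to_json(variant_path)

    Xg, yg = make_labeled_gene_set(spec, n=4000)
    w, b = train_logistic(Xg, yg)
    gene_path = outdir / "gene_model.json"
    LogisticDriverModel(w=w, b=b).to_json(gene_path)
    return variant_path, gene_path
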