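# icages

Three-layer interpretation of a single patient's somatic mutation profile:

1. **Variant layer** — every mutation gets a driver-potential score in [0,1]:
   coding point mutations through a calibrated radial-kernel SVM over 11
   normalized pathogenicity predictors (SIFT, PolyPhen-2 HumDiv, LRT,
   MutationTaster, MutationAssessor, FATHMM, GERP++, PhyloP, CADD, VEST,
   SiPhy); non-coding point mutations through a precomputed score lookup;
   structural variants and indels through normalized recurrent focal CNV
   signal regions gated by gene role (deletion x tumor suppressor,
   duplication x oncogene; indels take the more deleterious of both
   readings).
2. **Gene layer** — variant scores are assigned to their closest gene,
   reduced to per-category maxima, joined with a phenotype-prior score, and
   pushed through a 4-feature logistic model `h(x) = 1/(1+e^-(w.x+b))`.
   Genes with `h(x) >= 0.11` are called candidate drivers.
3. **Drug layer** — candidate drivers plus their top-4 pathway neighbors
   are queried against a drug-gene interaction table with role-specific
   interaction-term sets; each drug scores as
   `gene score x relatedness x activity` and is tiered (1 = FDA approved,
   2 = in active trials, 3 = otherwise).

Annotation databases (tab-delimited, key + integer coordinate, sorted) are
queried through **TDS**, a two-step dictionary-search binary index: a key
directory locates the per-key bin table, a binary search locates the bin,
and at most one bin of lines is read sequentially.

All inputs can be emulated at miniature scale by the `icages.fixtures`
module, which generates seeded synthetic resources (predictor databases,
gene/drug tables, labeled training sets, toy patients) in the exact text
formats the production readers consume.

## CLI

Generate a fixture tree (resources + patient + fixture-trained models),
then analyze the patient:

```sh
icages fixtures --out tree --seed 1 --scenario araf_like
icages run \
    --input tree/patient.annovar \
    --bed-sv tree/patient.sv.bed \
    --resources tree/resources \
    --variant-model tree/models/variant_model.json \
    --gene-model tree/models/gene_model.json \
    --out-prefix results/P
```

This writes `results/P.mutations.csv`, `results/P.genes.csv`,
`results/P.drugs.csv`, and `results/P.json` (the same tables as JSON).
Input may be ANNOVAR 5-column (`--format annovar`, the default) or VCF
(`--format vcf`, with `--sample` required for multi-sample files);
structural variants come from a BED file via `--bed-sv`.

Training and evaluation:

```sh
icages train-variant --table tree/resources/training_variants.tsv --out vm.json
icages train-gene    --table genes.tsv --out gm.json
icages evaluate      --scores scored.tsv --bootstrap 2000 --seed 1
```

The index is also exposed stand-alone:

```sh
tds build db.tsv --bin-size 10
tds query db.tsv chr1:100-200
```

The shipped models are fixture-trained (on seeded synthetic data); supply
your own model JSON files for real analyses.

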