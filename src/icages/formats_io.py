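"""Input parsing (ANNOVAR 5-column, VCF, BED structural) and output writing.

Internal coordinates are 1-based inclusive (ANNOVAR convention). BED input
(0-based half-open) is converted on ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    InvalidIntervalError,
    ParseError,
    SampleLookupError,
)

logger = logging.getLogger(__name__)


class Category(str, Enum):
    CODING_POINT = "coding_point"
    NONCODING_POINT = "noncoding_point"
    INDEL = "indel"
    STRUCTURAL = "structural"


class SvKind(str, Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    NONE = "none"


#: Table column names of the mutation prioritization CSV.
MUTATION_COLUMNS = [
    "Gene name",
    "Chromosome number",
    "Coordinate",
    "Reference allele",
    "Alternative allele",
    "Mutation category",
    "Mutation context",
    "Protein context",
    "Score category",
    "Driver mutation score",
]

#: Table column names of the gene prioritization CSV.
GENE_COLUMNS = [
    "Gene name",
    "Gene category",
    "Maximum radial SVM score",
    "Maximum FunSeq2 Score",
    "Maximum normalized CNV Signal score",
    "Phenolyzer score",
    "iCAGES gene score",
]

#: Table column names of the drug prioritization CSV.
DRUG_COLUMNS = [
    "Drug name",
    "Final target gene",
    "Direct target gene",
    "iCAGES gene score",
    "BioSystems normalized Relatedness probability",
    "PubChem normalized drug active probability",
    "iCAGES drug score",
    "Tier",
    "Brand name",
    "FDA approved subtype",
    "Clinical trial name",
    "Clinical trial organization",
    "Clinical trial phase",
    "Clinical trial URL",
]


@dataclass
class VariantRecord:
    """One somatic mutation.

    ``pos``/``end`` are 1-based inclusive; ``end == pos`` for SNVs.
    ``category == STRUCTURAL`` iff ``sv_kind != NONE``.
    """

    chrom: str
    pos: int
    end: int
    ref: str
    alt: str
    category: Category
    sv_kind: SvKind = SvKind.NONE
    gene: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidIntervalError(f"pos must be >= 1, got {self.pos}")
        if self.end < self.pos:
            raise InvalidIntervalError(
                f"end ({self.end}) < pos ({self.pos}) on {self.chrom}"
            )
        structural = self.category is Category.STRUCTURAL
        if structural != (self.sv_kind is not SvKind.NONE):
            raise ValueError("category=structural iff sv_kind != none")
        if self.category in (Category.CODING_POINT, Category.NONCODING_POINT):
            if self.ref == self.alt:
                raise ValueError("ref == alt for a point mutation")

    @property
    def is_point(self) -> bool:
        return self.category in (Category.CODING_POINT, Category.NONCODING_POINT)

    def reclassified(self, category: Category) -> "VariantRecord":
        return replace(self, category=category)


@dataclass
class PatientProfile:
    """All somatic mutations of a single patient."""

    sample_id: str
    variants: list[VariantRecord] = field(default_factory=list)
    cancer_subtype: str | None = None
    genome_build: str = "hg19"


def _infer_point_or_indel(ref: str, alt: str) -> Category:
    if ref == "-" or alt == "-" or len(ref) != len(alt) or len(ref) != 1:
        return Category.INDEL
    return Category.CODING_POINT  # provisional; router may reclassify


def read_annovar_input(path: str | Path, sample_id: str | None = None) -> PatientProfile:
    """Read a 5-column whitespace-delimited input file.

    Columns: chrom, start, end, ref, alt. Single-base substitutions become
    point mutations (coding vs non-coding is resolved later by annotation);
    length-changing alleles or ``-`` become indels.
    """
    path = Path(path)
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"expected >=5 fields, got {len(fields)}", line_number=lineno
                )
            chrom, start_s, end_s, ref, alt = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line_number=lineno)
            category = _infer_point_or_indel(ref, alt)
            try:
                variants.append(
                    VariantRecord(chrom=chrom, pos=start, end=end, ref=ref,
                                  alt=alt, category=category)
                )
            except (ValueError, InvalidIntervalError) as exc:
                raise ParseError(str(exc), line_number=lineno)
    if not variants:
        raise EmptyInputError(f"no variants in {path}")
    return PatientProfile(sample_id=sample_id or path.stem, variants=variants)


def read_vcf(
    path: str | Path,
    sample: str | None = None,
    germline_tags: frozenset[str] = frozenset({"GERMLINE"}),
) -> PatientProfile:
    """Read somatic variants of one sample from a VCF.

    Multi-allelic sites are split into one record per alternate allele
    carried by the selected sample. Records whose FILTER or INFO carries a
    recognized germline tag are excluded. Symbolic ``<DEL>``/``<DUP>``
    alleles become structural records; other symbolic alleles are skipped
    with a warning.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    sample_idx: int | None = None
    if len(samples) > 1:
        if sample is None:
            raise ConfigurationError(
                f"VCF has {len(samples)} samples; a sample must be specified"
            )
        if sample not in samples:
            raise SampleLookupError(f"sample {sample!r} not in VCF ({samples})")
        sample_idx = samples.index(sample)
    elif len(samples) == 1:
        if sample is not None and sample != samples[0]:
            raise SampleLookupError(f"sample {sample!r} not in VCF ({samples})")
        sample_idx = 0

    saw_germline_tag = False
    variants: list[VariantRecord] = []
    for rec in vcf:
        tags = set()
        if rec.FILTER:
            tags.update(rec.FILTER.split(";"))
        for tag in germline_tags:
            if rec.INFO.get(tag) is not None:
                tags.add(tag)
        if tags & germline_tags:
            saw_germline_tag = True
            continue

        if sample_idx is not None:
            gt = rec.genotypes[sample_idx][:-1]  # drop phasing flag
            carried = {a for a in gt if a is not None and a > 0}
        else:
            carried = set(range(1, len(rec.ALT) + 1))  # sites-only VCF
        if not carried:
            continue

        for ai in sorted(carried):
            alt = rec.ALT[ai - 1]
            pos = rec.POS
            ref = rec.REF
            if alt.startswith("<"):
                end = rec.INFO.get("END") or rec.end
                if alt == "<DEL>":
                    kind = SvKind.DELETION
                elif alt == "<DUP>":
                    kind = SvKind.DUPLICATION
                else:
                    logger.warning("skipping unsupported symbolic allele %s at %s:%d",
                                   alt, rec.CHROM, pos)
                    continue
                variants.append(
                    VariantRecord(chrom=rec.CHROM, pos=pos, end=int(end), ref=ref,
                                  alt=alt, category=Category.STRUCTURAL, sv_kind=kind)
                )
            elif len(ref) == 1 and len(alt) == 1:
                variants.append(
                    VariantRecord(chrom=rec.CHROM, pos=pos, end=pos, ref=ref,
                                  alt=alt, category=Category.CODING_POINT)
                )
            else:
                end = pos + len(ref) - 1
                variants.append(
                    VariantRecord(chrom=rec.CHROM, pos=pos, end=end, ref=ref,
                                  alt=alt, category=Category.INDEL)
                )
    vcf.close()
    if not saw_germline_tag:
        logger.warning(
            "no germline tag (%s) seen in %s; treating all records as somatic",
            ",".join(sorted(germline_tags)), path,
        )
    if not variants:
        raise EmptyInputError(f"no usable variants in {path}")
    sid = sample if sample is not None else (samples[0] if samples else Path(path).stem)
    return PatientProfile(sample_id=sid, variants=variants)


_SV_KINDS = {"deletion": SvKind.DELETION, "duplication": SvKind.DUPLICATION}


def read_bed_structural(path: str | Path, kind_field: int = 3) -> list[VariantRecord]:
    """Read structural variants from BED (0-based half-open).

    ``kind_field`` is the 0-based column index carrying the
    deletion/duplication label.
    """
    variants: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) <= kind_field:
                raise ParseError(
                    f"expected >{kind_field} fields, got {len(fields)}",
                    line_number=lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line_number=lineno)
            if start >= end:
                raise InvalidIntervalError(
                    f"line {lineno}: BED start ({start}) >= end ({end})"
                )
            label = fields[kind_field].lower()
            if label not in _SV_KINDS:
                raise ParseError(f"unknown SV kind {label!r}", line_number=lineno)
            variants.append(
                VariantRecord(chrom=chrom, pos=start + 1, end=end, ref="N",
                              alt=f"<{'DEL' if label == 'deletion' else 'DUP'}>",
                              category=Category.STRUCTURAL, sv_kind=_SV_KINDS[label])
            )
    return variants


def to_bed_interval(variant: VariantRecord) -> tuple[str, int, int]:
    """Inverse of the BED ingest conversion (1-based inclusive -> 0-based half-open)."""
    return variant.chrom, variant.pos - 1, variant.end


def _clean(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.reindex(columns=columns).astype(object)
    return out.where(out.notna(), ".")


def write_outputs(
    mutation_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    drug_table: pd.DataFrame,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write the three per-layer CSV files and the combined JSON mirror.

    Missing values serialize as ".". Returns the written paths keyed by
    ``mutations``/``genes``/``drugs``/``json``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tables = {
        "mutations": _clean(mutation_table, MUTATION_COLUMNS),
        "genes": _clean(gene_table, GENE_COLUMNS),
        "drugs": _clean(drug_table, DRUG_COLUMNS),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_prefix.with_name(out_prefix.name + f".{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    jp = out_prefix.with_name(out_prefix.name + ".json")
    payload = {name: df.to_dict(orient="records") for name, df in tables.items()}
    with open(jp, "w") as fh:
        json.dump(payload, fh, indent=1)
    paths["json"] = jp
    return paths


def read_json_outputs(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse the JSON mirror back into the three tables (round-trip check)."""
    with open(path) as fh:
        payload = json.load(fh)
    return {
        "mutations": pd.DataFrame(payload["mutations"], columns=MUTATION_COLUMNS),
        "genes": pd.DataFrame(payload["genes"], columns=GENE_COLUMNS),
        "drugs": pd.DataFrame(payload["drugs"], columns=DRUG_COLUMNS),
    }
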