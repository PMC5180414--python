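"""Layer 2: per-gene evidence aggregation and the logistic driver call.

Variant scores are mapped to genes (closest gene by genomic distance),
reduced to per-category maxima, joined with the phenotype prior, and pushed
through the 4-feature sigmoid h(x) = 1/(1+e^-(w.x+b)). Scores at or above
the cutoff (default 0.11) call the gene a driver.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, NotFittedError
from .formats_io import VariantRecord
from .variant_layer import ScoreCategory, VariantScore

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.11

GENE_FEATURES = ("max_radial_svm", "max_funseq2", "max_cnv_signal", "phenolyzer")

_CATEGORY_LABELS = {
    "cancer_gene_census": "Cancer Gene Census",
    "kegg_cancer_pathway": "KEGG cancer pathway",
    "other": "other",
}


@dataclass
class GeneEvidence:
    """Per-gene feature 4-vector feeding the logistic model."""

    gene: str
    max_radial_svm: float = 0.0
    max_funseq2: float = 0.0
    max_cnv_signal: float = 0.0
    phenolyzer: float = 0.0
    gene_category: str = "other"

    def __post_init__(self):
        for name in GENE_FEATURES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0,1] for gene {self.gene}")

    def feature_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GENE_FEATURES], dtype=float)


@dataclass
class LogisticDriverModel:
    """Weights, bias, and decision cutoff of the gene-score sigmoid."""

    w: np.ndarray | None = None
    b: float = 0.0
    cutoff: float = DEFAULT_CUTOFF
    version: int = 1

    def __post_init__(self):
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
        if not 0.0 < self.cutoff < 1.0:
            raise DataError(f"cutoff {self.cutoff} outside (0,1)")

    @property
    def is_fitted(self) -> bool:
        return self.w is not None

    def predict(self, x: np.ndarray) -> float:
        if not self.is_fitted:
            raise NotFittedError("logistic driver model is not fitted")
        z = float(self.w @ np.asarray(x, dtype=float) + self.b)
        if z >= 0:
            return 1.0 / (1.0 + math.exp(-z))
        ez = math.exp(z)
        return ez / (1.0 + ez)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "w": self.w.tolist(),
                       "b": self.b, "cutoff": self.cutoff}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticDriverModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(w=np.array(p["w"], dtype=float), b=float(p["b"]),
                   cutoff=float(p["cutoff"]), version=int(p["version"]))


@dataclass
class GeneAnnotationResources:
    """Gene spans, category sets, and the phenotype-prior score table.

    ``gene_models`` maps gene symbol -> list of (chrom, start, end) spans
    (1-based inclusive). ``prior_scores`` maps subtype -> gene -> score; the
    "default" subtype backs unknown subtypes.
    """

    gene_models: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    census_set: set[str] = field(default_factory=set)
    kegg_set: set[str] = field(default_factory=set)
    prior_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def prior(self, gene: str, subtype: str | None = None) -> float:
        table = self.prior_scores.get(subtype or "default")
        if table is None:
            if subtype is not None:
                logger.warning("unknown subtype %r; falling back to default priors", subtype)
            table = self.prior_scores.get("default", {})
        return float(table.get(gene, 0.0))


def assign_closest_gene(
    variant: VariantRecord,
    gene_models: dict[str, list[tuple[str, int, int]]],
) -> tuple[str, int] | None:
    """Closest gene by genomic distance (0 when inside a span).

    Distance ties break lexicographically by symbol. Returns None when the
    variant's chromosome carries no gene (the variant is then dropped from
    the gene layer with a warning).
    """
    best: tuple[int, str] | None = None
    for gene, spans in gene_models.items():
        for chrom, start, end in spans:
            if chrom != variant.chrom:
                continue
            if start <= variant.end and variant.pos <= end:
                dist = 0
            elif variant.end < start:
                dist = start - variant.end
            else:
                dist = variant.pos - end
            cand = (dist, gene)
            if best is None or cand < best:
                best = cand
    if best is None:
        logger.warning("no gene on chromosome %s; variant at %s:%d unassigned",
                       variant.chrom, variant.chrom, variant.pos)
        return None
    return best[1], best[0]


def aggregate_gene(scores: list[VariantScore]) -> GeneEvidence:
    """Per-category score maxima over all of one gene's variants.

    Categories with no variant contribute 0. All scores must belong to the
    same (assigned) gene.
    """
    if not scores:
        raise DataError("aggregate_gene requires at least one variant score")
    genes = {s.variant.gene for s in scores}
    if len(genes) != 1:
        raise DataError(f"scores span multiple genes: {sorted(map(str, genes))}")
    maxima = {cat: 0.0 for cat in ScoreCategory}
    for s in scores:
        maxima[s.score_category] = max(maxima[s.score_category], s.value)
    return GeneEvidence(
        gene=genes.pop() or "",
        max_radial_svm=maxima[ScoreCategory.RADIAL_SVM],
        max_funseq2=maxima[ScoreCategory.FUNSEQ2],
        max_cnv_signal=maxima[ScoreCategory.CNV_SIGNAL],
    )


def icages_gene_score(evidence: GeneEvidence, model: LogisticDriverModel) -> float:
    """h(x) for x = (max radial SVM, max FunSeq2, max CNV signal, prior)."""
    return model.predict(evidence.feature_vector())


def call_driver(score: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Binary driver call; the cutoff boundary is inclusive."""
    if not 0.0 <= score <= 1.0:
        raise DataError(f"gene score {score} outside [0,1]")
    return score >= cutoff


def categorize_gene(gene: str, census_set: set[str], kegg_set: set[str]) -> str:
    """Census membership takes precedence over KEGG; otherwise "other"."""
    if gene in census_set:
        return "cancer_gene_census"
    if gene in kegg_set:
        return "kegg_cancer_pathway"
    return "other"


def category_label(category: str) -> str:
    return _CATEGORY_LABELS[category]


def rank_genes(
    evidences: list[GeneEvidence],
    model: LogisticDriverModel,
) -> list[tuple[GeneEvidence, float, bool]]:
    """Score and order genes: descending gene score, then descending max
    radial SVM, then symbol. Returns (evidence, score, driver_call) rows."""
    rows = [(e, icages_gene_score(e, model)) for e in evidences]
    rows.sort(key=lambda r: (-r[1], -r[0].max_radial_svm, r[0].gene))
    return [(e, s, call_driver(s, model.cutoff)) for e, s in rows]
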