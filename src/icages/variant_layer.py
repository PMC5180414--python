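"""Layer 1: per-variant driver-potential scores.

Coding point mutations get a calibrated radial-kernel ensemble probability
over 11 pathogenicity predictors; non-coding points a database score
lookup; structural variants and indels a normalized focal CNV recurrence
signal gated by gene role (deletion x tumor suppressor, duplication x
oncogene).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, NotFittedError
from .formats_io import Category, SvKind, VariantRecord
from .tds import TdsDatabase

logger = logging.getLogger(__name__)

#: Fixed predictor order of the 11-dimensional feature space.
FEATURE_ORDER = (
    "sift",
    "polyphen2_humdiv",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
    "gerp_pp",
    "phylop",
    "cadd",
    "vest",
    "siphy",
)

#: Predictors already on a 0-1 deleteriousness scale at ingest.
UNIT_SCALE_FEATURES = FEATURE_ORDER[:6]
#: Predictors on native scales, min-max scaled from training ranges.
WIDE_SCALE_FEATURES = FEATURE_ORDER[6:]

N_FEATURES = len(FEATURE_ORDER)


class ScoreCategory(str, Enum):
    RADIAL_SVM = "radial_svm"
    FUNSEQ2 = "funseq2"
    CNV_SIGNAL = "cnv_signal"


_CATEGORY_TO_SCORE = {
    Category.CODING_POINT: ScoreCategory.RADIAL_SVM,
    Category.NONCODING_POINT: ScoreCategory.FUNSEQ2,
    Category.INDEL: ScoreCategory.CNV_SIGNAL,
    Category.STRUCTURAL: ScoreCategory.CNV_SIGNAL,
}


@dataclass
class CodingFeatureVector:
    """Raw-scale 11-predictor vector for one coding point mutation.

    ``values`` follows :data:`FEATURE_ORDER`; entries named in
    ``missing_mask`` were absent from the database (NaN until imputed).
    """

    values: np.ndarray
    missing_mask: frozenset[str] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} predictor values")

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[FEATURE_ORDER.index(name)])
        except ValueError:
            raise AttributeError(name)


@dataclass(frozen=True)
class SvmHyperparams:
    c: float = 10.0
    gamma: float = 0.001

    def __post_init__(self):
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")


@dataclass
class VariantScore:
    variant: VariantRecord
    score_category: ScoreCategory
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise DataError(f"variant score {self.value} outside [0,1]")
        expected = _CATEGORY_TO_SCORE[self.variant.category]
        if self.score_category is not expected:
            raise DataError(
                f"{self.variant.category.value} variant cannot carry a "
                f"{self.score_category.value} score"
            )


@dataclass
class CnvSignalRegion:
    """Recurrent focal CNV region with its normalized density signal.

    Coordinates are 1-based inclusive. ``gene`` is the gene whose span the
    region annotates; role gating checks it against the suppressor/oncogene
    sets.
    """

    chrom: str
    start: int
    end: int
    signal: float
    kind: SvKind
    gene: str

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(f"region start {self.start} > end {self.end}")
        if not 0.0 <= self.signal <= 1.0:
            raise DataError(f"region signal {self.signal} outside [0,1]")
        if self.kind not in (SvKind.DELETION, SvKind.DUPLICATION):
            raise DataError("region kind must be deletion or duplication")


def radial_kernel(u, v, gamma: float) -> float:
    """Gaussian kernel exp(-gamma * ||u - v||^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    d = u - v
    return float(np.exp(-gamma * float(d @ d)))


@dataclass
class EnsembleSvmModel:
    """Radial-kernel classifier in dual form with Platt calibration.

    Support vectors are stored on the scaled feature space. ``wide_min`` /
    ``wide_max`` are the training ranges used to min-max scale the wide
    predictors (clamped at inference); ``training_medians`` (raw scale)
    impute missing predictors.
    """

    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0
    hyperparams: SvmHyperparams = field(default_factory=SvmHyperparams)
    prob_a: float = 0.0
    prob_b: float = 0.0
    feature_order: tuple[str, ...] = FEATURE_ORDER
    training_medians: np.ndarray | None = None
    wide_min: np.ndarray | None = None
    wide_max: np.ndarray | None = None
    version: int = 1

    @property
    def is_fitted(self) -> bool:
        return self.support_vectors is not None

    # -- feature preparation ----------------------------------------------

    def impute(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float)
        miss = np.isnan(out)
        if miss.any():
            if self.training_medians is None:
                raise NotFittedError("no training medians for imputation")
            out[miss] = self.training_medians[miss]
        return out

    def scale(self, raw: np.ndarray) -> np.ndarray:
        """Raw predictor vector(s) -> [0,1]^11 model space."""
        x = np.atleast_2d(np.asarray(raw, dtype=float)).copy()
        n_unit = len(UNIT_SCALE_FEATURES)
        x[:, :n_unit] = np.clip(x[:, :n_unit], 0.0, 1.0)
        rng = np.where(self.wide_max > self.wide_min, self.wide_max - self.wide_min, 1.0)
        x[:, n_unit:] = np.clip((x[:, n_unit:] - self.wide_min) / rng, 0.0, 1.0)
        return x if np.asarray(raw).ndim == 2 else x[0]

    # -- scoring -----------------------------------------------------------

    def decision_function(self, x_scaled: np.ndarray) -> float:
        k = np.exp(
            -self.hyperparams.gamma
            * np.sum((self.support_vectors - x_scaled) ** 2, axis=1)
        )
        return float(self.dual_coef @ k + self.intercept)

    def predict_proba(self, vector: "CodingFeatureVector | np.ndarray") -> float:
        if not self.is_fitted:
            raise NotFittedError("ensemble model is not fitted")
        raw = vector.values if isinstance(vector, CodingFeatureVector) else np.asarray(vector, float)
        x = self.scale(self.impute(raw))
        d = self.decision_function(x)
        f = self.prob_a * d + self.prob_b
        # Platt sigmoid P(driver | d) = 1 / (1 + exp(A d + B)), overflow-safe
        p = math.exp(-f) / (1.0 + math.exp(-f)) if f >= 0 else 1.0 / (1.0 + math.exp(f))
        return min(max(p, 0.0), 1.0)

    # -- persistence (text JSON so models survive text-only pipelines) -----

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "hyperparams": {"c": self.hyperparams.c, "gamma": self.hyperparams.gamma},
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "prob_a": self.prob_a,
            "prob_b": self.prob_b,
            "feature_order": list(self.feature_order),
            "training_medians": self.training_medians.tolist(),
            "wide_min": self.wide_min.tolist(),
            "wide_max": self.wide_max.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleSvmModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            support_vectors=np.array(p["support_vectors"], dtype=float),
            dual_coef=np.array(p["dual_coef"], dtype=float),
            intercept=float(p["intercept"]),
            hyperparams=SvmHyperparams(**p["hyperparams"]),
            prob_a=float(p["prob_a"]),
            prob_b=float(p["prob_b"]),
            feature_order=tuple(p["feature_order"]),
            training_medians=np.array(p["training_medians"], dtype=float),
            wide_min=np.array(p["wide_min"], dtype=float),
            wide_max=np.array(p["wide_max"], dtype=float),
            version=int(p["version"]),
        )


# ---------------------------------------------------------------------------
# annotation / scoring operations


def annotate_coding(
    variant: VariantRecord,
    predictor_db: TdsDatabase,
) -> CodingFeatureVector | None:
    """Look up the 11 predictor scores for a point mutation.

    Database rows: chrom, pos, ref, alt, 11 predictor columns ("." =
    missing), MMAF. Returns None when there is no exact-allele row at the
    site (the caller then routes the variant to the non-coding scorer); a
    position hit with an allele mismatch is a no-hit with a warning.
    """
    if not variant.is_point:
        raise ValueError("annotate_coding requires a point mutation")
    lines = predictor_db.query(variant.chrom, variant.pos)
    hit = None
    for line in lines:
        f = line.split("\t")
        if f[2] == variant.ref and f[3] == variant.alt:
            hit = f
            break
    if hit is None:
        if lines:
            logger.warning(
                "allele mismatch at %s:%d (%s>%s); treated as no-hit",
                variant.chrom, variant.pos, variant.ref, variant.alt,
            )
        return None
    values = np.full(N_FEATURES, np.nan)
    missing = set()
    for i, name in enumerate(FEATURE_ORDER):
        cell = hit[4 + i]
        if cell == "." or cell == "":
            missing.add(name)
        else:
            values[i] = float(cell)
    return CodingFeatureVector(values=values, missing_mask=frozenset(missing))


def score_coding(vector: CodingFeatureVector, model: EnsembleSvmModel) -> float:
    """Calibrated driver probability of a coding point mutation."""
    return model.predict_proba(vector)


def score_noncoding(variant: VariantRecord, funseq2_db: TdsDatabase) -> VariantScore:
    """Non-coding driver score lookup (rows: chrom, pos, score); 0 when absent."""
    if variant.category is not Category.NONCODING_POINT:
        raise ValueError("score_noncoding requires a noncoding_point variant")
    lines = funseq2_db.query(variant.chrom, variant.pos)
    value = 0.0
    if lines:
        value = max(float(line.split("\t")[2]) for line in lines)
        value = min(max(value, 0.0), 1.0)
    return VariantScore(variant=variant, score_category=ScoreCategory.FUNSEQ2, value=value)


def score_structural(
    variant: VariantRecord,
    effect: str,
    regions: list[CnvSignalRegion],
    suppressors: set[str],
    oncogenes: set[str],
) -> VariantScore:
    """CNV recurrence signal of a structural variant or indel.

    ``effect`` is "loss_of_function" or "gain_of_function". A LoF variant
    overlapping a deletion-signal region of a tumor-suppressor gene takes
    that region's signal (max over overlaps); GoF pairs with duplication
    regions of oncogenes. Anything else scores 0.
    """
    if effect not in ("loss_of_function", "gain_of_function"):
        raise ValueError(f"unknown effect {effect!r}")
    if variant.category not in (Category.STRUCTURAL, Category.INDEL):
        raise ValueError("score_structural requires a structural variant or indel")
    if effect == "loss_of_function":
        want_kind, gene_set = SvKind.DELETION, suppressors
    else:
        want_kind, gene_set = SvKind.DUPLICATION, oncogenes
    best = 0.0
    for region in regions:
        if region.kind is not want_kind or region.gene not in gene_set:
            continue
        if region.chrom != variant.chrom:
            continue
        if region.start <= variant.end and variant.pos <= region.end:
            best = max(best, region.signal)
    return VariantScore(variant=variant, score_category=ScoreCategory.CNV_SIGNAL, value=best)


def score_indel(
    variant: VariantRecord,
    regions: list[CnvSignalRegion],
    suppressors: set[str],
    oncogenes: set[str],
) -> VariantScore:
    """Indels are tried under both effect directions; the more deleterious
    annotation wins."""
    lof = score_structural(variant, "loss_of_function", regions, suppressors, oncogenes)
    gof = score_structural(variant, "gain_of_function", regions, suppressors, oncogenes)
    return VariantScore(
        variant=variant,
        score_category=ScoreCategory.CNV_SIGNAL,
        value=max(lof.value, gof.value),
    )


def mmaf_filter(
    mutations: pd.DataFrame,
    role: str,
    other: pd.DataFrame | None = None,
    site_cols: tuple[str, ...] = ("chrom", "pos", "ref", "alt"),
) -> pd.DataFrame:
    """Population-frequency filter for training/testing set composition.

    role="tp" keeps MMAF <= 0.01; role="tn" keeps MMAF >= 0.20. When
    ``other`` (the TN candidates) is given for role="tp", sites present in
    both are removed from the TP side.
    """
    if role not in ("tp", "tn"):
        raise ValueError(f"role must be 'tp' or 'tn', got {role!r}")
    mmaf = mutations["mmaf"].astype(float)
    if ((mmaf < 0) | (mmaf > 1)).any():
        raise DataError("MMAF outside [0,1]")
    if role == "tp":
        kept = mutations[mmaf <= 0.01]
        if other is not None:
            other_sites = set(map(tuple, other[list(site_cols)].itertuples(index=False)))
            mask = [
                tuple(row) not in other_sites
                for row in kept[list(site_cols)].itertuples(index=False)
            ]
            kept = kept[mask]
        return kept
    return mutations[mmaf >= 0.20]
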