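"""Layer 3: targeted drug search, joint scoring, and regulatory tiers.

Candidate driver genes are classified by cancer role, expanded to their top
pathway neighbors, and matched against a drug-gene interaction table with
role-specific interaction-term sets. Each (drug, direct target, final
target) path scores as the product of the final target's gene score, the
direct-target relatedness probability, and the drug's normalized activity
probability; the best path per drug survives ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

#: Interaction terms with positive influence, queried for tumor suppressors.
SUPPRESSOR_TERMS = frozenset({
    "activator",
    "inducer",
    "positive allosteric modulator",
    "potentiator",
    "stimulator",
})

#: Interaction terms with negative influence, queried for oncogenes.
ONCOGENE_TERMS = frozenset({
    "agonist",
    "antisense",
    "competitive",
    "immunotherapy",
    "inhibitory allosteric modulator",
    "inverse agonist",
    "negative modulator",
    "partial agonist",
    "partial antagonist",
    "vaccine",
    "inhibitor",
    "suppressor",
    "antibody",
    "antagonist",
    "blocker",
})

#: Activity assigned to drugs with no assay data (flagged in the output).
DEFAULT_ACTIVITY = 0.5


@dataclass(frozen=True)
class GeneClass:
    gene: str
    role: str  # tumor_suppressor | oncogene | other


@dataclass(frozen=True)
class NeighborLink:
    source: str
    neighbor: str
    relatedness: float

    def __post_init__(self):
        if not 0.0 <= self.relatedness <= 1.0:
            raise DataError(f"relatedness {self.relatedness} outside [0,1]")


@dataclass(frozen=True)
class InteractionRecord:
    drug: str
    gene: str
    interaction_term: str
    source: str = "curated-db"  # curated-db | fda-list

    def __post_init__(self):
        if not self.interaction_term:
            raise DataError("interaction_term must be non-empty")


@dataclass
class DrugCandidate:
    drug: str
    direct_target: str
    final_target: str
    gene_score: float
    relatedness: float
    activity: float
    tier: int = 3
    brand_name: str | None = None
    approved_subtypes: tuple[str, ...] = ()
    trial: dict | None = None
    no_activity_data: bool = False
    repurposing: str | None = None

    @property
    def drug_score(self) -> float:
        return self.gene_score * self.relatedness * self.activity


def classify_gene_role(
    gene: str, suppressor_set: set[str], oncogene_set: set[str]
) -> GeneClass:
    """Role by list membership; both lists -> "other" with a warning."""
    in_sup, in_onc = gene in suppressor_set, gene in oncogene_set
    if in_sup and in_onc:
        logger.warning("gene %s listed as both suppressor and oncogene; "
                       "classified as other", gene)
        return GeneClass(gene, "other")
    if in_sup:
        return GeneClass(gene, "tumor_suppressor")
    if in_onc:
        return GeneClass(gene, "oncogene")
    return GeneClass(gene, "other")


def top_neighbors(
    gene: str, links: list[NeighborLink], k: int = 4
) -> list[NeighborLink]:
    """The gene itself (relatedness 1.0) plus its k most-related neighbors.

    Ties at rank k break lexicographically on the neighbor symbol; when
    fewer than k neighbors exist, all are returned.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    neighbors = [l for l in links if l.source == gene and l.neighbor != gene]
    neighbors.sort(key=lambda l: (-l.relatedness, l.neighbor))
    return [NeighborLink(gene, gene, 1.0)] + neighbors[:k]


def query_drugs(
    gene: GeneClass, interactions: list[InteractionRecord]
) -> list[InteractionRecord]:
    """Role-filtered interaction records for one gene.

    Suppressors accept only the 5-term activating set, oncogenes only the
    15-term inhibiting set, other genes any term; FDA-list records always
    pass.
    """
    out = []
    for rec in interactions:
        if rec.gene != gene.gene:
            continue
        if rec.source == "fda-list":
            out.append(rec)
        elif gene.role == "tumor_suppressor":
            if rec.interaction_term.lower() in SUPPRESSOR_TERMS:
                out.append(rec)
        elif gene.role == "oncogene":
            if rec.interaction_term.lower() in ONCOGENE_TERMS:
                out.append(rec)
        else:
            out.append(rec)
    return out


def normalize_activity(
    raw_scores: dict[str, list[float]],
    iqr_factor: float = 1.5,
) -> dict[str, float]:
    """Per-drug mean assay score, min-max normalized across drugs to [0,1].

    Within each drug, scores beyond ``iqr_factor`` x IQR of its own assay
    distribution are dropped before averaging. A degenerate range (all
    means equal, or a single drug) maps to 1.0.
    """
    if not raw_scores or all(len(v) == 0 for v in raw_scores.values()):
        raise DataError("normalize_activity needs at least one assay score")
    means = {}
    for drug, scores in raw_scores.items():
        if not scores:
            continue
        arr = np.asarray(scores, dtype=float)
        if len(arr) >= 4:
            q1, q3 = np.percentile(arr, [25, 75])
            iqr = q3 - q1
            keep = arr[(arr >= q1 - iqr_factor * iqr) & (arr <= q3 + iqr_factor * iqr)]
            if len(keep):
                arr = keep
        means[drug] = float(arr.mean())
    lo, hi = min(means.values()), max(means.values())
    if hi == lo:
        return {d: 1.0 for d in means}
    return {d: (m - lo) / (hi - lo) for d, m in means.items()}


def score_drug(gene_score: float, relatedness: float, activity: float) -> float:
    """Joint probability: the product of the three factor probabilities."""
    for name, v in (("gene_score", gene_score), ("relatedness", relatedness),
                    ("activity", activity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    return gene_score * relatedness * activity


@dataclass
class DrugResources:
    """Interaction, activity, and regulatory-status tables."""

    interactions: list[InteractionRecord] = field(default_factory=list)
    neighbor_links: list[NeighborLink] = field(default_factory=list)
    activity: dict[str, float] = field(default_factory=dict)
    fda: dict[str, dict] = field(default_factory=dict)  # drug -> {brand, subtypes}
    trials: dict[str, dict] = field(default_factory=dict)  # drug -> trial metadata
    suppressor_set: set[str] = field(default_factory=set)
    oncogene_set: set[str] = field(default_factory=set)


def assign_tier(
    drug: str,
    fda: dict[str, dict],
    trials: dict[str, dict],
    patient_subtype: str | None = None,
) -> tuple[int, dict]:
    """Tier 1 = FDA approved, tier 2 = in active trials only, tier 3 else.

    Tier-1/2 drugs carry brand/subtype/trial metadata; when the patient
    subtype is known and differs from every approved subtype, a tumor-type
    repurposing flag is attached (metadata only, no score change).
    """
    meta: dict = {}
    if drug in fda:
        tier = 1
        meta["brand_name"] = fda[drug].get("brand")
        meta["approved_subtypes"] = tuple(fda[drug].get("subtypes", ()))
        if drug in trials:
            meta["trial"] = trials[drug]
    elif drug in trials:
        tier = 2
        meta["trial"] = trials[drug]
    else:
        tier = 3
    if tier in (1, 2) and patient_subtype is not None:
        approved = {s.lower() for s in meta.get("approved_subtypes", ())}
        if patient_subtype.lower() not in approved:
            meta["repurposing"] = "tumor type repurposing"
    return tier, meta


def rank_drugs(candidates: list[DrugCandidate]) -> list[DrugCandidate]:
    """Order by descending drug score, then lower tier, then name.

    A drug reachable via several (direct target, final target) paths keeps
    only its highest-scoring path.
    """
    best: dict[str, DrugCandidate] = {}
    for c in candidates:
        cur = best.get(c.drug)
        if cur is None or (c.drug_score, -c.tier) > (cur.drug_score, -cur.tier):
            best[c.drug] = c
    out = list(best.values())
    out.sort(key=lambda c: (-c.drug_score, c.tier, c.drug))
    return out


def find_drug_candidates(
    gene_scores: dict[str, float],
    resources: DrugResources,
    k_neighbors: int = 4,
    patient_subtype: str | None = None,
) -> list[DrugCandidate]:
    """Full layer-3 expansion for a set of candidate driver genes.

    For each final-target gene, the gene itself plus its top neighbors are
    queried as direct targets under the direct target's role-term filter;
    every matching interaction becomes one candidate path.
    """
    candidates: list[DrugCandidate] = []
    for final_gene, gscore in gene_scores.items():
        for link in top_neighbors(final_gene, resources.neighbor_links, k=k_neighbors):
            direct = link.neighbor
            role = classify_gene_role(direct, resources.suppressor_set,
                                      resources.oncogene_set)
            for rec in query_drugs(role, resources.interactions):
                activity = resources.activity.get(rec.drug)
                no_data = activity is None
                if no_data:
                    activity = DEFAULT_ACTIVITY
                tier, meta = assign_tier(rec.drug, resources.fda, resources.trials,
                                         patient_subtype)
                candidates.append(DrugCandidate(
                    drug=rec.drug,
                    direct_target=direct,
                    final_target=final_gene,
                    gene_score=gscore,
                    relatedness=link.relatedness,
                    activity=activity,
                    tier=tier,
                    brand_name=meta.get("brand_name"),
                    approved_subtypes=meta.get("approved_subtypes", ()),
                    trial=meta.get("trial"),
                    no_activity_data=no_data,
                    repurposing=meta.get("repurposing"),
                ))
    return candidates
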