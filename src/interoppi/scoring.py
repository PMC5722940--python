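"""Confidence scoring and tier assignment for predicted interactions.

Each predicted pair receives a confidence value

    CV = CV_interolog * CV_DDI

where CV_interolog = sum_i S_i M_i / N averages over the N supporting
template species: S_i is the ortholog-existence factor (always 1 here,
since only pairs with identified orthologs enter the network) and M_i is
the reliability of the evidence in species i -- 1 for an experimental
measurement, 0.5 for a computational prediction.  When one species supplies
both kinds of witness the experimental one dominates (M_i = 1).  CV_DDI is
the domain-side factor d * D from :mod:`interoppi.ddi`.

Edges without any domain-interaction support form the Basal (B) confidence
class.  DDI-supported edges form the High (H) class and are split by the
percentile rank of their CV within the H population: H1 (> 80), H2 (50-80),
H3 (< 50).  Percentile rank is 100 * (H edges with strictly smaller CV) /
(H edges), so tied CVs always share a tier.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ddi import DdiAssessment, assess_pair
from .interolog import PredictedInteraction, Witness

__all__ = [
    "ScoreBreakdown",
    "TierAssignment",
    "compute_cv_interolog",
    "compute_cv",
    "score_predictions",
    "percentile_ranks",
    "assign_tiers",
]

M_EXPERIMENTAL = 1.0
M_COMPUTATIONAL = 0.5
S_EXISTENCE = 1.0  # orthologs are identified before a pair enters the network

TIER_HIGH_CUT = 80.0
TIER_LOW_CUT = 50.0


@dataclass(frozen=True)
class ScoreBreakdown:
    """All score components of one predicted interaction."""

    n_species: int
    m_by_species: tuple[tuple[str, float], ...]
    cv_interolog: float
    ddi: DdiAssessment
    cv: float


@dataclass(frozen=True)
class TierAssignment:
    """Confidence class of one edge; percentile rank is defined for H edges only."""

    tier: str
    percentile_rank: float | None


def _species_m(provenance: Iterable[Witness]) -> dict[str, float]:
    m: dict[str, float] = {}
    for w in provenance:
        weight = M_EXPERIMENTAL if w.evidence_method == "experimental" else M_COMPUTATIONAL
        m[w.species] = max(m.get(w.species, 0.0), weight)
    return m


def compute_cv_interolog(provenance: Iterable[Witness]) -> float:
    """Mean of S_i * M_i over the supporting species (S_i = 1)."""
    m = _species_m(provenance)
    if not m:
        raise ValueError("empty provenance: a prediction needs >= 1 witness")
    return sum(S_EXISTENCE * m[s] for s in sorted(m)) / len(m)


def compute_cv(cv_interolog: float, cv_ddi: float) -> float:
    """Final confidence value: product of the interolog and DDI factors."""
    return cv_interolog * cv_ddi


def score_predictions(
    predictions: Iterable[PredictedInteraction],
    domain_annotations: Mapping[str, Iterable[str]],
    ddi_rules: set[tuple[str, str]],
) -> list[PredictedInteraction]:
    """Fill the ScoreBreakdown of every prediction in place; returns the list."""
    preds = list(predictions)
    for pred in preds:
        m = _species_m(pred.provenance)
        cv_int = sum(S_EXISTENCE * m[s] for s in sorted(m)) / len(m)
        ddi = assess_pair(pred.pair, domain_annotations, ddi_rules)
        pred.score = ScoreBreakdown(
            n_species=len(m),
            m_by_species=tuple(sorted(m.items())),
            cv_interolog=cv_int,
            ddi=ddi,
            cv=compute_cv(cv_int, ddi.cv_ddi),
        )
    return preds


def percentile_ranks(values: Sequence[float]) -> list[float]:
    """Strict-less percentile rank of each value within the whole sequence."""
    ordered = sorted(values)
    n = len(values)
    return [100.0 * bisect_left(ordered, v) / n for v in values]


def _tier_for_rank(rank: float) -> str:
    if rank > TIER_HIGH_CUT:
        return "H1"
    if rank >= TIER_LOW_CUT:
        return "H2"
    return "H3"


def assign_tiers(predictions: Iterable[PredictedInteraction]) -> list[PredictedInteraction]:
    """Assign B/H1/H2/H3 confidence tiers in place; returns the list.

    Requires scored predictions.  Edges with ddi_count = 0 are Basal; the
    remaining (H) edges are ranked by CV within the H population.
    """
    preds = list(predictions)
    high = [p for p in preds if p.score is not None and p.score.ddi.ddi_count > 0]
    for p in preds:
        if p.score is None:
            raise ValueError(f"prediction {p.pair} is unscored; run score_predictions first")
        if p.score.ddi.ddi_count == 0:
            p.tier, p.percentile_rank = "B", None
    if high:
        ranks = percentile_ranks([p.score.cv for p in high])
        for p, rank in zip(high, ranks):
            p.tier, p.percentile_rank = _tier_for_rank(rank), rank
    return preds


def tier_assignment(pred: PredictedInteraction) -> TierAssignment:
    if pred.tier is None:
        raise ValueError("prediction has no tier; run assign_tiers first")
    return TierAssignment(pred.tier, pred.percentile_rank)
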