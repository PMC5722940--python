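"""Interolog transfer: map template-species interactions onto the target species.

For every template interaction (A, B) observed in species s, and every
target-species ortholog a of A and b of B, the unordered pair {a, b} is
predicted to interact.  Pairs witnessed from several templates merge into a
single prediction whose provenance accumulates every (species, evidence,
source, template pair) witness; the supporting-species count N is the number
of distinct species in the provenance.  Homodimer predictions (shared
ortholog) are retained.  Template interactions with an unmapped endpoint are
skipped and counted in the transfer report.

The module also provides the light network queries used for biological
interpretation: first-neighbor subnetworks and degree-based hub ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io_formats import TemplateInteraction, canonical_pair
from .orthology import OrthologMap

__all__ = [
    "Witness",
    "PredictedInteraction",
    "TransferReport",
    "transfer_interactions",
    "build_graph",
    "first_neighbors",
    "rank_hubs",
]


@dataclass(frozen=True, order=True)
class Witness:
    """One template-interaction observation supporting a predicted pair."""

    species: str
    evidence_method: str
    source_db: str
    template_pair: tuple[str, str]


@dataclass
class PredictedInteraction:
    """An unordered target-species protein pair with full provenance.

    Score, tier and validation flags are filled by the downstream scoring
    and validation stages.
    """

    pair: tuple[str, str]
    provenance: frozenset[Witness]
    score: object | None = None  # ScoreBreakdown, filled by confidence_scoring
    tier: str | None = None
    percentile_rank: float | None = None
    expression_supported: bool = False
    coexpressed: bool = False

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)
        if not self.provenance:
            raise ValueError("a prediction requires at least one witness")

    @property
    def n_species(self) -> int:
        """Number of distinct template species supporting this pair (N >= 1)."""
        return len({w.species for w in self.provenance})

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({w.species for w in self.provenance}))


@dataclass
class TransferReport:
    """Bookkeeping of one transfer run."""

    n_templates: int = 0
    n_transferred_templates: int = 0
    n_skipped: int = 0
    n_predictions: int = 0
    per_species_counts: dict[str, int] = field(default_factory=dict)


def transfer_interactions(
    template_interactions: Iterable[TemplateInteraction],
    ortholog_map: OrthologMap,
) -> tuple[list[PredictedInteraction], TransferReport]:
    """Transfer template interactions through the ortholog map.

    Every ortholog combination is transferred (full cross-product), matching
    a many-to-many orthology in which one template pair can expand into
    several target pairs and several template pairs can collapse onto one.
    Returns the merged predictions (sorted by canonical pair) and a report
    counting skipped templates and per-species inferred pairs.
    """
    report = TransferReport()
    witnesses: dict[tuple[str, str], set[Witness]] = {}
    for t in template_interactions:
        report.n_templates += 1
        orth_a = ortholog_map.orthologs(t.protein_a)
        orth_b = ortholog_map.orthologs(t.protein_b)
        if not orth_a or not orth_b:
            report.n_skipped += 1
            continue
        report.n_transferred_templates += 1
        w = Witness(t.species, t.evidence_method, t.source_db, t.pair)
        for a in orth_a:
            for b in orth_b:
                witnesses.setdefault(canonical_pair(a, b), set()).add(w)
    predictions = [
        PredictedInteraction(pair=pair, provenance=frozenset(ws))
        for pair, ws in sorted(witnesses.items())
    ]
    report.n_predictions = len(predictions)
    species_pairs: dict[str, set[tuple[str, str]]] = {}
    for pred in predictions:
        for w in pred.provenance:
            species_pairs.setdefault(w.species, set()).add(pred.pair)
    report.per_species_counts = {s: len(p) for s, p in sorted(species_pairs.items())}
    return predictions, report


def build_graph(predictions: Iterable[PredictedInteraction]) -> nx.Graph:
    """Undirected graph over predicted pairs; edge data holds the prediction."""
    g = nx.Graph()
    for pred in predictions:
        g.add_edge(pred.pair[0], pred.pair[1], prediction=pred)
    return g


def first_neighbors(network: nx.Graph, protein_id: str) -> nx.Graph:
    """Induced subnetwork of a protein and its direct interaction partners."""
    if protein_id not in network:
        raise KeyError(f"protein {protein_id!r} not in network")
    nodes = set(network.neighbors(protein_id)) | {protein_id}
    return network.subgraph(nodes).copy()


def _degree(network: nx.Graph, node) -> int:
    # networkx counts a self-loop twice; the package convention is once
    deg = network.degree(node)
    if network.has_edge(node, node):
        deg -= 1
    return deg


def rank_hubs(
    network: nx.Graph, top_n: int | None = None
) -> list[tuple[str, int]]:
    """Proteins ranked by degree (descending; ties lexicographic).

    Self-loops contribute 1 to degree.  The top-ranked proteins are the
    network's hubs, the putative communication centers of the interactome.
    """
    ranking = sorted(
        ((node, _degree(network, node)) for node in network.nodes),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranking if top_n is None else ranking[:top_n]
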