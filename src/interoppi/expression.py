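"""Expression-based validation of a predicted interaction network.

Two complementary checks are performed.  First, a protein is considered
*expressed* if it appears in any proteomics presence list, or if its summary
expression in any matrix dataset lies above the dataset's 80th percentile
(only highly expressed genes are trusted as evidence of presence); an edge
is *expression supported* when both endpoints are expressed.  Second, for
time-series datasets the expression profiles of each interacting pair are
correlated: a pair is *co-expressed* when the Pearson correlation exceeds
0.9 with a two-sided p-value below 0.1 (t transform with n - 2 degrees of
freedom) in at least one dataset -- thresholds strict, as co-expression is
a suggestion, not proof, of physical interaction.

Co-expressed pairs are finally grouped into connected components and
classified by topology into heterodimeric (two proteins), linear multimeric
(open chains) and circular multimeric (containing a cycle) groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .interolog import PredictedInteraction
from .io_formats import ExpressionDataset, canonical_pair

__all__ = [
    "UndefinedCorrelationError",
    "CoexpressionResult",
    "CoexpressionGroup",
    "high_expression_set",
    "expressed_protein_set",
    "flag_edge_expression",
    "pearson_with_p",
    "find_coexpressed_edges",
    "classify_coexpression_groups",
]

logger = logging.getLogger(__name__)

DEFAULT_EXPRESSION_PERCENTILE = 80.0
DEFAULT_PCC_MIN = 0.9
DEFAULT_P_MAX = 0.1


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a profile has zero variance)."""


@dataclass(frozen=True)
class CoexpressionResult:
    """Correlation of one interacting pair's profiles in one time-series dataset."""

    pair: tuple[str, str]
    dataset_id: str
    pcc: float
    p_value: float
    n_points: int

    @property
    def coexpressed(self) -> bool:
        return self.pcc > DEFAULT_PCC_MIN and self.p_value < DEFAULT_P_MAX


@dataclass
class CoexpressionGroup:
    """A connected component of co-expressed interacting proteins."""

    proteins: frozenset[str]
    edges: tuple[tuple[str, str], ...]
    shape: str  # heterodimeric | linear_multimeric | circular_multimeric
    branched: bool = False


def high_expression_set(
    matrix_dataset: ExpressionDataset,
    percentile: float = DEFAULT_EXPRESSION_PERCENTILE,
    summary: str = "mean",
) -> set[str]:
    """Genes whose summary expression lies strictly above the dataset percentile.

    Each gene is summarized across the dataset's samples by its mean
    (``summary="max"`` uses the maximum instead); the cut point is the
    linear-interpolated percentile of the summaries, and only genes strictly
    above it qualify, so a flat dataset yields the empty set.
    """
    if matrix_dataset.table is None or matrix_dataset.table.empty:
        raise ValueError(f"dataset {matrix_dataset.dataset_id!r} has no expression matrix")
    if summary == "mean":
        summaries = matrix_dataset.table.mean(axis=1)
    elif summary == "max":
        summaries = matrix_dataset.table.max(axis=1)
    else:
        raise ValueError(f"unknown summary {summary!r}; use 'mean' or 'max'")
    cut = float(np.percentile(summaries.to_numpy(), percentile))
    return set(summaries.index[summaries > cut])


def expressed_protein_set(
    datasets: Iterable[ExpressionDataset],
    percentile: float = DEFAULT_EXPRESSION_PERCENTILE,
    summary: str = "mean",
) -> set[str]:
    """Union of presence-list members and each matrix dataset's high expressors."""
    expressed: set[str] = set()
    for ds in datasets:
        if ds.kind == "protein_presence":
            assert ds.members is not None
            expressed |= ds.members
        else:
            expressed |= high_expression_set(ds, percentile=percentile, summary=summary)
    return expressed


def flag_edge_expression(
    predictions: Iterable[PredictedInteraction], expressed_set: set[str]
) -> float:
    """Flag edges whose BOTH endpoints are expressed; returns the supported fraction."""
    preds = list(predictions)
    n_supported = 0
    for p in preds:
        p.expression_supported = p.pair[0] in expressed_set and p.pair[1] in expressed_set
        n_supported += p.expression_supported
    return n_supported / len(preds) if preds else 0.0


def pearson_with_p(
    profile_x: Sequence[float], profile_y: Sequence[float]
) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(profile_x, dtype=float)
    y = np.asarray(profile_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 points for a correlation p-value, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance profile: correlation undefined")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:  # exactly collinear: the t statistic diverges
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def find_coexpressed_edges(
    predictions: Iterable[PredictedInteraction],
    time_series_datasets: Iterable[ExpressionDataset],
    pcc_min: float = DEFAULT_PCC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[CoexpressionResult]:
    """Correlate every edge's endpoint profiles in every time-series dataset.

    An edge is flagged co-expressed when any dataset satisfies BOTH strict
    thresholds (pcc > pcc_min and p < p_max).  Edges missing either profile
    in a dataset are skipped for that dataset; zero-variance profiles are
    logged and treated as not co-expressed there.  All per-dataset results
    are returned.
    """
    preds = list(predictions)
    datasets = [ds for ds in time_series_datasets if ds.kind == "time_series"]
    results: list[CoexpressionResult] = []
    for p in preds:
        p.coexpressed = False
    for ds in datasets:
        assert ds.table is not None
        index = ds.table.index
        for p in preds:
            a, b = p.pair
            if a not in index or b not in index:
                continue
            try:
                pcc, pval = pearson_with_p(
                    ds.table.loc[a].to_numpy(), ds.table.loc[b].to_numpy()
                )
            except UndefinedCorrelationError:
                logger.info(
                    "zero-variance profile for pair %s in dataset %s; not co-expressed",
                    p.pair,
                    ds.dataset_id,
                )
                continue
            results.append(
                CoexpressionResult(p.pair, ds.dataset_id, pcc, pval, ds.table.shape[1])
            )
            if pcc > pcc_min and pval < p_max:
                p.coexpressed = True
    return results


def classify_coexpression_groups(
    coexpressed_edges: Iterable[tuple[str, str]],
) -> list[CoexpressionGroup]:
    """Group co-expressed pairs into components and classify their topology.

    Components with exactly two proteins are heterodimeric; larger acyclic
    components with maximum degree <= 2 are linear multimeric; components
    containing a cycle are circular multimeric.  Acyclic components with a
    branch (degree >= 3) are reported as linear with a warning, since chain
    and ring are the only multimeric shapes modelled.  Self-pairs are
    dropped before grouping (a protein trivially co-expresses with itself).
    """
    g = nx.Graph()
    for a, b in coexpressed_edges:
        a, b = canonical_pair(a, b)
        if a != b:
            g.add_edge(a, b)
    groups: list[CoexpressionGroup] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        edges = tuple(sorted(canonical_pair(a, b) for a, b in sub.edges))
        has_cycle = sub.number_of_edges() >= sub.number_of_nodes()  # connected comp.
        branched = False
        if len(comp) == 2:
            shape = "heterodimeric"
        elif has_cycle:
            shape = "circular_multimeric"
        else:
            shape = "linear_multimeric"
            branched = max(dict(sub.degree).values()) > 2
            if branched:
                warnings.warn(
                    f"branched acyclic co-expression component {sorted(comp)}; "
                    "reported as linear_multimeric",
                    stacklevel=2,
                )
        groups.append(
            CoexpressionGroup(frozenset(comp), edges, shape, branched=branched)
        )
    groups.sort(key=lambda grp: min(grp.proteins))
    return groups
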