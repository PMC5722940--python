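"""Domain-based support for predicted interactions.

A predicted protein pair gains credibility when its two domain complements
contain at least one domain pair reported to physically interact.  Support
is quantified by the domain enrichment ratio

    D = (matched DDI rules) / (n_domains_a * n_domains_b),

the fraction of all possible cross-domain pairs that are known DDIs, with
D = 0 when either protein has no annotated domain.  Because a pair of
single-domain proteins forces D into {0, 1}, a correction factor d = 0.5 is
applied when BOTH proteins carry exactly one domain (d = 1 otherwise), and
the domain-side confidence is CV_DDI = d * D.

Domain complements are sets (repeat accessions collapse); a matched rule
counts once regardless of orientation, so D never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import canonical_pair

__all__ = ["DdiAssessment", "count_ddi", "compute_D", "compute_d", "assess_pair"]


@dataclass(frozen=True)
class DdiAssessment:
    """Domain-domain interaction support breakdown for one protein pair."""

    ddi_count: int
    n_dom_a: int
    n_dom_b: int
    D: float
    d: float
    cv_ddi: float


def count_ddi(
    domains_a: Iterable[str],
    domains_b: Iterable[str],
    ddi_rules: set[tuple[str, str]],
) -> int:
    """Number of distinct DDI rules matched across the two domain sets.

    A rule (x, y) with x in A and y in B (or the mirror) counts once.
    """
    set_a, set_b = set(domains_a), set(domains_b)
    matched = {
        canonical_pair(x, y)
        for x in set_a
        for y in set_b
        if canonical_pair(x, y) in ddi_rules
    }
    return len(matched)


def compute_D(ddi_count: int, n_dom_a: int, n_dom_b: int) -> float:
    """Domain enrichment: matched rules over all possible cross-domain pairs."""
    if n_dom_a == 0 or n_dom_b == 0:
        return 0.0
    return ddi_count / (n_dom_a * n_dom_b)


def compute_d(n_dom_a: int, n_dom_b: int) -> float:
    """Single-domain correction: 0.5 when both proteins have exactly one domain."""
    return 0.5 if (n_dom_a == 1 and n_dom_b == 1) else 1.0


def assess_pair(
    pair: tuple[str, str],
    domain_annotations: Mapping[str, Iterable[str]],
    ddi_rules: set[tuple[str, str]],
) -> DdiAssessment:
    """Full DDI assessment of a protein pair; absent proteins have no domains."""
    doms_a = set(domain_annotations.get(pair[0], ()))
    doms_b = set(domain_annotations.get(pair[1], ()))
    n_a, n_b = len(doms_a), len(doms_b)
    count = count_ddi(doms_a, doms_b, ddi_rules)
    D = compute_D(count, n_a, n_b)
    d = compute_d(n_a, n_b)
    return DdiAssessment(count, n_a, n_b, D, d, d * D)
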