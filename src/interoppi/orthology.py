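"""Ortholog identification from BLASTp tabular output.

A target-species protein is accepted as the ortholog of a template protein
when at least one alignment hit passes all three thresholds simultaneously:
percent identity >= 60, query coverage >= 80 and e-value <= 1e-10 (boundary
values inclusive exactly as stated).  Coverage is computed over the query
(template) protein: 100 * aligned query span / query length.  Orthology is
one-way and many-to-many: no reciprocal-best-hit requirement, and every
hit row is tested independently (multiple HSPs are not merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io_formats import AlignmentHit, ParseError, _iter_lines, _read_table, _write_table

__all__ = [
    "OrthologEdge",
    "OrthologMap",
    "compute_coverage",
    "filter_orthologs",
    "read_ortholog_map",
    "write_ortholog_map",
]

DEFAULT_MIN_IDENTITY = 60.0
DEFAULT_MIN_COVERAGE = 80.0
DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class OrthologEdge:
    """Alignment statistics of the hit that admitted a (template, target) pair."""

    identity: float | None
    coverage: float | None
    evalue: float


@dataclass
class OrthologMap:
    """Many-to-many mapping from template proteins to target-species proteins.

    Every mapped pair passed all three admission thresholds; ``stats`` keeps
    the admitting hit (smallest e-value; ties broken by highest identity).
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)
    stats: dict[tuple[str, str], OrthologEdge] = field(default_factory=dict)

    def orthologs(self, template_id: str) -> set[str]:
        return self.mapping.get(template_id, set())

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.stats)

    def __len__(self) -> int:
        return len(self.stats)


def compute_coverage(hit: AlignmentHit) -> float:
    """Query coverage percentage: aligned query span over query length."""
    return 100.0 * (hit.align_end_q - hit.align_start_q + 1) / hit.query_length


def filter_orthologs(
    hits: Iterable[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> OrthologMap:
    """Admit (template, target) pairs whose best hit passes all thresholds.

    A pair is admitted iff at least one hit satisfies identity >=
    ``min_identity``, query coverage >= ``min_coverage`` and e-value <=
    ``max_evalue``.  Among multiple admitting hits for the same pair the one
    with the smallest e-value is recorded (ties: highest identity).
    """
    omap = OrthologMap()
    for hit in hits:
        if hit.percent_identity < min_identity:
            continue
        if compute_coverage(hit) < min_coverage:
            continue
        if hit.evalue > max_evalue:
            continue
        key = (hit.query_id, hit.subject_id)
        edge = OrthologEdge(hit.percent_identity, compute_coverage(hit), hit.evalue)
        prev = omap.stats.get(key)
        if prev is None:
            omap.mapping.setdefault(hit.query_id, set()).add(hit.subject_id)
            omap.stats[key] = edge
        elif (edge.evalue, -(edge.identity or 0.0)) < (prev.evalue, -(prev.identity or 0.0)):
            omap.stats[key] = edge
    return omap


ORTHOMAP_HEADER = ("template_id", "target_id", "evalue")


def write_ortholog_map(path: str | Path, omap: OrthologMap) -> None:
    """Persist the map as a 3-column TSV (template_id, target_id, evalue)."""
    rows = [
        (q, s, repr(float(omap.stats[(q, s)].evalue)))
        for q, s in sorted(omap.stats)
    ]
    _write_table(path, ORTHOMAP_HEADER, rows)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a persisted map; identity/coverage of admitting hits are not stored."""
    omap = OrthologMap()
    for lineno, cells in _read_table(path, ORTHOMAP_HEADER):
        q, s = cells[0].strip(), cells[1].strip()
        try:
            evalue = float(cells[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad evalue {cells[2]!r}") from exc
        omap.mapping.setdefault(q, set()).add(s)
        omap.stats[(q, s)] = OrthologEdge(None, None, evalue)
    return omap
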