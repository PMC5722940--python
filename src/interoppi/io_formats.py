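"""Readers and writers for every tabular and network format the pipeline touches.

All canonical interchange files are UTF-8 TSVs with a required header row;
lines starting with ``#`` are ignored.  Interacting pairs (proteins or
domains) are undirected and stored in canonical lexicographic order
everywhere, so that writing and re-reading any table reproduces the
in-memory records exactly.

Supported formats
-----------------
* template PPI table (5 columns: species, protein_a, protein_b,
  evidence_method, source_db)
* a minimal PSI-MITAB 2.5 column subset (interactor ids + detection method)
* BLAST tabular output (outfmt 6; 12 columns, or 13 with a trailing qlen)
* protein -> domain long table, domain-domain interaction (DDI) rule table
* expression data: presence lists and expression matrices
* network export: edge/node TSV, SIF and GraphML
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "EVIDENCE_METHODS",
    "canonical_pair",
    "TemplateInteraction",
    "AlignmentHit",
    "DomainAnnotation",
    "DDIRule",
    "ExpressionDataset",
    "EdgeRow",
    "read_template_ppi_tsv",
    "write_template_ppi_tsv",
    "read_mitab_subset",
    "read_blast_tab",
    "write_blast_tab",
    "read_domain_table",
    "write_domain_table",
    "read_ddi_rules",
    "write_ddi_rules",
    "read_presence_list",
    "write_presence_list",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_tsv",
    "write_edge_rows",
    "write_network",
    "EDGE_COLUMNS",
]


class ParseError(ValueError):
    """A file violates its column or type contract."""


class ValidationError(ValueError):
    """A well-formed row carries a value outside the allowed domain."""


EVIDENCE_METHODS = ("experimental", "computational")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical lexicographic order."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class TemplateInteraction:
    """An observed interaction in a template species.

    The pair is stored unordered: ``protein_a <= protein_b`` always holds
    after construction.  ``evidence_method`` records whether the source
    database lists the interaction as an experimental measurement or a
    computational prediction; it is the basis of the method-reliability
    weight M in confidence scoring.
    """

    species: str
    protein_a: str
    protein_b: str
    evidence_method: str
    source_db: str

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValidationError("protein identifiers must be non-empty")
        if self.evidence_method not in EVIDENCE_METHODS:
            raise ValidationError(
                f"unknown evidence_method {self.evidence_method!r}; "
                f"expected one of {EVIDENCE_METHODS}"
            )
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class AlignmentHit:
    """One BLASTp hit of a template protein (query) against the target genome."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_start_q: int
    align_end_q: int
    evalue: float
    query_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if not (1 <= self.align_start_q <= self.align_end_q <= self.query_length):
            raise ValidationError(
                f"alignment span {self.align_start_q}-{self.align_end_q} invalid "
                f"for query length {self.query_length}"
            )
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class DomainAnnotation:
    """Domain complement of one protein (Pfam-style accessions, possibly empty)."""

    protein_id: str
    domains: frozenset[str]


@dataclass(frozen=True, order=True)
class DDIRule:
    """An unordered pair of domain accessions reported to interact."""

    domain_x: str
    domain_y: str

    def __post_init__(self) -> None:
        x, y = canonical_pair(self.domain_x, self.domain_y)
        object.__setattr__(self, "domain_x", x)
        object.__setattr__(self, "domain_y", y)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.domain_x, self.domain_y)


EXPRESSION_KINDS = ("protein_presence", "gene_matrix", "time_series")


@dataclass
class ExpressionDataset:
    """One expression evidence set.

    ``protein_presence`` datasets carry only a member set (proteins detected
    in a proteomics study).  ``gene_matrix`` and ``time_series`` datasets
    carry a non-negative expression matrix (rows: proteins/genes, columns:
    ordered sample labels).  Time series require at least 3 ordered samples.
    Missing cells are rejected at load time; no imputation is performed.
    """

    dataset_id: str
    kind: str
    members: frozenset[str] | None = None
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in EXPRESSION_KINDS:
            raise ValidationError(f"unknown expression dataset kind {self.kind!r}")
        if self.kind == "protein_presence":
            if self.members is None:
                raise ValidationError("protein_presence dataset requires members")
        else:
            t = self.table
            if t is None:
                raise ValidationError(f"{self.kind} dataset requires a table")
            if t.index.has_duplicates:
                dup = t.index[t.index.duplicated()][0]
                raise ValidationError(f"duplicate matrix row id {dup!r}")
            if t.isna().any().any():
                raise ValidationError(
                    f"dataset {self.dataset_id!r} has missing cells; "
                    "resolve them before loading (no imputation is applied)"
                )
            if (t.values < 0).any():
                raise ValidationError("expression values must be non-negative")
            if self.kind == "time_series" and t.shape[1] < 3:
                raise ValidationError(
                    f"time series {self.dataset_id!r} needs >= 3 ordered samples, "
                    f"got {t.shape[1]}"
                )


# ---------------------------------------------------------------------------
# low-level TSV plumbing
# ---------------------------------------------------------------------------


def _iter_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _read_table(path: str | Path, header: Sequence[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, fields) for data rows of a header-bearing TSV."""
    lines = _iter_lines(path)
    try:
        lineno, first = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected header {list(header)}")
    got = first.split("\t")
    if [c.strip() for c in got] != list(header):
        raise ParseError(
            f"{path}:{lineno}: bad header {got!r}, expected {list(header)}"
        )
    n = len(header)
    for lineno, line in lines:
        cells = line.split("\t")
        if len(cells) != n:
            raise ParseError(
                f"{path}:{lineno}: expected {n} tab-separated columns, got {len(cells)}"
            )
        yield lineno, cells


def _write_table(path: str | Path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(float(x))


# ---------------------------------------------------------------------------
# template PPI tables
# ---------------------------------------------------------------------------

TEMPLATE_PPI_HEADER = ("species", "protein_a", "protein_b", "evidence_method", "source_db")


def read_template_ppi_tsv(path: str | Path) -> list[TemplateInteraction]:
    """Read the canonical 5-column template PPI table.

    Pairs are canonicalized and exact duplicates (same species, pair,
    evidence and source) collapsed, preserving first-seen order.
    """
    records: dict[TemplateInteraction, None] = {}
    for lineno, cells in _read_table(path, TEMPLATE_PPI_HEADER):
        try:
            rec = TemplateInteraction(*[c.strip() for c in cells])
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        records.setdefault(rec, None)
    return list(records)


def write_template_ppi_tsv(path: str | Path, interactions: Iterable[TemplateInteraction]) -> None:
    rows = [
        (t.species, t.protein_a, t.protein_b, t.evidence_method, t.source_db)
        for t in interactions
    ]
    _write_table(path, TEMPLATE_PPI_HEADER, rows)


_MITAB_ID_RE = re.compile(r"^[^:]+:(.+)$")
_MI_TERM_RE = re.compile(r"MI:\d{4}")


def _mitab_accession(field_value: str) -> str:
    """Accession part of the first db:accession token of a MITAB id column."""
    first = field_value.split("|", 1)[0].strip()
    m = _MITAB_ID_RE.match(first)
    acc = (m.group(1) if m else first).strip().strip('"')
    if not acc or acc == "-":
        raise ValidationError(f"cannot extract an accession from {field_value!r}")
    return acc


def read_mitab_subset(
    path: str | Path,
    method_map: Mapping[str, str],
    species: str,
    default_method: str = "computational",
    source_db: str = "mitab",
) -> list[TemplateInteraction]:
    """Read interactor ids and detection method from PSI-MITAB 2.5 lines.

    Only columns 1 and 2 (interactor ids) and 7 (interaction detection
    method) are consumed.  ``method_map`` maps detection-method term strings
    (either the full column value or an embedded ``MI:nnnn`` identifier) to
    ``experimental`` / ``computational``; unmapped methods fall back to
    ``default_method``.  MITAB carries no species token in these columns, so
    the template species is supplied by the caller.
    """
    if default_method not in EVIDENCE_METHODS:
        raise ValidationError(f"bad default_method {default_method!r}")
    records: dict[TemplateInteraction, None] = {}
    for lineno, line in _iter_lines(path):
        cells = line.split("\t")
        if len(cells) < 7:
            raise ParseError(
                f"{path}:{lineno}: PSI-MITAB subset needs >= 7 columns, got {len(cells)}"
            )
        try:
            id_a = _mitab_accession(cells[0])
            id_b = _mitab_accession(cells[1])
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        detection = cells[6].strip()
        method = method_map.get(detection)
        if method is None:
            mi = _MI_TERM_RE.search(detection)
            if mi is not None:
                method = method_map.get(mi.group(0))
        if method is None:
            method = default_method
        rec = TemplateInteraction(species, id_a, id_b, method, source_db)
        records.setdefault(rec, None)
    return list(records)


# ---------------------------------------------------------------------------
# BLAST tabular output
# ---------------------------------------------------------------------------

QLEN_HEADER = ("protein_id", "length")


def _read_qlen_table(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for lineno, cells in _read_table(path, QLEN_HEADER):
        pid, raw = cells[0].strip(), cells[1].strip()
        try:
            lengths[pid] = int(raw)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {raw!r}")
    return lengths


def read_blast_tab(path: str | Path, qlen_table_path: str | Path | None = None) -> list[AlignmentHit]:
    """Read BLASTp tabular output (outfmt 6).

    Accepts the standard 12-column dialect (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore) plus an
    optional 13th column carrying the query length.  Rows without a 13th
    column resolve the query length from the 2-column qlen table; a query id
    with no resolvable length is an error.
    """
    qlen = _read_qlen_table(qlen_table_path) if qlen_table_path is not None else {}
    hits: list[AlignmentHit] = []
    for lineno, line in _iter_lines(path):
        cells = line.split("\t")
        if len(cells) not in (12, 13):
            raise ParseError(
                f"{path}:{lineno}: expected 12 or 13 BLAST columns, got {len(cells)}"
            )
        query_id, subject_id = cells[0].strip(), cells[1].strip()
        try:
            pident = float(cells[2])
            qstart = int(cells[6])
            qend = int(cells[7])
            evalue = float(cells[10])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
        if len(cells) == 13:
            try:
                length = int(cells[12])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer qlen {cells[12]!r}")
        elif query_id in qlen:
            length = qlen[query_id]
        else:
            raise ValidationError(
                f"{path}:{lineno}: no query length available for {query_id!r}"
            )
        try:
            hits.append(
                AlignmentHit(query_id, subject_id, pident, qstart, qend, evalue, length)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(
    path: str | Path,
    hits: Iterable[AlignmentHit],
    qlen_table_path: str | Path | None = None,
) -> None:
    """Write hits as 12-column outfmt 6 plus, if requested, a qlen table.

    Fields that outfmt 6 carries but AlignmentHit does not model (aligned
    length, mismatches, gap opens, subject coordinates, bit score) are
    emitted as plausible placeholders derived from the query span.
    """
    lengths: dict[str, int] = {}
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            span = h.align_end_q - h.align_start_q + 1
            row = (
                h.query_id,
                h.subject_id,
                repr(float(h.percent_identity)),
                str(span),
                "0",
                "0",
                str(h.align_start_q),
                str(h.align_end_q),
                "1",
                str(span),
                repr(float(h.evalue)),
                "0.0",
            )
            fh.write("\t".join(row) + "\n")
            lengths[h.query_id] = h.query_length
    if qlen_table_path is not None:
        rows = [(pid, str(n)) for pid, n in sorted(lengths.items())]
        _write_table(qlen_table_path, QLEN_HEADER, rows)


# ---------------------------------------------------------------------------
# domain and DDI tables
# ---------------------------------------------------------------------------

DOMAIN_HEADER = ("protein_id", "domain_accession")
DDI_HEADER = ("domain_x", "domain_y")


def read_domain_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read the 2-column protein-to-domain long table into a mapping."""
    ann: dict[str, set[str]] = {}
    for _, cells in _read_table(path, DOMAIN_HEADER):
        pid, dom = cells[0].strip(), cells[1].strip()
        if not pid or not dom:
            raise ValidationError(f"{path}: empty protein or domain token")
        ann.setdefault(pid, set()).add(dom)
    return {pid: frozenset(doms) for pid, doms in ann.items()}


def write_domain_table(path: str | Path, annotations: Mapping[str, Iterable[str]]) -> None:
    rows = [
        (pid, dom)
        for pid in sorted(annotations)
        for dom in sorted(annotations[pid])
    ]
    _write_table(path, DOMAIN_HEADER, rows)


def read_ddi_rules(path: str | Path) -> set[tuple[str, str]]:
    """Read the DDI rule table into a set of canonical domain pairs."""
    rules: set[tuple[str, str]] = set()
    for _, cells in _read_table(path, DDI_HEADER):
        x, y = cells[0].strip(), cells[1].strip()
        if not x or not y:
            raise ValidationError(f"{path}: empty domain token in DDI rule")
        rules.add(canonical_pair(x, y))
    return rules


def write_ddi_rules(path: str | Path, rules: Iterable[tuple[str, str]]) -> None:
    canon = sorted(canonical_pair(x, y) for x, y in rules)
    _write_table(path, DDI_HEADER, canon)


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

PRESENCE_HEADER = ("protein_id",)


def read_presence_list(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    members = set()
    for _, cells in _read_table(path, PRESENCE_HEADER):
        members.add(cells[0].strip())
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem,
        kind="protein_presence",
        members=frozenset(members),
    )


def write_presence_list(path: str | Path, dataset: ExpressionDataset) -> None:
    assert dataset.members is not None
    _write_table(path, PRESENCE_HEADER, [(m,) for m in sorted(dataset.members)])


def read_expression_matrix(
    path: str | Path,
    kind: str = "gene_matrix",
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix TSV (first column id, then ordered samples)."""
    try:
        table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if table.shape[1] == 0:
        raise ParseError(f"{path}: expression matrix has no sample columns")
    if not all(pd.api.types.is_numeric_dtype(t) for t in table.dtypes):
        raise ParseError(f"{path}: non-numeric expression values")
    table.index = table.index.astype(str)
    return ExpressionDataset(
        dataset_id=dataset_id or Path(path).stem,
        kind=kind,
        table=table.astype(float),
    )


def write_expression_matrix(path: str | Path, dataset: ExpressionDataset) -> None:
    assert dataset.table is not None
    out = dataset.table.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

EDGE_COLUMNS = (
    "protein_a",
    "protein_b",
    "CV",
    "CV_interolog",
    "CV_DDI",
    "N",
    "ddi_count",
    "D",
    "d",
    "tier",
    "expression_supported",
    "coexpressed",
    "supporting_species",
)


@dataclass
class EdgeRow:
    """One (possibly partially scored) network edge as stored in the edge TSV."""

    protein_a: str
    protein_b: str
    cv: float | None = None
    cv_interolog: float | None = None
    cv_ddi: float | None = None
    n_species: int | None = None
    ddi_count: int | None = None
    D: float | None = None
    d: float | None = None
    tier: str | None = None
    expression_supported: bool = False
    coexpressed: bool = False
    supporting_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.protein_a, self.protein_b)
        self.protein_a, self.protein_b = a, b
        self.supporting_species = tuple(self.supporting_species)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def _edge_row_cells(e: EdgeRow) -> tuple[str, ...]:
    return (
        e.protein_a,
        e.protein_b,
        _fmt_float(e.cv),
        _fmt_float(e.cv_interolog),
        _fmt_float(e.cv_ddi),
        "" if e.n_species is None else str(e.n_species),
        "" if e.ddi_count is None else str(e.ddi_count),
        _fmt_float(e.D),
        _fmt_float(e.d),
        e.tier or "",
        "true" if e.expression_supported else "false",
        "true" if e.coexpressed else "false",
        ";".join(e.supporting_species),
    )


def write_edge_rows(path: str | Path, edges: Iterable[EdgeRow]) -> None:
    ordered = sorted(edges, key=lambda e: e.pair)
    _write_table(path, EDGE_COLUMNS, [_edge_row_cells(e) for e in ordered])


def _opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def _opt_int(s: str) -> int | None:
    return None if s == "" else int(s)


def read_edge_tsv(path: str | Path) -> list[EdgeRow]:
    edges: list[EdgeRow] = []
    for lineno, cells in _read_table(path, EDGE_COLUMNS):
        try:
            edges.append(
                EdgeRow(
                    protein_a=cells[0],
                    protein_b=cells[1],
                    cv=_opt_float(cells[2]),
                    cv_interolog=_opt_float(cells[3]),
                    cv_ddi=_opt_float(cells[4]),
                    n_species=_opt_int(cells[5]),
                    ddi_count=_opt_int(cells[6]),
                    D=_opt_float(cells[7]),
                    d=_opt_float(cells[8]),
                    tier=cells[9] or None,
                    expression_supported=cells[10] == "true",
                    coexpressed=cells[11] == "true",
                    supporting_species=tuple(s for s in cells[12].split(";") if s),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return edges


def _prediction_to_edge_row(pred) -> EdgeRow:
    """Convert a PredictedInteraction (duck-typed) to an EdgeRow."""
    score = getattr(pred, "score", None)
    ddi = getattr(score, "ddi", None) if score is not None else None
    return EdgeRow(
        protein_a=pred.pair[0],
        protein_b=pred.pair[1],
        cv=None if score is None else score.cv,
        cv_interolog=None if score is None else score.cv_interolog,
        cv_ddi=None if ddi is None else ddi.cv_ddi,
        n_species=pred.n_species,
        ddi_count=None if ddi is None else ddi.ddi_count,
        D=None if ddi is None else ddi.D,
        d=None if ddi is None else ddi.d,
        tier=getattr(pred, "tier", None),
        expression_supported=getattr(pred, "expression_supported", False),
        coexpressed=getattr(pred, "coexpressed", False),
        supporting_species=tuple(sorted({w.species for w in pred.provenance})),
    )


NETWORK_FORMATS = ("edge_tsv", "node_tsv", "sif", "graphml")


def write_network(
    predictions: Iterable,
    node_attributes: Mapping[str, Mapping[str, object]] | None,
    out_dir: str | Path,
    formats: Iterable[str] = ("edge_tsv",),
    basename: str = "network",
) -> dict[str, Path]:
    """Export a predicted network in one or more interchange formats.

    ``predictions`` may be PredictedInteraction objects or EdgeRows.  Rows
    are emitted in deterministic order (canonical pair, lexicographic).  SIF
    uses the relation token ``pp``; GraphML carries the same edge attributes
    as typed keys.  Returns a mapping format -> written path.
    """
    formats = list(formats)
    unknown = [f for f in formats if f not in NETWORK_FORMATS]
    if unknown:
        raise ValidationError(f"unknown network format(s) {unknown!r}")
    rows = [
        p if isinstance(p, EdgeRow) else _prediction_to_edge_row(p)
        for p in predictions
    ]
    rows.sort(key=lambda e: e.pair)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "edge_tsv" in formats:
        path = out_dir / f"{basename}.edges.tsv"
        write_edge_rows(path, rows)
        written["edge_tsv"] = path
    if "node_tsv" in formats:
        path = out_dir / f"{basename}.nodes.tsv"
        nodes = sorted({n for e in rows for n in e.pair})
        attrs = node_attributes or {}
        keys = sorted({k for v in attrs.values() for k in v})
        header = ["protein_id"] + keys
        table = [
            [n] + [str(attrs.get(n, {}).get(k, "")) for k in keys] for n in nodes
        ]
        _write_table(path, header, table)
        written["node_tsv"] = path
    if "sif" in formats:
        path = out_dir / f"{basename}.sif"
        with open(path, "w", encoding="utf-8") as fh:
            for e in rows:
                fh.write(f"{e.protein_a}\tpp\t{e.protein_b}\n")
        written["sif"] = path
    if "graphml" in formats:
        path = out_dir / f"{basename}.graphml"
        g = nx.Graph()
        attrs = node_attributes or {}
        for e in rows:
            data: dict[str, object] = {
                "expression_supported": e.expression_supported,
                "coexpressed": e.coexpressed,
                "supporting_species": ";".join(e.supporting_species),
            }
            for key, val in (
                ("CV", e.cv),
                ("CV_interolog", e.cv_interolog),
                ("CV_DDI", e.cv_ddi),
                ("D", e.D),
                ("d", e.d),
            ):
                if val is not None:
                    data[key] = float(val)
            if e.n_species is not None:
                data["N"] = int(e.n_species)
            if e.ddi_count is not None:
                data["ddi_count"] = int(e.ddi_count)
            if e.tier is not None:
                data["tier"] = e.tier
            g.add_edge(e.protein_a, e.protein_b, **data)
        for node, data in attrs.items():
            if node in g:
                g.nodes[node].update(data)
        nx.write_graphml(g, path)
        written["graphml"] = path
    return written
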