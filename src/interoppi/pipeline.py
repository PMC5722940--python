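"""One-shot orchestration of the full prediction and validation procedure.

The pipeline chains five file-based stages -- ortholog filtering, interolog
transfer, DDI assessment, confidence scoring/tiering, expression validation
-- followed by a topology characterization of the final network, and writes
a machine-readable JSON run report.  Each stage reads and writes the
canonical interchange files of :mod:`interoppi.io_formats`, and the CLI
exposes exactly these stage functions, so a one-shot run and a manual
stage-by-stage run produce byte-identical outputs.

Configuration is a flat ``key = value`` text file; every threshold of the
method (alignment admission 60/80/1e-10, expression percentile 80,
co-expression PCC > 0.9 and p < 0.1, tier cut points 50/80) is a config key
holding its conventional default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io_formats as iof
from . import orthology, scoring, topology
from .ddi import assess_pair
from .expression import (
    expressed_protein_set,
    find_coexpressed_edges,
    flag_edge_expression,
)
from .interolog import PredictedInteraction, Witness, build_graph, transfer_interactions
from .io_formats import EdgeRow, read_edge_tsv, write_edge_rows

__all__ = [
    "PipelineConfig",
    "RunReport",
    "read_config",
    "run_pipeline",
    "stage_orthologs",
    "stage_predict",
    "stage_ddi",
    "stage_score",
    "stage_expression",
    "stage_topology",
]

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (paths plus method parameters)."""

    templates: list[Path]
    blast: Path
    qlen: Path | None
    domains: Path
    ddi_rules: Path
    presence: list[Path] = field(default_factory=list)
    matrix: list[Path] = field(default_factory=list)
    timeseries: list[Path] = field(default_factory=list)
    out_dir: Path = Path("pipeline_out")
    seed: int = 17
    min_identity: float = orthology.DEFAULT_MIN_IDENTITY
    min_coverage: float = orthology.DEFAULT_MIN_COVERAGE
    max_evalue: float = orthology.DEFAULT_MAX_EVALUE
    expression_percentile: float = 80.0
    expression_summary: str = "mean"
    pcc_min: float = 0.9
    p_max: float = 0.1
    tier_high_cut: float = scoring.TIER_HIGH_CUT
    tier_low_cut: float = scoring.TIER_LOW_CUT
    n_reference: int = 10
    ratio_threshold: float = 2.0
    config_hash: str = ""


_PATH_LIST_KEYS = {"templates", "presence", "matrix", "timeseries"}
_FLOAT_KEYS = {
    "min_identity",
    "min_coverage",
    "max_evalue",
    "expression_percentile",
    "pcc_min",
    "p_max",
    "tier_high_cut",
    "tier_low_cut",
    "ratio_threshold",
}
_INT_KEYS = {"seed", "n_reference"}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file (``#`` comments, blank lines ignored)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    base = path.parent
    raw: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise iof.ParseError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value

    def path_list(key: str) -> list[Path]:
        return [base / p.strip() for p in raw.get(key, "").split(",") if p.strip()]

    kwargs: dict = {}
    for key in ("templates", "presence", "matrix", "timeseries"):
        kwargs[key] = path_list(key)
    for key in ("blast", "domains", "ddi_rules"):
        if key not in raw:
            raise iof.ValidationError(f"{path}: missing required config key {key!r}")
        kwargs[key] = base / raw[key]
    kwargs["qlen"] = base / raw["qlen"] if raw.get("qlen") else None
    kwargs["out_dir"] = base / raw.get("out_dir", "pipeline_out")
    for key in _FLOAT_KEYS:
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in _INT_KEYS:
        if key in raw:
            kwargs[key] = int(raw[key])
    if "expression_summary" in raw:
        kwargs["expression_summary"] = raw["expression_summary"]
    if not kwargs["templates"]:
        raise iof.ValidationError(f"{path}: missing required config key 'templates'")
    cfg = PipelineConfig(**kwargs)
    cfg.config_hash = hashlib.sha256(text.encode("utf-8")).hexdigest()
    return cfg


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str = VERSION
    seed: int = 0
    config_hash: str = ""
    stages: dict = field(default_factory=dict)
    per_species_counts: dict = field(default_factory=dict)
    fraction_expression_supported: float | None = None
    n_coexpressed: int | None = None
    tier_counts: dict = field(default_factory=dict)
    network_stats: dict = field(default_factory=dict)
    small_world: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# file-based stages (shared by run_pipeline and the CLI)
# ---------------------------------------------------------------------------


def stage_orthologs(
    blast: Path,
    qlen: Path | None,
    out: Path,
    min_identity: float = orthology.DEFAULT_MIN_IDENTITY,
    min_coverage: float = orthology.DEFAULT_MIN_COVERAGE,
    max_evalue: float = orthology.DEFAULT_MAX_EVALUE,
) -> dict:
    hits = iof.read_blast_tab(blast, qlen)
    omap = orthology.filter_orthologs(hits, min_identity, min_coverage, max_evalue)
    orthology.write_ortholog_map(out, omap)
    return {"n_hits": len(hits), "n_ortholog_pairs": len(omap)}


def stage_predict(templates: Sequence[Path], orthomap: Path, out: Path) -> dict:
    """Transfer template interactions; writes edges with N and CV_interolog filled."""
    interactions = []
    for t in templates:
        interactions.extend(iof.read_template_ppi_tsv(t))
    omap = orthology.read_ortholog_map(orthomap)
    predictions, report = transfer_interactions(interactions, omap)
    rows = []
    for p in predictions:
        rows.append(
            EdgeRow(
                protein_a=p.pair[0],
                protein_b=p.pair[1],
                cv_interolog=scoring.compute_cv_interolog(p.provenance),
                n_species=p.n_species,
                supporting_species=p.species,
            )
        )
    write_edge_rows(out, rows)
    return {
        "n_templates": report.n_templates,
        "n_transferred_templates": report.n_transferred_templates,
        "n_skipped": report.n_skipped,
        "n_predictions": report.n_predictions,
        "per_species_counts": report.per_species_counts,
    }


def stage_ddi(edges: Path, domains: Path, ddi_rules: Path, out: Path) -> dict:
    """Fill ddi_count, D, d and CV_DDI on every edge row."""
    rows = read_edge_tsv(edges)
    annotations = iof.read_domain_table(domains)
    rules = iof.read_ddi_rules(ddi_rules)
    n_supported = 0
    for row in rows:
        a = assess_pair(row.pair, annotations, rules)
        row.ddi_count, row.D, row.d, row.cv_ddi = a.ddi_count, a.D, a.d, a.cv_ddi
        n_supported += a.ddi_count > 0
    write_edge_rows(out, rows)
    return {"n_edges": len(rows), "n_ddi_supported": n_supported}


def stage_score(
    edges: Path,
    out: Path,
    tier_high_cut: float = scoring.TIER_HIGH_CUT,
    tier_low_cut: float = scoring.TIER_LOW_CUT,
) -> dict:
    """Compute CV = CV_interolog * CV_DDI and assign B/H1/H2/H3 tiers."""
    rows = read_edge_tsv(edges)
    for row in rows:
        if row.cv_interolog is None or row.cv_ddi is None:
            raise iof.ValidationError(
                f"edge {row.pair} lacks CV_interolog/CV_DDI; run predict and ddi first"
            )
        row.cv = scoring.compute_cv(row.cv_interolog, row.cv_ddi)
    high = [r for r in rows if r.ddi_count]
    for row in rows:
        if not row.ddi_count:
            row.tier = "B"
    if high:
        ranks = scoring.percentile_ranks([r.cv for r in high])
        for row, rank in zip(high, ranks):
            if rank > tier_high_cut:
                row.tier = "H1"
            elif rank >= tier_low_cut:
                row.tier = "H2"
            else:
                row.tier = "H3"
    write_edge_rows(out, rows)
    counts: dict[str, int] = {}
    for row in rows:
        counts[row.tier] = counts.get(row.tier, 0) + 1
    return {"n_edges": len(rows), "tier_counts": counts}


def _load_expression(cfg: PipelineConfig) -> tuple[list, list]:
    static = [iof.read_presence_list(p) for p in cfg.presence]
    static += [iof.read_expression_matrix(p, kind="gene_matrix") for p in cfg.matrix]
    series = [iof.read_expression_matrix(p, kind="time_series") for p in cfg.timeseries]
    return static, series


def stage_expression(
    edges: Path,
    out: Path,
    presence: Sequence[Path] = (),
    matrix: Sequence[Path] = (),
    timeseries: Sequence[Path] = (),
    expression_percentile: float = 80.0,
    expression_summary: str = "mean",
    pcc_min: float = 0.9,
    p_max: float = 0.1,
) -> dict:
    """Flag expression-supported and co-expressed edges."""
    rows = read_edge_tsv(edges)
    static = [iof.read_presence_list(p) for p in presence]
    static += [iof.read_expression_matrix(p, kind="gene_matrix") for p in matrix]
    series = [iof.read_expression_matrix(p, kind="time_series") for p in timeseries]
    expressed = expressed_protein_set(
        static + series, percentile=expression_percentile, summary=expression_summary
    )
    # EdgeRow quacks enough like a prediction for the flagging helpers
    fraction = flag_edge_expression(rows, expressed)
    results = find_coexpressed_edges(rows, series, pcc_min=pcc_min, p_max=p_max)
    write_edge_rows(out, rows)
    return {
        "n_edges": len(rows),
        "n_expressed_proteins": len(expressed),
        "fraction_expression_supported": fraction,
        "n_coexpressed": sum(r.coexpressed for r in rows),
        "n_correlations": len(results),
    }


def stage_topology(
    edges: Path,
    out: Path,
    seed: int,
    n_reference: int = 10,
    ratio_threshold: float = 2.0,
) -> dict:
    """Global topology statistics and small-world comparison of the network."""
    rows = read_edge_tsv(edges)
    import networkx as nx

    g = nx.Graph()
    for row in rows:
        g.add_edge(*row.pair)
    stats = topology.network_stats(g)
    payload: dict = {"network_stats": stats.to_dict()}
    try:
        report = topology.small_world_report(
            g, seed=seed, n_reference=n_reference, ratio_threshold=ratio_threshold
        )
        payload["small_world"] = report.to_dict()
    except ValueError as exc:
        payload["small_world"] = {"error": str(exc)}
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload


# ---------------------------------------------------------------------------
# one-shot run
# ---------------------------------------------------------------------------


def run_pipeline(config_path: str | Path) -> RunReport:
    """Run all stages in order; returns (and writes) the run report.

    All inputs are checked for existence before any stage runs.  On a stage
    failure the partial outputs are preserved and the report marks the
    failed stage before the exception propagates.
    """
    cfg = read_config(config_path)
    required = list(cfg.templates) + [cfg.blast, cfg.domains, cfg.ddi_rules]
    required += list(cfg.presence) + list(cfg.matrix) + list(cfg.timeseries)
    if cfg.qlen is not None:
        required.append(cfg.qlen)
    missing = [str(p) for p in required if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, config_hash=cfg.config_hash)

    stage_files = {
        "orthologs": out / "orthologs.tsv",
        "predict": out / "edges.predicted.tsv",
        "ddi": out / "edges.ddi.tsv",
        "score": out / "edges.scored.tsv",
        "expression": out / "edges.validated.tsv",
        "topology": out / "topology.json",
    }
    try:
        report.stages["orthologs"] = stage_orthologs(
            cfg.blast,
            cfg.qlen,
            stage_files["orthologs"],
            cfg.min_identity,
            cfg.min_coverage,
            cfg.max_evalue,
        )
        report.stages["predict"] = stage_predict(
            cfg.templates, stage_files["orthologs"], stage_files["predict"]
        )
        report.per_species_counts = report.stages["predict"]["per_species_counts"]
        report.stages["ddi"] = stage_ddi(
            stage_files["predict"], cfg.domains, cfg.ddi_rules, stage_files["ddi"]
        )
        report.stages["score"] = stage_score(
            stage_files["ddi"], stage_files["score"], cfg.tier_high_cut, cfg.tier_low_cut
        )
        report.tier_counts = report.stages["score"]["tier_counts"]
        report.stages["expression"] = stage_expression(
            stage_files["score"],
            stage_files["expression"],
            presence=cfg.presence,
            matrix=cfg.matrix,
            timeseries=cfg.timeseries,
            expression_percentile=cfg.expression_percentile,
            expression_summary=cfg.expression_summary,
            pcc_min=cfg.pcc_min,
            p_max=cfg.p_max,
        )
        report.fraction_expression_supported = report.stages["expression"][
            "fraction_expression_supported"
        ]
        report.n_coexpressed = report.stages["expression"]["n_coexpressed"]
        report.stages["topology"] = stage_topology(
            stage_files["expression"],
            stage_files["topology"],
            seed=cfg.seed,
            n_reference=cfg.n_reference,
            ratio_threshold=cfg.ratio_threshold,
        )
        report.network_stats = report.stages["topology"]["network_stats"]
        report.small_world = report.stages["topology"]["small_world"]
    except Exception as exc:
        done = set(report.stages)
        remaining = [s for s in stage_files if s not in done]
        report.failed_stage = remaining[0] if remaining else None
        report.to_json(out / "run_report.json")
        logger.error("stage %s failed: %s", report.failed_stage, exc)
        raise
    report.to_json(out / "run_report.json")
    return report
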