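"""Seeded synthetic test worlds with recorded planted truth.

The generator emulates the input landscape of an interolog study: several
template species with interaction sets of very unequal size (one dominant,
well-studied species and a log-spread tail, as real aggregated databases
show), a many-to-many ortholog map encoded as BLASTp-style alignment hits
that straddle the admission thresholds, Pfam-style domain annotations with
planted interacting-domain rules, and expression data (presence lists plus
time-series matrices) with planted co-expressed pairs sharing a latent
random-walk profile.

Template interactions are drawn over a common pool of *gene families*; the
same family pair interacting in two species therefore transfers to the same
target pair, producing multi-species support (N > 1).  Conserved families
receive alignment hits sampled strictly inside the admission region
(identity >= 60, query coverage >= 80, e-value <= 1e-10) while decoy hits
are sampled to fail at least one threshold, so the set of transferable
interactions -- and every downstream score component -- is known exactly
and recorded in :class:`SyntheticTruth` for recovery-based testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    AlignmentHit,
    ExpressionDataset,
    TemplateInteraction,
    canonical_pair,
)

__all__ = [
    "WorldConfig",
    "World",
    "ExpectedScore",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_world",
    "write_world",
    "end_to_end_check",
]

DEFAULT_SPECIES = ("ath", "osa", "stu", "zma", "gma", "ptr", "rco")


@dataclass
class WorldConfig:
    """Study conditions of one synthetic world.

    Defaults mimic the aggregated-database setting of an interolog study:
    seven template species whose interaction counts are log-spread so one
    species dominates, a four-point expression time course, and moderate
    conservation, evidence and support fractions.
    """

    species: tuple[str, ...] = DEFAULT_SPECIES
    edges_per_species: tuple[int, ...] = (500, 120, 30, 14, 8, 6, 4)
    n_families: int = 400
    conservation_fraction: float = 0.7
    paralog_fraction: float = 0.1
    experimental_fraction: float = 0.3
    ddi_fraction: float = 0.3
    domain_count_probs: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)  # 1..4 domains
    n_time_points: int = 4
    noise_sigma: float = 0.05
    coexpressed_fraction: float = 0.1
    n_time_series: int = 2
    n_presence: int = 2
    presence_fraction: float = 0.5

    def __post_init__(self) -> None:
        if len(self.edges_per_species) != len(self.species):
            raise ValueError("edges_per_species must match the species list")
        for name, frac in (
            ("conservation_fraction", self.conservation_fraction),
            ("paralog_fraction", self.paralog_fraction),
            ("experimental_fraction", self.experimental_fraction),
            ("ddi_fraction", self.ddi_fraction),
            ("coexpressed_fraction", self.coexpressed_fraction),
            ("presence_fraction", self.presence_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        if any(n < 0 for n in self.edges_per_species):
            raise ValueError("negative per-species edge count")
        if self.n_families <= 2 or self.n_time_points < 3:
            raise ValueError("need > 2 families and >= 3 time points")
        if abs(sum(self.domain_count_probs) - 1.0) > 1e-9:
            raise ValueError("domain_count_probs must sum to 1")


@dataclass(frozen=True)
class ExpectedScore:
    """Independently recomputed score components for one transferable pair."""

    n_species: int
    m_by_species: tuple[tuple[str, float], ...]
    cv_interolog: float
    ddi_count: int
    n_dom_a: int
    n_dom_b: int
    D: float
    d: float
    cv_ddi: float
    cv: float


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic world."""

    transferable_interactions: set[tuple[str, str]] = field(default_factory=set)
    expected_scores: dict[tuple[str, str], ExpectedScore] = field(default_factory=dict)
    ddi_supported_pairs: set[tuple[str, str]] = field(default_factory=set)
    coexpressed_pairs: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class World:
    """All pipeline inputs of one synthetic world, in canonical in-memory form."""

    config: WorldConfig
    seed: int
    template_interactions: list[TemplateInteraction]
    alignment_hits: list[AlignmentHit]
    domain_annotations: dict[str, frozenset[str]]
    ddi_rules: set[tuple[str, str]]
    expression_datasets: list[ExpressionDataset]


def _passing_hit(
    rng: np.random.Generator, query_id: str, subject_id: str, qlen: int
) -> AlignmentHit:
    """A hit strictly inside the admission region (all three thresholds pass)."""
    identity = float(rng.uniform(60.0, 99.9))
    span = int(math.ceil(0.8 * qlen)) + int(rng.integers(0, qlen - math.ceil(0.8 * qlen) + 1))
    span = min(span, qlen)
    evalue = float(10.0 ** -rng.uniform(10.0, 60.0))
    return AlignmentHit(query_id, subject_id, identity, 1, span, evalue, qlen)


def _failing_hit(
    rng: np.random.Generator, query_id: str, subject_id: str, qlen: int
) -> AlignmentHit:
    """A decoy hit guaranteed to fail at least one admission threshold."""
    which = int(rng.integers(1, 8))  # non-empty subset of {identity, coverage, evalue}
    fail_identity = bool(which & 1)
    fail_coverage = bool(which & 2)
    fail_evalue = bool(which & 4)
    identity = float(rng.uniform(20.0, 59.5)) if fail_identity else float(rng.uniform(60.0, 99.9))
    if fail_coverage:
        span = max(1, int(0.79 * qlen) - int(rng.integers(0, qlen // 3)))
    else:
        span = min(qlen, int(math.ceil(0.8 * qlen)) + int(rng.integers(0, max(1, qlen // 5))))
    evalue = float(10.0 ** -rng.uniform(0.5, 9.5)) if fail_evalue else float(10.0 ** -rng.uniform(10.0, 60.0))
    return AlignmentHit(query_id, subject_id, identity, 1, span, evalue, qlen)


def _species_edges(
    rng: np.random.Generator, n_edges: int, n_families: int
) -> list[tuple[int, int]]:
    """Preferential-attachment edge list over a random family subset."""
    if n_edges == 0:
        return []
    m_attach = 2 if n_edges >= 4 else 1
    n_nodes = max(m_attach + 1, n_edges // m_attach + 2)
    n_nodes = min(n_nodes, n_families)
    families = rng.choice(n_families, size=n_nodes, replace=False)
    # Barabasi-Albert growth with a repeated-node attachment pool
    targets = list(range(m_attach))
    pool: list[int] = []
    edges: list[tuple[int, int]] = []
    for new in range(m_attach, n_nodes):
        for t in targets:
            edges.append((int(families[new]), int(families[t])))
        pool.extend(targets)
        pool.extend([new] * m_attach)
        chosen: set[int] = set()
        while len(chosen) < m_attach and len(chosen) < new + 1:
            chosen.add(pool[int(rng.integers(0, len(pool)))])
        targets = list(chosen)
    rng.shuffle(edges)
    return edges[:n_edges]


def generate_world(
    config: WorldConfig | None = None, seed: int = 0
) -> tuple[World, SyntheticTruth]:
    """Generate a seeded synthetic world and its planted truth."""
    cfg = config or WorldConfig()
    rng = np.random.default_rng(seed)

    conserved = rng.random(cfg.n_families) < cfg.conservation_fraction
    targets: dict[int, tuple[str, ...]] = {}
    for k in range(cfg.n_families):
        if conserved[k]:
            names = [f"Me{k:04d}"]
            if rng.random() < cfg.paralog_fraction:
                names.append(f"Me{k:04d}p")
            targets[k] = tuple(names)

    template_interactions: list[TemplateInteraction] = []
    family_edges: dict[str, list[tuple[int, int]]] = {}
    for sp, n_edges in zip(cfg.species, cfg.edges_per_species):
        edges = _species_edges(rng, n_edges, cfg.n_families)
        family_edges[sp] = edges
        for fa, fb in edges:
            evidence = (
                "experimental"
                if rng.random() < cfg.experimental_fraction
                else "computational"
            )
            template_interactions.append(
                TemplateInteraction(
                    sp, f"{sp}_P{fa:04d}", f"{sp}_P{fb:04d}", evidence, f"{sp}_db"
                )
            )
    # collapse duplicates exactly as the reader would
    template_interactions = list(dict.fromkeys(template_interactions))

    # alignment hits: passing hits for conserved template proteins, decoys otherwise
    alignment_hits: list[AlignmentHit] = []
    used_families: dict[str, set[int]] = {
        sp: {f for e in edges for f in e} for sp, edges in family_edges.items()
    }
    target_pool = sorted({t for names in targets.values() for t in names}) or ["Me9999"]
    qlens: dict[str, int] = {}  # one length per template protein (keys the qlen table)
    for sp in cfg.species:
        for fam in sorted(used_families[sp]):
            qid = f"{sp}_P{fam:04d}"
            qlen = qlens.setdefault(qid, int(rng.integers(150, 600)))
            if conserved[fam]:
                for tgt in targets[fam]:
                    alignment_hits.append(_passing_hit(rng, qid, tgt, qlen))
                # an extra decoy against a wrong target exercises the filter
                if rng.random() < 0.3:
                    wrong = target_pool[int(rng.integers(0, len(target_pool)))]
                    if wrong not in targets[fam]:
                        alignment_hits.append(_failing_hit(rng, qid, wrong, qlen))
            else:
                wrong = target_pool[int(rng.integers(0, len(target_pool)))]
                alignment_hits.append(_failing_hit(rng, qid, wrong, qlen))

    # ground truth transfer: nested loops over template edges and ortholog sets
    truth = SyntheticTruth()
    witnesses: dict[tuple[str, str], dict[str, float]] = {}
    for t in template_interactions:
        fa = int(t.protein_a.split("_P")[1])
        fb = int(t.protein_b.split("_P")[1])
        if not (conserved[fa] and conserved[fb]):
            continue
        m = 1.0 if t.evidence_method == "experimental" else 0.5
        for a in targets[fa]:
            for b in targets[fb]:
                pair = canonical_pair(a, b)
                sp_m = witnesses.setdefault(pair, {})
                sp_m[t.species] = max(sp_m.get(t.species, 0.0), m)
    truth.transferable_interactions = set(witnesses)

    # domains and DDI rules
    network_proteins = sorted({p for pair in witnesses for p in pair})
    domain_annotations: dict[str, frozenset[str]] = {}
    next_acc = 0
    counts = rng.choice(
        np.arange(1, len(cfg.domain_count_probs) + 1),
        size=len(network_proteins),
        p=cfg.domain_count_probs,
    )
    for protein, n_dom in zip(network_proteins, counts):
        doms = frozenset(f"PF{next_acc + i:05d}" for i in range(int(n_dom)))
        next_acc += int(n_dom)
        domain_annotations[protein] = doms

    ddi_rules: set[tuple[str, str]] = set()
    sorted_pairs = sorted(witnesses)
    planted = rng.random(len(sorted_pairs)) < cfg.ddi_fraction
    for pair, plant in zip(sorted_pairs, planted):
        if not plant:
            continue
        doms_a = sorted(domain_annotations[pair[0]])
        doms_b = sorted(domain_annotations[pair[1]])
        x = doms_a[int(rng.integers(0, len(doms_a)))]
        y = doms_b[int(rng.integers(0, len(doms_b)))]
        ddi_rules.add(canonical_pair(x, y))
    # a few decoy rules among fresh accessions (support nothing)
    for _ in range(5):
        ddi_rules.add(canonical_pair(f"PF{next_acc:05d}", f"PF{next_acc + 1:05d}"))
        next_acc += 2

    # expected scores, recomputed from the planted annotations by the formulas
    for pair, sp_m in witnesses.items():
        n = len(sp_m)
        cv_int = sum(sp_m[s] for s in sorted(sp_m)) / n
        doms_a = domain_annotations[pair[0]]
        doms_b = domain_annotations[pair[1]]
        matched = {
            canonical_pair(x, y)
            for x in doms_a
            for y in doms_b
            if canonical_pair(x, y) in ddi_rules
        }
        count = len(matched)
        n_a, n_b = len(doms_a), len(doms_b)
        D = count / (n_a * n_b) if n_a and n_b else 0.0
        d = 0.5 if (n_a == 1 and n_b == 1) else 1.0
        cv_ddi = d * D
        truth.expected_scores[pair] = ExpectedScore(
            n_species=n,
            m_by_species=tuple(sorted(sp_m.items())),
            cv_interolog=cv_int,
            ddi_count=count,
            n_dom_a=n_a,
            n_dom_b=n_b,
            D=D,
            d=d,
            cv_ddi=cv_ddi,
            cv=cv_int * cv_ddi,
        )
        if count > 0:
            truth.ddi_supported_pairs.add(pair)

    # expression data
    datasets: list[ExpressionDataset] = []
    for i in range(cfg.n_presence):
        members = [
            p for p in network_proteins if rng.random() < cfg.presence_fraction
        ]
        datasets.append(
            ExpressionDataset(
                dataset_id=f"presence{i + 1}",
                kind="protein_presence",
                members=frozenset(members),
            )
        )

    candidate_pairs = [p for p in sorted_pairs if p[0] != p[1]]
    plant_coex = rng.random(len(candidate_pairs)) < cfg.coexpressed_fraction
    latent: dict[str, np.ndarray] = {}
    for pair, plant in zip(candidate_pairs, plant_coex):
        if not plant:
            continue
        a, b = pair
        if a in latent and b in latent:
            continue  # both already committed to other groups
        profile = latent.get(a)
        if profile is None:
            profile = latent.get(b)
        if profile is None:
            profile = np.cumsum(rng.normal(size=cfg.n_time_points))
        latent[a] = profile
        latent[b] = profile
        truth.coexpressed_pairs.add(pair)
    time_cols = [f"t{j}" for j in range(cfg.n_time_points)]
    for i in range(cfg.n_time_series):
        rows = {}
        for p in network_proteins:
            base = latent.get(p)
            if base is None:
                base = np.cumsum(rng.normal(size=cfg.n_time_points))
            values = base + rng.normal(scale=cfg.noise_sigma, size=cfg.n_time_points)
            rows[p] = values - values.min()  # expression levels are non-negative
        if rows:
            table = pd.DataFrame.from_dict(rows, orient="index")
            table.columns = time_cols
        else:
            table = pd.DataFrame(columns=time_cols, index=pd.Index([], dtype=str))
        table = table.sort_index().astype(float)
        datasets.append(
            ExpressionDataset(
                dataset_id=f"timeseries{i + 1}", kind="time_series", table=table
            )
        )

    world = World(
        config=cfg,
        seed=seed,
        template_interactions=template_interactions,
        alignment_hits=alignment_hits,
        domain_annotations=domain_annotations,
        ddi_rules=ddi_rules,
        expression_datasets=datasets,
    )
    return world, truth


def write_world(world: World, truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Persist a world as the canonical pipeline input files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["templates"] = out / "templates.tsv"
    iof.write_template_ppi_tsv(paths["templates"], world.template_interactions)
    paths["blast"] = out / "blast.tsv"
    paths["qlen"] = out / "qlen.tsv"
    iof.write_blast_tab(paths["blast"], world.alignment_hits, paths["qlen"])
    paths["domains"] = out / "domains.tsv"
    iof.write_domain_table(paths["domains"], world.domain_annotations)
    paths["ddi_rules"] = out / "ddi_rules.tsv"
    iof.write_ddi_rules(paths["ddi_rules"], world.ddi_rules)
    for ds in world.expression_datasets:
        p = out / f"{ds.dataset_id}.tsv"
        if ds.kind == "protein_presence":
            iof.write_presence_list(p, ds)
        else:
            iof.write_expression_matrix(p, ds)
        paths[ds.dataset_id] = p
    paths["truth"] = out / "truth.json"
    payload = {
        "transferable_interactions": sorted(map(list, truth.transferable_interactions)),
        "ddi_supported_pairs": sorted(map(list, truth.ddi_supported_pairs)),
        "coexpressed_pairs": sorted(map(list, truth.coexpressed_pairs)),
        "expected_scores": {
            f"{a}\t{b}": asdict(score)
            for (a, b), score in sorted(truth.expected_scores.items())
        },
        "seed": world.seed,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


@dataclass
class RecoveryReport:
    """Agreement between a pipeline run and a world's planted truth."""

    transfer_recall: float
    transfer_precision: float
    n_predictions: int
    n_score_mismatches: int
    scores_match: bool
    coexpression_tp: int
    coexpression_fn: int
    coexpression_fp: int


def end_to_end_check(
    truth: SyntheticTruth,
    predictions: Iterable,
    coexpressed_pairs: Iterable[tuple[str, str]] | None = None,
) -> RecoveryReport:
    """Compare pipeline output with the planted truth.

    Checks the predicted pair set against the transferable set, every score
    component against the truth's expectation (exact equality: both sides
    follow the same closed-form arithmetic), and, when given, the detected
    co-expressed pairs against the planted ones.
    """
    preds = {p.pair: p for p in predictions}
    expected = truth.transferable_interactions
    got = set(preds)
    recall = len(got & expected) / len(expected) if expected else 1.0
    precision = len(got & expected) / len(got) if got else 1.0

    mismatches = 0
    for pair, exp in truth.expected_scores.items():
        pred = preds.get(pair)
        score = getattr(pred, "score", None) if pred is not None else None
        if score is None:
            mismatches += 1
            continue
        ok = (
            score.n_species == exp.n_species
            and tuple(score.m_by_species) == exp.m_by_species
            and score.cv_interolog == exp.cv_interolog
            and score.ddi.ddi_count == exp.ddi_count
            and score.ddi.D == exp.D
            and score.ddi.d == exp.d
            and score.ddi.cv_ddi == exp.cv_ddi
            and score.cv == exp.cv
        )
        mismatches += not ok

    tp = fn = fp = 0
    if coexpressed_pairs is not None:
        detected = {canonical_pair(*p) for p in coexpressed_pairs}
        tp = len(detected & truth.coexpressed_pairs)
        fn = len(truth.coexpressed_pairs - detected)
        fp = len(detected - truth.coexpressed_pairs)
    return RecoveryReport(
        transfer_recall=recall,
        transfer_precision=precision,
        n_predictions=len(got),
        n_score_mismatches=mismatches,
        scores_match=mismatches == 0,
        coexpression_tp=tp,
        coexpression_fn=fn,
        coexpression_fp=fp,
    )
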