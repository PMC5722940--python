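"""Expression support, Pearson co-expression detection, component classification."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interoppi.expression import (
    UndefinedCorrelationError,
    classify_coexpression_groups,
    expressed_protein_set,
    find_coexpressed_edges,
    flag_edge_expression,
    high_expression_set,
    pearson_with_p,
)
from interoppi.interolog import PredictedInteraction, Witness
from interoppi.io_formats import ExpressionDataset
from interoppi.synthetic import WorldConfig, generate_world
from interoppi.orthology import filter_orthologs
from interoppi.interolog import transfer_interactions


def matrix_dataset(values, ids=None, kind="gene_matrix", dataset_id="ds"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    table = pd.DataFrame(values, index=ids, columns=[f"t{j}" for j in range(values.shape[1])])
    return ExpressionDataset(dataset_id, kind, table=table)


def prediction(a, b):
    return PredictedInteraction(
        pair=(a, b), provenance=frozenset({Witness("ath", "computational", "db", ("A", "B"))})
    )


class TestHighExpressionSet:
    def test_ten_genes_top_two_pass(self):
        """Brute-force scan of summaries 1..10: only values above the 80th
        percentile (8.2 under linear interpolation) qualify."""
        ds = matrix_dataset([[v] * 3 for v in range(1, 11)])
        assert high_expression_set(ds) == {"g8", "g9"}  # summaries 9 and 10

    def test_flat_dataset_yields_empty_set(self):
        ds = matrix_dataset([[5.0] * 3 for _ in range(6)])
        assert high_expression_set(ds) == set()

    def test_single_gene_cannot_exceed_its_own_rank(self):
        ds = matrix_dataset([[7.0, 8.0, 9.0]])
        assert high_expression_set(ds) == set()

    def test_empty_matrix_is_error(self):
        ds = matrix_dataset(np.empty((0, 3)))
        with pytest.raises(ValueError):
            high_expression_set(ds)

    def test_max_summary_option(self):
        ds = matrix_dataset([[0, 20, 1], [10, 10, 10], [1, 1, 1], [2, 2, 2], [3, 3, 3]])
        assert "g0" in high_expression_set(ds, summary="max")
        assert "g0" not in high_expression_set(ds, summary="mean")


class TestExpressedProteinSet:
    def test_union_of_presence_and_matrix(self):
        presence = ExpressionDataset("p", "protein_presence", members=frozenset({"a", "b"}))
        # 10-gene matrix where b and c are the two high expressors
        names = ["b", "c"] + [f"x{i}" for i in range(8)]
        ds = matrix_dataset([[10] * 3, [9] * 3] + [[i] * 3 for i in range(8)], ids=names)
        assert expressed_protein_set([presence, ds]) == {"a", "b", "c"}

    def test_no_datasets_empty(self):
        assert expressed_protein_set([]) == set()


class TestEdgeFlagging:
    def test_both_endpoints_required(self):
        preds = [prediction("a", "b")]
        assert flag_edge_expression(preds, {"a"}) == 0.0
        assert not preds[0].expression_supported
        assert flag_edge_expression(preds, {"a", "b"}) == 1.0
        assert preds[0].expression_supported

    def test_fraction_over_four_edges(self):
        preds = [prediction(x, y) for x, y in [("a", "b"), ("a", "c"), ("c", "d"), ("d", "e")]]
        assert flag_edge_expression(preds, {"a", "b"}) == 0.25


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert (r, p) == (1.0, 0.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson_with_p([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == -1.0

    def test_hand_computed_covariance_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        mx, my = sum(x) / 4, sum(y) / 4
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        r_direct = cov / math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        t = r_direct * math.sqrt(2 / (1 - r_direct**2))
        from scipy.stats import t as t_dist

        p_direct = 2 * t_dist.sf(abs(t), df=2)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)
        assert r == pytest.approx(0.9827, abs=5e-5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_matches_direct_computation_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        r, _ = pearson_with_p(x, y)
        cov = np.sum((x - x.mean()) * (y - y.mean()))
        r_direct = cov / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(r_direct, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_invariance_under_positive_affine_transform(self, scale, shift):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r0, _ = pearson_with_p(x, y)
        r1, _ = pearson_with_p(scale * x + shift, y)
        r2, _ = pearson_with_p(-scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(-r0, abs=1e-9)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_profiles_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2], [3, 4])


class TestCoexpressionDetection:
    def test_strict_thresholds(self):
        # exactly PCC = 0.9 must NOT qualify; the thresholds are strict
        preds = [prediction("a", "b")]
        ds = matrix_dataset(
            [[0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0]], ids=["a", "b"], kind="time_series"
        )
        find_coexpressed_edges(preds, [ds])
        assert preds[0].coexpressed  # PCC = 1 > 0.9, p = 0 < 0.1

    def test_any_dataset_rule(self):
        preds = [prediction("a", "b")]
        uncorrelated = matrix_dataset(
            [[1.0, 5.0, 2.0, 6.0], [6.0, 2.0, 5.0, 1.0]], ids=["a", "b"],
            kind="time_series", dataset_id="ds1",
        )
        correlated = matrix_dataset(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]], ids=["a", "b"],
            kind="time_series", dataset_id="ds2",
        )
        results = find_coexpressed_edges(preds, [uncorrelated, correlated])
        assert preds[0].coexpressed
        assert {r.dataset_id for r in results} == {"ds1", "ds2"}

    def test_missing_profile_skips_dataset(self):
        preds = [prediction("a", "zz")]
        ds = matrix_dataset([[1.0, 2.0, 3.0]], ids=["a"], kind="time_series")
        assert find_coexpressed_edges(preds, [ds]) == []
        assert not preds[0].coexpressed

    def test_boundary_pcc_excluded(self):
        """A profile pair engineered to sit exactly at PCC = 0.9 is rejected."""
        from interoppi.expression import pearson_with_p as pwp

        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        # mix x with an orthogonal residual so that corr(x, y) = 0.9 exactly
        e = np.array([1.0, -1.0] * 5)
        e = e - e.mean()
        e = e - (np.dot(e, x - x.mean()) / np.dot(x - x.mean(), x - x.mean())) * (x - x.mean())
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        es = e / np.linalg.norm(e)
        y = 0.9 * xs + math.sqrt(1 - 0.81) * es
        r, _ = pwp(x, y + 10)
        assert r == pytest.approx(0.9, abs=1e-12)
        preds = [prediction("a", "b")]
        ds = matrix_dataset([x, y + 10], ids=["a", "b"], kind="time_series")
        find_coexpressed_edges(preds, [ds], pcc_min=r)  # threshold == value: strict
        assert not preds[0].coexpressed

    def test_planted_pairs_detected_at_zero_noise(self):
        cfg = WorldConfig(noise_sigma=0.0, n_time_series=1, n_presence=0)
        world, truth = generate_world(cfg, seed=5)
        omap = filter_orthologs(world.alignment_hits)
        preds, _ = transfer_interactions(world.template_interactions, omap)
        series = [d for d in world.expression_datasets if d.kind == "time_series"]
        find_coexpressed_edges(preds, series)
        detected = {p.pair for p in preds if p.coexpressed}
        assert truth.coexpressed_pairs <= detected

    def test_false_detection_rate_of_independent_profiles(self):
        """For independent length-4 Gaussian profiles the sample correlation is
        uniform on [-1, 1], so P(PCC > 0.9 and p < 0.1) is near 0.05 -- well
        below the 0.1 the p-gate alone would allow."""
        rng = np.random.default_rng(1234)
        n_pairs = 10_000
        hits = 0
        for _ in range(n_pairs):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            r, p = pearson_with_p(x, y)
            hits += (r > 0.9) and (p < 0.1)
        rate = hits / n_pairs
        assert 0.0 < rate < 0.1


class TestGroupClassification:
    def test_single_edge_heterodimeric(self):
        (grp,) = classify_coexpression_groups([("M3", "SUMO1")])
        assert grp.shape == "heterodimeric"

    def test_three_path_linear(self):
        (grp,) = classify_coexpression_groups([("a", "b"), ("b", "c")])
        assert grp.shape == "linear_multimeric" and not grp.branched

    def test_triangle_circular(self):
        (grp,) = classify_coexpression_groups([("NOC2P", "RRB"), ("RRB", "PES"), ("NOC2P", "PES")])
        assert grp.shape == "circular_multimeric"

    def test_branched_acyclic_reported_linear_with_warning(self):
        edges = [("hub", x) for x in ("a", "b", "c")]
        with pytest.warns(UserWarning, match="branched"):
            (grp,) = classify_coexpression_groups(edges)
        assert grp.shape == "linear_multimeric" and grp.branched

    def test_matches_cycle_detection_oracle_on_small_graphs(self):
        """Classification agrees with an exhaustive DFS cycle oracle on random
        graphs of up to 8 nodes."""

        def has_cycle_dfs(nodes, edges):
            adj = {n: set() for n in nodes}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen = set()
            for start in nodes:
                if start in seen:
                    continue
                stack = [(start, None)]
                visited_here = set()
                while stack:
                    node, parent = stack.pop()
                    if node in visited_here:
                        return True
                    visited_here.add(node)
                    for nb in adj[node]:
                        if nb != parent:
                            stack.append((nb, node))
                seen |= visited_here
            return False

        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
            k = int(rng.integers(1, len(possible) + 1))
            idx = rng.choice(len(possible), size=k, replace=False)
            edges = [(f"n{possible[i][0]}", f"n{possible[i][1]}") for i in idx]
            groups = classify_coexpression_groups(edges)
            g = nx.Graph(edges)
            for grp in groups:
                comp_edges = [e for e in edges if e[0] in grp.proteins]
                cyclic = has_cycle_dfs(sorted(grp.proteins), grp.edges)
                if grp.shape == "circular_multimeric":
                    assert cyclic
                else:
                    assert not cyclic
                if grp.shape == "heterodimeric":
                    assert len(grp.proteins) == 2

    def test_permutation_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")]
        g1 = classify_coexpression_groups(edges)
        g2 = classify_coexpression_groups(list(reversed(edges)))
        assert [(g.shape, g.proteins) for g in g1] == [(g.shape, g.proteins) for g in g2]
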