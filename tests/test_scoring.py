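"""Confidence value computation and percentile-based tier assignment."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interoppi.ddi import DdiAssessment
from interoppi.interolog import PredictedInteraction, Witness
from interoppi.scoring import (
    ScoreBreakdown,
    assign_tiers,
    compute_cv,
    compute_cv_interolog,
    percentile_ranks,
)


def witness(species="ath", evidence="computational", n=0):
    return Witness(species, evidence, "db", (f"A{n}", f"B{n}"))


class TestCvInterolog:
    def test_single_computational_species(self):
        assert compute_cv_interolog([witness()]) == 0.5

    def test_mixed_two_species_mean(self):
        prov = [witness("ath", "experimental"), witness("osa", "computational")]
        assert compute_cv_interolog(prov) == 0.75

    def test_experimental_dominates_within_one_species(self):
        prov = [witness("ath", "experimental"), witness("ath", "computational", n=1)]
        assert compute_cv_interolog(prov) == 1.0

    def test_empty_provenance_is_error(self):
        with pytest.raises(ValueError):
            compute_cv_interolog([])

    def test_exhaustive_witness_combinations_match_per_species_max(self):
        """Per-species M is the max over that species' witnesses, enumerated."""
        species = ["ath", "osa"]
        kinds = ["experimental", "computational"]
        for assignment in itertools.product(kinds, repeat=4):
            prov = [
                witness(sp, kind, n=i)
                for i, (sp, kind) in enumerate(zip(species * 2, assignment))
            ]
            expected_m = {
                sp: max(
                    1.0 if k == "experimental" else 0.5
                    for w, k in zip(species * 2, assignment)
                    if w == sp
                )
                for sp in species
            }
            expected = sum(expected_m.values()) / len(expected_m)
            assert compute_cv_interolog(prov) == expected


class TestFinalCv:
    def test_product_of_worked_example_factors(self):
        assert compute_cv(0.5, 2 / 12) == pytest.approx(0.0833, abs=5e-5)

    def test_zero_ddi_annihilates(self):
        for x in (0.5, 0.75, 1.0):
            assert compute_cv(x, 0.0) == 0.0

    @settings(derandomize=True, max_examples=500)
    @given(
        st.integers(1, 7),
        st.integers(1, 6),
        st.integers(1, 6),
        st.data(),
    )
    def test_all_computational_provenance_caps_cv_at_half(self, n, na, nb, data):
        """With M = 0.5 everywhere, no domain configuration can push CV above 0.5."""
        count = data.draw(st.integers(0, na * nb))
        cv_int = sum(0.5 for _ in range(n)) / n
        D = count / (na * nb)
        d = 0.5 if (na == 1 and nb == 1) else 1.0
        assert compute_cv(cv_int, d * D) <= 0.5


def scored_prediction(pair, cv, ddi_count=1):
    pred = PredictedInteraction(pair=pair, provenance=frozenset({witness()}))
    n = max(ddi_count, 1)
    ddi = DdiAssessment(ddi_count, n, n, ddi_count / (n * n), 1.0, cv * 2)
    pred.score = ScoreBreakdown(1, (("ath", 0.5),), 0.5, ddi, cv)
    return pred


def brute_force_tiers(cvs):
    """Independent O(n^2) percentile-rank and tier computation."""
    tiers = []
    for v in cvs:
        rank = 100.0 * sum(1 for u in cvs if u < v) / len(cvs)
        tiers.append("H1" if rank > 80 else ("H2" if rank >= 50 else "H3"))
    return tiers


class TestTierAssignment:
    def test_ten_distinct_cvs_against_percentile_oracle(self):
        preds = [scored_prediction((f"a{i}", f"b{i}"), cv) for i, cv in enumerate(
            [0.05 * (i + 1) for i in range(10)]
        )]
        assign_tiers(preds)
        assert [p.tier for p in preds] == brute_force_tiers([p.score.cv for p in preds])
        # strict-less rank on 10 distinct values: ranks 0,10,...,90
        assert [p.tier for p in preds] == ["H3"] * 5 + ["H2"] * 4 + ["H1"]

    def test_identical_cvs_share_a_tier(self):
        preds = [scored_prediction((f"a{i}", f"b{i}"), 0.2) for i in range(7)]
        assign_tiers(preds)
        assert len({p.tier for p in preds}) == 1

    def test_no_ddi_support_means_all_basal(self):
        preds = [scored_prediction((f"a{i}", f"b{i}"), 0.0, ddi_count=0) for i in range(4)]
        assign_tiers(preds)
        assert all(p.tier == "B" and p.percentile_rank is None for p in preds)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 0.5), min_size=1, max_size=40))
    def test_tie_cases_match_brute_force_oracle(self, cvs):
        cvs = [round(v, 2) for v in cvs]  # rounding forces ties
        preds = [scored_prediction((f"a{i}", f"b{i}"), v) for i, v in enumerate(cvs)]
        assign_tiers(preds)
        assert [p.tier for p in preds] == brute_force_tiers(cvs)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 0.5), min_size=2, max_size=30))
    def test_tier_monotone_in_cv(self, cvs):
        preds = [scored_prediction((f"a{i}", f"b{i}"), v) for i, v in enumerate(cvs)]
        assign_tiers(preds)
        order = {"H1": 1, "H2": 2, "H3": 3}
        for p1 in preds:
            for p2 in preds:
                if p1.score.cv > p2.score.cv:
                    assert order[p1.tier] <= order[p2.tier]

    def test_partition_of_all_edges(self):
        preds = [scored_prediction((f"a{i}", f"b{i}"), 0.1 * (i + 1)) for i in range(5)]
        preds += [scored_prediction((f"c{i}", f"d{i}"), 0.0, ddi_count=0) for i in range(3)]
        assign_tiers(preds)
        counts = {t: sum(p.tier == t for p in preds) for t in ("B", "H1", "H2", "H3")}
        assert sum(counts.values()) == len(preds)
        assert counts["B"] == 3

    def test_duplicating_every_h_edge_leaves_tiers_unchanged(self):
        cvs = [0.1, 0.2, 0.2, 0.3, 0.4]
        single = [scored_prediction((f"a{i}", f"b{i}"), v) for i, v in enumerate(cvs)]
        doubled = [
            scored_prediction((f"x{i}", f"y{i}"), v) for i, v in enumerate(cvs + cvs)
        ]
        assign_tiers(single)
        assign_tiers(doubled)
        assert [p.tier for p in doubled[: len(cvs)]] == [p.tier for p in single]
        assert [p.tier for p in doubled[len(cvs):]] == [p.tier for p in single]


def test_percentile_rank_definition():
    assert percentile_ranks([1.0, 2.0, 2.0, 3.0]) == [0.0, 25.0, 25.0, 75.0]
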