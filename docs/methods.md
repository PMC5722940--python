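# Methods

This note documents the model implemented by `interoppi`, its assumptions,
the parameters that matter, the synthetic data it is validated on, and the
design choices made where the procedure was genuinely open.

## Interolog transfer

The core assumption is evolutionary conservation of interactions: an
interacting protein pair in a template species implies an interaction
between the pair's orthologs in the target species. Orthology is
operationalized purely by alignment thresholds applied to BLASTp tabular
output — percent identity ≥ 60, query coverage ≥ 80 and e-value ≤ 10⁻¹⁰,
all boundaries inclusive. Three conventions are deliberate:

- **Coverage is computed over the query (template) protein**: 100 ×
  aligned query span / query length. This is the conventional reading when
  template proteomes are searched against a target genome and is the only
  definition computable from 12-column tabular output plus a length table.
  Subject-side coverage is not evaluated.
- **Orthology is one-way and many-to-many.** No reciprocal-best-hit step is
  applied, and each hit row (HSP) is tested independently; HSPs are not
  merged. A single template protein may admit several target paralogs and
  vice versa.
- **Transfer takes the full cross-product** of ortholog sets, not best
  hits only, so one template interaction may expand into several target
  pairs and several template interactions may collapse onto one. Predicted
  pairs are unordered (canonical lexicographic order everywhere) and
  self-pairs (shared orthologs → homodimers) are retained.

Provenance is conserved exactly: every surviving prediction records each
(species, evidence method, source database, template pair) witness, and N
is the number of distinct witness species. Template interactions with an
unmapped endpoint are skipped and counted in the run report, which is the
expected outcome for sparse ortholog maps, not an error.

## Confidence model

CV = CV_interolog × CV_DDI, with CV_interolog = Σᵢ Sᵢ Mᵢ / N over the N
supporting species. S is an ortholog-existence indicator that is always 1
inside the network (pairs without identified orthologs never enter), so
CV_interolog is the mean method-reliability weight: M = 1 for experimental
evidence, M = 0.5 for computational predictions. When one species supplies
both kinds of witness for the same pair, the experimental witness wins
(M = 1 for that species): an experimental measurement subsumes a
prediction of the same interaction. Consequently CV_interolog ∈ [0.5, 1],
and with computational-only evidence it is exactly 0.5, which caps the
final CV at 0.5 — the acceptance script verifies this bound by exhaustive
and randomized enumeration.

CV_DDI = d·D. D is the fraction of the n_a × n_b possible cross-domain
pairs that are catalogued domain–domain interactions; domain complements
are *sets* (repeat accessions collapse — D is defined on domain types, and
repeats would double-count support without new evidence), a rule matched
in both orientations counts once (so D ≤ 1), and a protein with no
annotated domain yields D = 0. The correction d = 0.5 applies when **both**
proteins carry exactly one domain; only then is D forced into {0, 1} and
the probability bias being compensated is maximal. The alternative reading
(either protein single-domain) is rejected but covered by a documented
unit test showing where the two differ (n_dom = (1, 2) → d = 1 here).

### Tiers

Edges with no matched DDI rule form the Basal (B) class: CV = 0 for them,
so the CV scale cannot rank them. DDI-supported edges form the High (H)
class and are ranked by percentile within the H population:
rank = 100 × (H edges with strictly smaller CV) / |H|, with H1 ⇔ rank >
80, H2 ⇔ 50 ≤ rank ≤ 80, H3 ⇔ rank < 50. The strict-less rank makes tied
CVs share one rank and hence one tier, so tiering is independent of input
order; it also means that on n distinct values the top edge alone carries
rank 100(n−1)/n. Ranks are computed on raw (unrounded) CVs.

## Expression validation

Presence lists assert a protein exists in the organism; matrix datasets
assert it for *highly expressed* genes only, defined as genes whose
summary expression (mean across samples by default; max is a config
option) lies strictly above the dataset's 80th percentile under linear
interpolation. A flat dataset therefore contributes nothing. An edge is
expression-supported iff both endpoints are in the union of these sets.

Co-expression uses the sample Pearson correlation with the two-sided
t-transform p-value (t = r√((n−2)/(1−r²)), df = n − 2; |r| = 1 maps to
p = 0). Thresholds are strict: r > 0.9 AND p < 0.1, satisfied in at least
one time-series dataset (OR across datasets — the pooled-evidence
convention). With 3–4 time points this test is deliberately underpowered,
mirroring the scale of real plant time courses; at n = 4 the independent-
profile correlation is uniform on [−1, 1], so the false-detection
probability of the joint gate is ≈ 0.05 per dataset, and the seeded
10,000-pair simulation in the test suite confirms a rate in (0, 0.1).
Zero-variance profiles make r undefined; such pairs are logged and treated
as not co-expressed rather than imputed.

Co-expressed pairs are grouped into connected components: 2 proteins →
heterodimeric; acyclic with maximum degree ≤ 2 → linear multimeric; any
cycle → circular multimeric. Acyclic components with a branch are reported
as linear with an explicit warning — chains and rings are the only
multimeric shapes modelled, and inventing a fourth class would not be
comparable with the three-group convention. Self-pairs are dropped before
grouping.

## Topology

- Degree: self-loops count once.
- γ: ordinary least squares of log₁₀ P(k) on log₁₀ k over k ≥ 1 with
  P(k) > 0, needing ≥ 3 support points; −slope is returned. OLS on log–log
  axes (rather than maximum likelihood) matches the visual-fit practice of
  GUI network tools and is exact on exact power-law histograms.
- L: mean shortest-path length over *connected* pairs of distinct nodes;
  unreachable pairs are excluded from numerator and denominator (not
  ∞-padded, not largest-component-only), which keeps L finite and defined
  for fragmented networks.
- C: mean local clustering with C_i = 0 for degree < 2 nodes included in
  the mean; self-loops excluded from neighbor sets.
- Random reference: uniform G(n, m) with exactly the same node and edge
  counts, seeded. The small-world report averages (L, C) over a configurable
  number of references (default 10) and judges L ≥ L_rand and
  C/C_rand > 2 (ratio threshold configurable).

## Synthetic worlds

The generator emulates what an aggregated-database interolog study sees,
not real biology:

- **Template networks** are preferential-attachment graphs drawn over a
  shared pool of gene families (default 400), one per species, with edge
  counts (500, 120, 30, 14, 8, 6, 4) across seven species — a log-spread
  chosen so a single data-rich species dominates, as real template
  collections do. Edges are labelled experimental with probability 0.3.
- **Orthology**: each family is conserved with probability 0.7; conserved
  families map to one target protein, plus a second paralog with
  probability 0.1 (exercising many-to-many transfer). Conserved template
  proteins get alignment hits sampled strictly inside the admission region;
  decoys are sampled to fail at least one threshold (which one(s) is drawn
  uniformly over the seven non-empty subsets). Query lengths are sampled
  once per template protein so the 12-column-plus-length-table file format
  stays consistent.
- **Domains/DDI**: 1–4 domains per protein with probabilities (0.45, 0.30,
  0.15, 0.10); 30 % of transferable pairs get one planted rule between a
  random domain of each side, plus decoy rules among unused accessions.
  The truth record recomputes every pair's ddi_count/D/d/CV by independent
  double-loop arithmetic over the full rule set, so accidental support is
  part of the truth, and score recovery can be asserted exactly (both
  sides perform the same closed-form arithmetic).
- **Expression**: two presence lists (inclusion probability 0.5) and two
  4-point time series. Planted co-expressed pairs (10 % of candidate
  pairs) share a latent cumulative-sum Gaussian profile; every protein's
  observed profile adds independent Gaussian noise (σ = 0.05 by default)
  and is shifted to be non-negative — Pearson correlation is invariant to
  the shift. As σ → 0 planted pairs reach PCC = 1 exactly.

What passing tests on these worlds shows: the pipeline recovers planted
structure perfectly when the signal is noiseless and thresholds are met by
construction, and every score agrees with closed-form expectation. What it
does not show: robustness to real-data pathologies — isoform identifier
mismatches, partial-domain architectures, normalization artefacts,
correlated noise across profiles — none of which the generator models.

## Problem sizes and determinism

Default worlds carry ~680 template edges and a few hundred predicted
pairs; the many-world sweeps in the test suite use ~100-edge worlds, and
topology oracles run on graphs of ≤ 60 nodes, sizes at which brute-force
oracles (nested-loop transfer, O(n²) percentile ranks, all-pairs BFS,
triangle enumeration) are exact and fast. All randomness flows from a
single integer seed through `numpy.random.default_rng`; identical
(config, seed) pairs produce byte-identical world files, and the pipeline
run report contains no timestamps, so reruns are reproducible.

## Known limitations

- Evidence labelling of real source databases (experimental vs
  computational) must be supplied by the user (e.g. via the MITAB
  detection-method map); no ontology resolution is performed.
- Identifiers are opaque tokens; isoform collapsing, if desired, must
  happen upstream.
- The percentile tier boundaries are relative to each network's CV
  distribution; absolute CV ranges of tiers are data-dependent by design.
- The power-law fit is a descriptive regression, not a goodness-of-fit
  test; it will happily return an exponent for non-power-law histograms
  with ≥ 3 support points.
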