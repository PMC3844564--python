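# Methods

## Problem and data model

The unit of analysis is one edge of an undirected simple interactome.
Input is three tables: interactions (protein pair plus the PMIDs of the
papers reporting it; optionally PSI-MI TAB 2.5 restricted to binary
physical interactions, MI:0407), publications (PMID, year) and citations
(cited PMID, citing PMID, citing year, optional self-reference flag).
Homodimer rows are removed before anything else — every centrality used
here assumes a simple graph — and duplicate unordered pairs are merged,
pooling their PMIDs. The self-reference flag is consumed from the input
and never inferred; self-references are *included* in citation counts by
default, matching how reference totals are usually reported.

An interaction is labeled high-impact (y = 1) when its reporting paper
received at least *t* citations within the 5-year window following
publication. The window is interpreted as the five calendar years
[pub_year, pub_year + 4]; data carry years, not dates, so finer
granularity is not meaningful. Only interactions in one-to-one relation
with a paper are labeled, and interactions published later than
study_year − window are excluded because their window is still open. The
accounting identity (labeled + too-recent + non-one-to-one = all edges) is
enforced. Excluded edges still contribute to centralities and still
receive predictions.

## Centrality conventions

All measures are computed on the *entire* network, not the labeled subset.

| measure | convention |
|---|---|
| degree | deg(v)/(n−1) |
| clustering | 2·T(v)/(deg(v)(deg(v)−1)), 0 when deg < 2 |
| closeness | component-scaled (Wasserman–Faust): (r/(n−1))·(r/Σd); finite on disconnected graphs |
| node betweenness | Brandes accumulation, unordered pairs, endpoints excluded, unnormalized |
| edge betweenness | Brandes edge variant, unordered pairs, unnormalized |
| eigenvector | non-negative principal adjacency eigenvector, unit L2 norm |
| Burt constraint | Σ_j (p_ij + Σ_q p_iq p_qj)², p_ij = 1/deg(i); isolated nodes 0 |
| PageRank | uniform teleport, damping 0.85 (configurable), sums to 1 |
| HITS hub | identical to the eigenvector on an undirected graph (hub = authority) |

Betweenness is left unnormalized deliberately: the values feed a forest
classifier, which is invariant to monotone rescaling, and raw values keep
the conservation identity Σ_e eb(e) = Σ_{s<t} d(s,t) available as a test
invariant. Eigenvector/hub centrality is computed by power iteration on
A + I from a uniform positive start: the identity shift makes the
iteration convergent on bipartite components (where plain power iteration
oscillates between the ±λ eigenpair) without changing the Perron vector.
Convergence is declared when the successive-iterate L1 change drops below
`tol` (default 1e-8, max 1000 iterations); non-convergence raises an error
naming the measure. On disconnected graphs the iteration concentrates mass
on the spectrally dominant component and other components legitimately go
to ~0. Tests back every shortest-path-based measure with a from-scratch
oracle that enumerates all shortest paths explicitly (n ≤ 10).

## Features, model, evaluation

Each edge gets 17 features: per-measure maxima of the two endpoint
centralities (order: degree, closeness, betweenness, eigenvector,
constraint, clustering, pagerank, hub), per-measure minima in the same
order, then edge betweenness. Max/min symmetrization makes the vector
independent of endpoint order; the fixed ordering keeps importance plots
comparable across runs.

The classifier is a random forest: 100 trees, √17 features per split, no
depth limit, probability voting, deterministic given its seed. These are
unremarkable defaults for a 17-feature tabular problem; they are exposed
in `CVConfig`.

Evaluation is per-fold precision–recall. The PR curve ranks instances by
score descending with ties kept in stable input order, emits one
(recall, precision) point per distinct score threshold, and prepends an
anchor (0, precision of the top-1 prefix); AUPR is the trapezoidal
integral over recall. R50 applies the same construction to the ranked
prefix ending just before the 51st negative, keeps the full-set recall
denominator and is not renormalized — hence R50 ≤ AUPR always, with
equality when a fold has ≤ 50 negatives. These conventions are fixed
because partial-PR definitions vary across libraries and the absolute
numbers are convention-sensitive, particularly for a random scorer at
extreme class skew: with the precision-1 anchor some toolkits use, a
random ranking gains a large spurious first-segment area when positives
are rare. Numbers produced here are stable under the stated convention but
not comparable across conventions.

Cross-validation is stratified 10-fold with 20 random repeats (both
configurable); stratification matters because at high thresholds fewer
than 100 positives may exist and unstratified folds can lack positives
entirely, leaving the PR curve undefined. Within a repeat the forest and
the uniform-random baseline are evaluated on identical partitions, so
per-(repeat, fold) AUPRs are paired; the comparison is a two-sided
Wilcoxon signed-rank test with zero differences dropped (p = 1 with a
warning if all differences vanish). Metrics are averaged per fold rather
than pooled: per-fold averaging reproduces the well-known upward drift of
random-baseline AUPR as positives-per-fold shrink, which pooling hides.
Gini (mean-decrease-in-impurity) importances come from a forest trained on
the full labeled set.

For whole-interactome ranking, a final forest is trained on the complete
one-to-one labeled set and applied to every edge; ties are broken by
canonical (lexicographic) edge name so rankings are byte-stable.

## Synthetic studies

The generator emulates the structure of a curated interactome study, not
any particular organism's parameters:

* **topology** — preferential attachment: a star seed on m + 1 nodes, then
  each new node attaches m edges preferentially; m(n − m) edges in total.
  Defaults n = 2000, m = 3 give a ~6000-edge scale-free network, large
  enough for stable cross-validation yet cheap enough that exact
  centralities take well under a minute.
* **curation** — each edge is reported by one synthetic paper; 10% of
  papers (default) absorb 2–4 edges, exercising the one-to-one filter the
  way multi-interaction papers do in real curation.
* **citations** — per edge, η = β0 + β·z with z the column-standardized
  17-d features (standardization makes coefficients comparable across
  measures with wildly different scales); the 5-year count is negative
  binomial with mean exp(η) and dispersion 2 (citation counts are
  overdispersed; Poisson would understate heavy tails). η is clipped to
  [−10, 7] because centrality features are themselves heavy-tailed and an
  unbounded log link would assign hub edges millions of citations; the cap
  (~1100 expected citations in 5 years) exceeds any real paper while
  keeping the signal monotone. Citation years are uniform over the window;
  publication years uniform over 1995–2006 with study year 2011, so
  default runs have no too-recent exclusions unless configured otherwise;
  14% of citations are flagged as self-references, a realistic share.
* **ground truth** — η, exp(η) and realized counts are stored alongside
  the generated tables so tests never re-derive the truth from the
  pipeline under test. β = 0 yields labels independent of topology, an
  exact null whose positive rate has a closed form used as a test.
* **robustness** — an edge-subsampling fraction models incomplete
  interactome knowledge; recovery degrades as sampling gets sparser.

What the generator does *not* emulate: real degree/citation distributions
of any database snapshot, the late second citation peak seen in real
citation histories, or any biological annotation. Passing tests therefore
demonstrate that the pipeline detects (and, under the null, does not
invent) a topology→impact dependence — not that topology predicts impact
in any particular real interactome.

## Problem sizes and determinism

The planted-recovery checks run on the default 2000-node study with
2 repeats of 10-fold cross-validation (20 paired folds; the signed-rank
test can resolve p ≈ 2e-6 at that size, far beyond the p < 0.01 question
being asked). The random-baseline reproduction uses the full 20 repeats,
which is cheap because no model is trained. All randomness flows from
explicit seeds; pipeline stages derive their seeds from one base seed via
`numpy.random.SeedSequence([base, stage_index])`, so partial reruns stay
consistent and identical configs reproduce artifacts byte-identically.

## Known limitations

* Weighted or directed interactomes are out of scope; exact betweenness is
  O(nm) and the package offers no approximate variant for very large graphs.
* Calendar-year citation windows cannot distinguish a paper published in
  January from one published in December.
* Whether self-references should count toward impact labels is a judgment
  call; they are included by default and the flag is carried through so a
  caller can filter them out before labeling.
* The absolute AUPR/R50 of a random baseline at extreme skew depends on
  the PR conventions above; only the fixed-convention numbers are
  meaningful.
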