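# ppi-impact

Predicting the future biomedical impact of protein–protein interactions
(PPIs) from interactome topology alone.

When a new interaction is reported, which ones will the community build on?
`ppi-impact` frames this as edge classification on the interactome: an
interaction is *high-impact* if the paper that first reported it received at
least *t* citations within the 5-year window following publication. The
package builds the interaction network from curated tables, computes eight
node centralities (degree, closeness, betweenness, eigenvector, Burt
constraint, clustering coefficient, PageRank, HITS hub) plus Brandes edge
betweenness, represents each interaction (a, b) by a symmetrized 17-feature
vector

```
x1..x8  = per-measure max( c(a), c(b) )
x9..x16 = per-measure min( c(a), c(b) )
x17     = edge betweenness of a–b
```

and trains a random forest on the subset of interactions with a one-to-one
relation to a paper (the paper reports only that interaction, and the
interaction appears in no other paper — the only edges whose citation count
is unambiguous). Because high-impact edges are rare at large *t*, evaluation
uses precision–recall: AUPR and R50 (partial AUPR up to the 50th retrieved
negative), averaged per fold over 20 repeats of stratified 10-fold
cross-validation, against a Uniform(0, 1) random-scoring baseline, with a
paired Wilcoxon signed-rank test. The final model scores *every* edge of the
interactome, one-to-one or not.

A synthetic-study generator produces scale-free interactomes with per-paper
citation histories whose 5-year counts depend on edge topology through a
planted coefficient vector, so the whole pipeline is testable end to end
without any database access.

## Worked example

Plant a citation signal on edge betweenness and degree, then ask the
pipeline to find it:

```python
import numpy as np
from ppi_impact import (CVConfig, SyntheticConfig, build_labeled_dataset,
                        centrality_table, cross_validate)
from ppi_impact.synthetic import generate_network, plant_citation_process
from ppi_impact.dataset import FEATURE_NAMES

beta = [0.0] * 17
beta[16], beta[0] = 1.5, 1.0          # signal on edge betweenness + max degree
cfg = SyntheticConfig(n_nodes=600, m=3, seed=42, beta=tuple(beta), beta0=1.0)
network = generate_network(cfg)
table = centrality_table(network)
study = plant_citation_process(network, table, cfg)
ds = build_labeled_dataset(network, table, study.papers, study.citations,
                           threshold=5, study_year=2011)
print(f"labeled interactions: {ds.n} ({ds.n_positive} high-impact)")
res = cross_validate(ds.X, ds.y, CVConfig(folds=10, repeats=2, seed=0))
print(f"forest AUPR {res.mean_aupr['forest']:.3f}  R50 {res.mean_r50['forest']:.3f}")
print(f"random AUPR {res.mean_aupr['random']:.3f}  R50 {res.mean_r50['random']:.3f}")
print(f"Wilcoxon p = {res.p_value:.2e}")
top = np.argsort(-res.importances)[:3]
print("top features:", [(FEATURE_NAMES[i], round(float(res.importances[i]), 3)) for i in top])
```

Output:

```
labeled interactions: 1332 (363 high-impact)
forest AUPR 0.943  R50 0.942
random AUPR 0.278  R50 0.144
Wilcoxon p = 1.91e-06
top features: [('edge_betweenness', 0.259), ('max_degree', 0.118), ('max_betweenness', 0.098)]
```

The forest recovers the planted topology dependence (AUPR 0.94 against a
0.28 baseline, which sits at the positive-class prevalence), and the Gini
importances point back at the planted features. With `beta = 0` the two
methods are statistically indistinguishable.

The same flow is available from a shell:

```
ppi-impact simulate --n-nodes 2000 --m 3 --seed 1 --out-dir study/
ppi-impact build-network --interactions study/interactions.tsv --out network.json
ppi-impact centrality --network network.json --out centrality.tsv
ppi-impact make-dataset --network network.json --papers study/publications.tsv \
    --citations study/citations.tsv --threshold 5 --study-year 2011 --out dataset.tsv
ppi-impact evaluate --dataset dataset.tsv --out eval.json
ppi-impact rank --network network.json --dataset dataset.tsv --top 100 --out ranked.tsv
```

or as one reproducible run: `ppi-impact run --config config.json`.

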