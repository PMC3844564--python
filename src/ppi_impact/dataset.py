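"""Labeled training data: citation-window impact labels and 17-d edge features.

Only interactions with a one-to-one relation to a paper (the paper reports
exactly that interaction, and the interaction is reported by exactly that
paper) have an unambiguous citation count, so only those become labeled
samples.  Every edge of the interactome still contributes to the
centralities and still receives a prediction later.

A feature vector has 17 entries: per-measure maxima of the two endpoint
node centralities (x1..x8, in the order degree, closeness, betweenness,
eigenvector, constraint, clustering, pagerank, hub), the per-measure
minima in the same order (x9..x16), and edge betweenness (x17).  Max/min
ordering makes the vector invariant under endpoint swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .centrality import NODE_MEASURES, CentralityTable
from .graph_io import CitationRecord, Edge, InteractionNetwork, PublicationRecord

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"max_{m}" for m in NODE_MEASURES)
    + tuple(f"min_{m}" for m in NODE_MEASURES)
    + ("edge_betweenness",)
)

N_FEATURES = len(FEATURE_NAMES)  # 17


@dataclass(frozen=True)
class ImpactLabel:
    """Binary high-impact label from a 5-year-window citation count."""

    citation_count_5y: int
    threshold: int

    @property
    def y(self) -> int:
        return int(self.citation_count_5y >= self.threshold)


@dataclass
class LabeledDataset:
    """Per-edge features and impact labels sharing a single threshold."""

    edges: list[Edge]
    pmids: list[str]  # reporting paper per edge (the one-to-one map)
    X: np.ndarray  # (n, 17)
    counts: np.ndarray  # 5-year citation counts, (n,)
    y: np.ndarray  # binary labels, (n,)
    threshold: int
    window: int = 5
    n_excluded_recent: int = 0
    n_excluded_not_one_to_one: int = 0

    def __post_init__(self) -> None:
        n = len(self.edges)
        if not (len(self.pmids) == self.X.shape[0] == len(self.counts) == len(self.y) == n):
            raise ValueError("inconsistent dataset field lengths")
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must have {N_FEATURES} columns")

    @property
    def n(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n - self.y.sum())

    @property
    def positive_fraction(self) -> float:
        """n_positive / n_total rounded to three decimals (table convention)."""
        return class_balance(self.y)


def class_balance(y: Sequence[int] | np.ndarray) -> float:
    """Positive fraction n_positive / n_total, rounded to three decimals."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    return round(float(y.sum()) / y.size, 3)


def citations_in_window(
    pub_year: int, citing_years: Iterable[int], window: int = 5
) -> int:
    """Citations received in the ``window`` calendar years starting at
    publication, i.e. years in [pub_year, pub_year + window - 1]."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    count = 0
    n_before = 0
    for year in citing_years:
        if year < pub_year:
            n_before += 1
            continue
        if year <= pub_year + window - 1:
            count += 1
    if n_before:
        logger.warning(
            "ignored %d citation(s) dated before publication year %d", n_before, pub_year
        )
    return count


def one_to_one_subset(network: InteractionNetwork) -> dict[Edge, str]:
    """Bijection between edges and papers: edges with exactly one reporting
    paper whose paper reports no other edge."""
    mapping: dict[Edge, str] = {}
    for edge in network.edges:
        pmids = network.edge_pmids(edge)
        if len(pmids) != 1:
            continue
        (pmid,) = pmids
        if network.provenance.get(pmid) == {edge}:
            mapping[edge] = pmid
    if not mapping:
        logger.warning("one-to-one subset is empty")
    return mapping


def symmetrized_features(
    centrality_a: np.ndarray, centrality_b: np.ndarray, edge_b: float
) -> np.ndarray:
    """17-d feature vector: per-measure max, per-measure min, edge betweenness."""
    a = np.asarray(centrality_a, dtype=float)
    b = np.asarray(centrality_b, dtype=float)
    if a.shape != (8,) or b.shape != (8,):
        raise ValueError("endpoint centrality vectors must have 8 entries")
    if not (np.isfinite(a).all() and np.isfinite(b).all() and np.isfinite(edge_b)):
        raise ValueError("non-finite centrality input")
    return np.concatenate([np.maximum(a, b), np.minimum(a, b), [float(edge_b)]])


def features_for_edge(centralities: CentralityTable, edge: Edge) -> np.ndarray:
    """Feature vector of one edge from a full-network centrality table."""
    a, b = edge
    eb_map = centralities.edges.to_dict()
    if edge not in eb_map:
        raise KeyError(f"edge {edge} missing from centrality table")
    return symmetrized_features(
        centralities.node_vector(a), centralities.node_vector(b), float(eb_map[edge])
    )


def feature_matrix(
    centralities: CentralityTable, edges: Sequence[Edge]
) -> np.ndarray:
    """(n_edges, 17) feature matrix in the given edge order."""
    node_arr = centralities.nodes.to_numpy(dtype=float)
    index = {v: i for i, v in enumerate(centralities.nodes.index)}
    eb_map = centralities.edges.to_dict()
    out = np.empty((len(edges), N_FEATURES))
    for i, (a, b) in enumerate(edges):
        if (a, b) not in eb_map:
            raise KeyError(f"edge {(a, b)} missing from centrality table")
        va, vb = node_arr[index[a]], node_arr[index[b]]
        out[i, :8] = np.maximum(va, vb)
        out[i, 8:16] = np.minimum(va, vb)
        out[i, 16] = eb_map[(a, b)]
    if not np.isfinite(out).all():
        raise ValueError("non-finite centrality input")
    return out


def build_labeled_dataset(
    network: InteractionNetwork,
    centralities: CentralityTable,
    papers: Sequence[PublicationRecord],
    citations: Sequence[CitationRecord],
    threshold: int,
    study_year: int,
    window: int = 5,
) -> LabeledDataset:
    """Label the one-to-one subset by thresholded citation counts.

    Edges whose reporting paper appeared later than ``study_year - window``
    are excluded: their citation window has not fully elapsed.  Features are
    taken from the full-network centrality table, never recomputed on the
    subset.
    """
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    one_to_one = one_to_one_subset(network)
    if not one_to_one:
        raise ValueError("one-to-one subset is empty; nothing to label")

    year_of: Mapping[str, int] = {p.pmid: p.year for p in papers}
    missing = sorted({p for p in one_to_one.values() if p not in year_of})
    if missing:
        raise ValueError(f"publication year missing for PMID(s): {missing[:10]}")
    used_years = [year_of[p] for p in one_to_one.values()]
    if study_year < max(used_years):
        raise ValueError("study_year precedes the latest publication year in use")

    citing_years: dict[str, list[int]] = {}
    for c in citations:
        citing_years.setdefault(c.cited_pmid, []).append(c.citing_year)

    kept_edges: list[Edge] = []
    kept_pmids: list[str] = []
    counts: list[int] = []
    n_recent = 0
    for edge in sorted(one_to_one):
        pmid = one_to_one[edge]
        if year_of[pmid] > study_year - window:
            n_recent += 1
            continue
        kept_edges.append(edge)
        kept_pmids.append(pmid)
        counts.append(
            citations_in_window(year_of[pmid], citing_years.get(pmid, ()), window)
        )

    if not kept_edges:
        raise ValueError("all one-to-one edges are too recent for the citation window")
    counts_arr = np.asarray(counts, dtype=int)
    dataset = LabeledDataset(
        edges=kept_edges,
        pmids=kept_pmids,
        X=feature_matrix(centralities, kept_edges),
        counts=counts_arr,
        y=(counts_arr >= threshold).astype(int),
        threshold=threshold,
        window=window,
        n_excluded_recent=n_recent,
        n_excluded_not_one_to_one=len(network.edges) - len(one_to_one),
    )
    logger.info(
        "labeled dataset: n=%d (%d positive / %d negative at t=%d), "
        "excluded %d recent and %d non-one-to-one edge(s)",
        dataset.n,
        dataset.n_positive,
        dataset.n_negative,
        threshold,
        n_recent,
        dataset.n_excluded_not_one_to_one,
    )
    return dataset
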