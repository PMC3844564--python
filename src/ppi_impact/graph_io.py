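"""Reading and writing interactome tables.

Interactions arrive either as a plain three-column TSV
(``protein_a``, ``protein_b``, ``pmids`` with semicolon-separated PubMed
identifiers) or as a minimal PSI-MI TAB 2.5 file, from which only binary
physical interactions (interaction type containing ``MI:0407``) are kept.
The interactome itself is an undirected simple graph; homodimer rows
(self-loops) are removed up front because every centrality measure used
downstream assumes a simple graph.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

#: PSI-MI controlled-vocabulary term for a direct (binary physical) interaction.
BINARY_INTERACTION_MI = "MI:0407"

_MITAB_PMID_COLUMN = 8  # column 9, 1-based: publication identifiers
_MITAB_TYPE_COLUMN = 11  # column 12, 1-based: interaction type


def canonical_edge(a: str, b: str) -> Edge:
    """Unordered protein pair in canonical (lexicographically sorted) form."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionEdge:
    """A binary PPI with the publications that report it.

    The pair is unordered: endpoints are stored lexicographically sorted.
    """

    protein_a: str
    protein_b: str
    pmids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction {self.protein_a!r} is not a valid edge")
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)
        object.__setattr__(self, "pmids", frozenset(self.pmids))

    @property
    def key(self) -> Edge:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class PublicationRecord:
    """A paper identified by PMID with its calendar year of publication."""

    pmid: str
    year: int

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= date.today().year:
            raise ValueError(f"publication year {self.year} out of range for {self.pmid}")


@dataclass(frozen=True)
class CitationRecord:
    """One citation event: ``citing_pmid`` (in ``citing_year``) cites ``cited_pmid``."""

    cited_pmid: str
    citing_pmid: str
    citing_year: int
    is_self: bool = False

    def __post_init__(self) -> None:
        if self.cited_pmid == self.citing_pmid:
            raise ValueError(f"paper {self.cited_pmid} cannot cite itself")


@dataclass
class InteractionNetwork:
    """Undirected simple interactome with per-edge publication provenance.

    ``graph`` holds the topology; each edge carries a ``pmids`` frozenset
    attribute.  ``provenance`` is the exact inverse index
    (PMID -> set of canonical edges that PMID reports).
    """

    graph: nx.Graph
    provenance: dict[str, set[Edge]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[Edge]:
        return sorted(canonical_edge(a, b) for a, b in self.graph.edges)

    def edge_pmids(self, edge: Edge) -> frozenset[str]:
        return self.graph.edges[edge]["pmids"]

    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


@dataclass(frozen=True)
class ReferenceSummary:
    total_references: int
    self_references: int
    self_reference_pct: float


def read_interactions_table(path: str | Path, dialect: str = "tsv") -> list[InteractionEdge]:
    """Parse an interaction table into deduplicated, self-loop-free edges.

    ``dialect`` is ``"tsv"`` (header row ``protein_a``, ``protein_b``,
    ``pmids``; PMIDs semicolon-separated) or ``"psi_mitab_2_5"`` (15+
    tab-separated columns, no header; only rows whose interaction-type
    column contains MI:0407 are kept).  Duplicate unordered pairs are
    merged, pooling their PMIDs; self-pairs are dropped with a logged count.
    """
    path = Path(path)
    if dialect == "tsv":
        rows = _read_tsv_rows(path)
    elif dialect in ("psi_mitab_2_5", "psi-mitab", "psi_mitab"):
        rows = _read_mitab_rows(path)
    else:
        raise ValueError(f"unknown interaction dialect {dialect!r}")

    merged: dict[Edge, set[str]] = {}
    n_self = 0
    for a, b, pmids in rows:
        if a == b:
            n_self += 1
            continue
        merged.setdefault(canonical_edge(a, b), set()).update(pmids)
    if n_self:
        logger.info("dropped %d self-interaction row(s)", n_self)
    return [
        InteractionEdge(a, b, frozenset(pmids))
        for (a, b), pmids in sorted(merged.items())
    ]


def _read_tsv_rows(path: Path) -> Iterable[tuple[str, str, set[str]]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_a", "protein_b", "pmids"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            a = (row.get("protein_a") or "").strip()
            b = (row.get("protein_b") or "").strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: missing protein identifier")
            pmids = {p.strip() for p in (row.get("pmids") or "").split(";") if p.strip()}
            yield a, b, pmids


def _read_mitab_rows(path: Path) -> Iterable[tuple[str, str, set[str]]]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise ValueError(
                    f"{path}:{lineno}: PSI-MI TAB 2.5 needs >=15 columns, got {len(cols)}"
                )
            if BINARY_INTERACTION_MI not in cols[_MITAB_TYPE_COLUMN]:
                continue
            a = _strip_mitab_prefix(cols[0])
            b = _strip_mitab_prefix(cols[1])
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: missing interactor identifier")
            pmids = {
                field.split(":", 1)[1]
                for field in cols[_MITAB_PMID_COLUMN].split("|")
                if field.lower().startswith("pubmed:")
            }
            yield a, b, pmids


def _strip_mitab_prefix(value: str) -> str:
    value = value.strip()
    return value.split(":", 1)[1] if ":" in value else value


def build_network(edges: Sequence[InteractionEdge]) -> InteractionNetwork:
    """Assemble the interactome graph and its PMID provenance index."""
    if not edges:
        raise ValueError("cannot build a network from an empty edge list")
    g = nx.Graph()
    provenance: dict[str, set[Edge]] = {}
    for e in edges:
        g.add_edge(e.protein_a, e.protein_b, pmids=e.pmids)
        for pmid in e.pmids:
            provenance.setdefault(pmid, set()).add(e.key)
    net = InteractionNetwork(graph=g, provenance=provenance)
    logger.info(
        "network: %d nodes, %d edges, %d connected component(s)",
        g.number_of_nodes(),
        g.number_of_edges(),
        net.n_components(),
    )
    return net


def read_publications_table(path: str | Path) -> list[PublicationRecord]:
    """TSV with columns ``pmid``, ``year``; PMIDs must be unique."""
    path = Path(path)
    records: list[PublicationRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                pmid = row["pmid"].strip()
                year = int(row["year"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed publication row") from exc
            if pmid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pmid {pmid}")
            seen.add(pmid)
            records.append(PublicationRecord(pmid, year))
    return records


def read_citations_table(path: str | Path) -> list[CitationRecord]:
    """TSV with columns ``cited_pmid``, ``citing_pmid``, ``citing_year`` and
    an optional ``is_self`` column (values 0/1 or true/false)."""
    path = Path(path)
    records: list[CitationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                cited = row["cited_pmid"].strip()
                citing = row["citing_pmid"].strip()
                year = int(row["citing_year"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed citation row") from exc
            raw_self = (row.get("is_self") or "0").strip().lower()
            records.append(
                CitationRecord(cited, citing, year, raw_self in ("1", "true", "yes"))
            )
    return records


def reference_summary(
    citations: Sequence[CitationRecord], papers: Sequence[PublicationRecord]
) -> ReferenceSummary:
    """Total and self-reference counts over the papers of a study.

    The percentage is 100 * self / total, rounded to two decimals.  The
    self-reference flag is taken from the input, never inferred.
    """
    known = {p.pmid for p in papers}
    missing = {c.cited_pmid for c in citations} - known
    if missing:
        raise ValueError(
            f"{len(missing)} cited PMID(s) absent from the publication table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    total = len(citations)
    if total == 0:
        raise ValueError("no citations: reference summary undefined")
    n_self = sum(c.is_self for c in citations)
    return ReferenceSummary(total, n_self, round(100.0 * n_self / total, 2))


def write_ranked_edges(
    ranking: Sequence[tuple[Edge, float]],
    path: str | Path,
    network: InteractionNetwork | None = None,
) -> None:
    """Write a ranked edge list as TSV (rank, protein_a, protein_b, score, pmids).

    Scores must lie in [0, 1] and be non-increasing; ties are ordered by
    canonical edge name so output is byte-stable.
    """
    scores = [s for _, s in ranking]
    for s in scores:
        if not (0.0 <= s <= 1.0) or not math.isfinite(s):
            raise ValueError(f"score {s} outside [0, 1]")
    if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
        raise ValueError("ranking is not sorted by descending score")
    rows = sorted(ranking, key=lambda item: (-item[1], item[0]))
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "protein_a", "protein_b", "score", "pmids"])
        for rank, (edge, score) in enumerate(rows, start=1):
            pmids = ""
            if network is not None and network.graph.has_edge(*edge):
                pmids = ";".join(sorted(network.edge_pmids(edge)))
            writer.writerow([rank, edge[0], edge[1], repr(float(score)), pmids])


def read_ranked_edges(path: str | Path) -> list[tuple[Edge, float]]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            (canonical_edge(row["protein_a"], row["protein_b"]), float(row["score"]))
            for row in reader
        ]


def write_network_json(network: InteractionNetwork, path: str | Path) -> None:
    payload = {
        "nodes": network.nodes,
        "edges": [
            {"a": a, "b": b, "pmids": sorted(network.edge_pmids((a, b)))}
            for a, b in network.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_network_json(path: str | Path) -> InteractionNetwork:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    edges = [
        InteractionEdge(e["a"], e["b"], frozenset(e["pmids"])) for e in payload["edges"]
    ]
    net = build_network(edges)
    net.graph.add_nodes_from(payload["nodes"])  # keep isolated nodes
    return net
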