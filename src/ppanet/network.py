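"""Candidate interaction edges and the rough association network.

Edge lists emulate tab-delimited exports from interaction databases:
two-column symbol pairs (BioGRID-like) or three-column rows with a combined
confidence score in [0, 1] (STRING-like).  Candidate edges from all sources
are merged and induced on the protein pool to form the *rough* association
network — every association the databases consider possible, prior to any
dynamic-model pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .pool import ProteinPool, normalize_symbol

logger = logging.getLogger(__name__)

BIOGRID_LIKE = "BIOGRID_LIKE"
STRING_LIKE = "STRING_LIKE"

#: Default STRING combined-score cut-off ("medium confidence" convention).
DEFAULT_MIN_SCORE = 0.4


def _pair(a: str, b: str) -> tuple[str, str]:
    """Normalise an edge to an unordered (sorted) symbol pair."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class CandidateEdgeSet:
    """Unordered symbol pairs with per-edge provenance and optional score."""

    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add(self, a: str, b: str, source: str, score: float | None = None) -> bool:
        """Add one edge; self-pairs are rejected. Returns True if stored."""
        key = _pair(a, b)
        if key[0] == key[1]:
            return False
        rec = self.edges.setdefault(key, {"provenance": set(), "score": None})
        rec["provenance"].add(source)
        if score is not None:
            prev = rec["score"]
            rec["score"] = score if prev is None else max(prev, score)
        return True

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _pair(*pair) in self.edges

    def __iter__(self):
        return iter(self.edges)


def parse_edge_list(
    records: str,
    source_tag: str = BIOGRID_LIKE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> CandidateEdgeSet:
    """Parse tab-delimited interaction rows into a :class:`CandidateEdgeSet`.

    Parameters
    ----------
    records : str
        Text with one interaction per line.  ``#`` comment lines are
        ignored.  BioGRID-like rows carry two symbol columns; STRING-like
        rows carry a third numeric combined-score column.
    source_tag : str
        Provenance label, ``BIOGRID_LIKE`` or ``STRING_LIKE``.
    min_score : float
        Combined-score threshold applied to STRING-like rows only.

    Malformed rows are skipped with a logged warning and counted; a
    non-numeric score on a STRING-like row rejects that row.
    """
    if source_tag not in (BIOGRID_LIKE, STRING_LIKE):
        raise ValueError(f"unknown source tag {source_tag!r}")
    out = CandidateEdgeSet()
    skipped = 0
    for lineno, line in enumerate(records.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            skipped += 1
            logger.warning("skipping malformed row %d: %r", lineno, line)
            continue
        a, b = fields[0], fields[1]
        score: float | None = None
        if source_tag == STRING_LIKE:
            if len(fields) < 3:
                skipped += 1
                logger.warning("STRING-like row %d lacks a score: %r", lineno, line)
                continue
            try:
                score = float(fields[2])
            except ValueError:
                skipped += 1
                logger.warning("non-numeric score on row %d: %r", lineno, line)
                continue
            if score < min_score:
                continue
        out.add(a, b, source_tag, score)
    if skipped:
        logger.warning("%d malformed rows skipped", skipped)
    return out


def read_edge_list(
    path: str | Path,
    source_tag: str = BIOGRID_LIKE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> CandidateEdgeSet:
    return parse_edge_list(
        Path(path).read_text(encoding="utf-8"), source_tag, min_score
    )


@dataclass
class RoughPPAN:
    """Candidate association network induced on the protein pool.

    Undirected: databases record associations, not regulation direction.
    ``Q(node)`` — the candidate-neighbourhood size entering the dynamic
    model — is simply the node degree here.
    """

    graph: nx.Graph
    excluded_edges: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighborhood(self, symbol: str) -> list[str]:
        """Candidate interactors of ``symbol`` (the Q proteins)."""
        return sorted(self.graph.neighbors(normalize_symbol(symbol)))

    def q(self, symbol: str) -> int:
        return self.graph.degree(normalize_symbol(symbol))


def assemble_rough_ppan(
    pool: ProteinPool, sources: list[CandidateEdgeSet]
) -> RoughPPAN:
    """Merge candidate edge sets and induce them on the pool.

    Edges with an endpoint outside the pool are excluded (counted and
    logged); duplicate edges across sources are merged with provenance
    unioned.  Every pool symbol becomes a node even if isolated.
    """
    if len(pool) == 0:
        raise ValueError("protein pool is empty")
    g = nx.Graph()
    g.add_nodes_from(pool.symbols)
    members = set(pool.symbols)
    excluded = 0
    for src in sources:
        for (a, b), rec in src.edges.items():
            if a not in members or b not in members:
                excluded += 1
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["provenance"] |= rec["provenance"]
                if rec["score"] is not None:
                    prev = g.edges[a, b].get("score")
                    g.edges[a, b]["score"] = (
                        rec["score"] if prev is None else max(prev, rec["score"])
                    )
            else:
                g.add_edge(
                    a, b, provenance=set(rec["provenance"]), score=rec["score"]
                )
    if excluded:
        logger.info("%d candidate edges outside the pool excluded", excluded)
    return RoughPPAN(graph=g, excluded_edges=excluded)


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write an undirected graph in Cytoscape SIF form (``A pp B``)."""
    with open(path, "w", encoding="utf-8") as fh:
        written = set()
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
            written.update((a, b))
        for node in sorted(set(graph.nodes) - written):
            fh.write(f"{node}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write GraphML; set-valued attributes are serialised as sorted CSV."""
    g = graph.copy()
    for *_, data in g.edges(data=True):
        if isinstance(data.get("provenance"), set):
            data["provenance"] = ",".join(sorted(data["provenance"]))
        if data.get("score") is None:
            data.pop("score", None)
    nx.write_graphml(g, str(path))
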