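"""Protein interaction networks and pathway-defined subnetworks.

An :class:`InteractionNetwork` is an undirected networkx graph whose edges
carry a STRING-style combined confidence score on the native 0-1000 integer
scale.  Nodes may carry analysis attributes (differential-expression effect,
significance flag, pathway and top-level labels) that are preserved through
subnetwork extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import ValidationError


@dataclass
class InteractionNetwork:
    """Undirected weighted graph over protein identifiers.

    Invariants: no self-loops, no duplicate edges (networkx guarantees the
    latter), every edge endpoint is a node.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        """Build from (a, b, score) triples; A-B / B-A collapse to the max score."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, score in edges:
            if a == b:
                raise ValidationError(f"self-interaction not allowed: {a!r}")
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], float(score))
            else:
                g.add_edge(a, b, score=float(score))
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_with_scores(self) -> list[tuple[str, str, float]]:
        """Edges as (a, b, score) with endpoints in sorted order, so the
        listing is independent of insertion order."""
        return [
            (*sorted((a, b)), d["score"])
            for a, b, d in self.graph.edges(data=True)
        ]

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    # -- serialization ---------------------------------------------------

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        # GraphML cannot store sets/lists of strings; join them.
        for _, attrs in g.nodes(data=True):
            for key, val in list(attrs.items()):
                if isinstance(val, (set, frozenset, list, tuple)):
                    attrs[key] = ";".join(sorted(map(str, val)))
        nx.write_graphml(g, path)

    def to_edgelist_tsv(self, path, species_prefix: str = "") -> None:
        """Three-column TSV (protein_a, protein_b, combined_score).

        ``species_prefix`` (e.g. ``"9606."``) is restored on write when the
        source file carried one.
        """
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tcombined_score\n")
            for a, b, s in sorted(self.edges_with_scores()):
                fh.write(
                    f"{species_prefix}{a}\t{species_prefix}{b}\t{int(round(s))}\n"
                )

    def node_table(self):
        import pandas as pd

        rows = []
        for n, attrs in self.graph.nodes(data=True):
            row = {"protein": n}
            for key, val in attrs.items():
                if isinstance(val, (set, frozenset, list, tuple)):
                    val = ";".join(sorted(map(str, val)))
                row[key] = val
            rows.append(row)
        return pd.DataFrame(rows)


def build_network(
    proteins: Iterable[str],
    interactions: InteractionNetwork,
    score_cutoff: float = 400.0,
) -> InteractionNetwork:
    """Induce the interaction subgraph on a protein set.

    Keeps every requested protein that exists in the source graph as a node
    (isolated ones are flagged ``isolated=True`` rather than dropped) and
    every source edge between kept proteins whose combined score is at least
    ``score_cutoff``.  Proteins absent from the interaction source are kept
    as isolated, flagged nodes too, so the query set is never silently
    understated.
    """
    proteins = set(proteins)
    g = nx.Graph()
    g.add_nodes_from(proteins)
    src = interactions.graph
    for a, b, d in src.edges(data=True):
        if a in proteins and b in proteins and d["score"] >= score_cutoff:
            g.add_edge(a, b, score=d["score"])
    for n in g.nodes:
        g.nodes[n]["isolated"] = g.degree(n) == 0
    return InteractionNetwork(g)


def label_by_pathway(net: InteractionNetwork, db) -> InteractionNetwork:
    """Attach pathway and top-level labels to every node.

    Nodes without any annotation are labelled ``"unannotated"`` in both
    attributes.  ``db`` is a :class:`proteoflow.pathways.PathwayDB`.
    """
    out = net.copy()
    for n in out.graph.nodes:
        pws = sorted(db.annotations.get(n, set()))
        if pws:
            roots: set[str] = set()
            for p in pws:
                roots |= db.top_level.get(p, {p})
            out.graph.nodes[n]["pathways"] = pws
            out.graph.nodes[n]["top_level"] = sorted(roots)
        else:
            out.graph.nodes[n]["pathways"] = ["unannotated"]
            out.graph.nodes[n]["top_level"] = ["unannotated"]
    return out


def extract_subnetwork(
    net: InteractionNetwork,
    pathway_id: Optional[str] = None,
    top_level_id: Optional[str] = None,
    nodes: Optional[Iterable[str]] = None,
    db=None,
) -> InteractionNetwork:
    """Induced, attribute-preserving subgraph selected by pathway, top-level
    pathway, or an explicit node set.

    Exactly one selector must be given.  Pathway / top-level selection
    requires ``db`` and resolves to the network nodes annotated to the
    pathway (resp. to any pathway whose top-level set contains the id).
    """
    selectors = [pathway_id is not None, top_level_id is not None, nodes is not None]
    if sum(selectors) != 1:
        raise ValidationError("give exactly one of pathway_id/top_level_id/nodes")

    if nodes is not None:
        selected = set(nodes) & set(net.graph.nodes)
    else:
        if db is None:
            raise ValidationError("pathway selectors need a PathwayDB")
        if pathway_id is not None:
            members = {p for p, pws in db.annotations.items() if pathway_id in pws}
        else:
            wanted = set()
            for pw, roots in db.top_level.items():
                if top_level_id in roots:
                    wanted.add(pw)
            members = {
                p for p, pws in db.annotations.items() if pws & wanted
            }
        selected = members & set(net.graph.nodes)

    if not selected:
        raise ValidationError("selector resolves to zero nodes")
    sub = net.graph.subgraph(selected).copy()
    return InteractionNetwork(sub)


def network_stats(net: InteractionNetwork) -> dict:
    """Deterministic summary: counts, degree distribution, components, mean score."""
    g = net.graph
    degrees = sorted(d for _, d in g.degree())
    scores = [d["score"] for _, _, d in g.edges(data=True)]
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_components": nx.number_connected_components(g) if g.number_of_nodes() else 0,
        "degree_distribution": degrees,
        "mean_score": float(sum(scores) / len(scores)) if scores else 0.0,
    }
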