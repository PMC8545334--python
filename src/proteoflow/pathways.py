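"""Hypergeometric pathway over-representation and hierarchy annotation.

The over-representation test: draw n query proteins from a background of N,
of which M are annotated to a pathway; the probability of seeing exactly x
annotated proteins in the query is

    P(X = x) = C(M, x) * C(N - M, n - x) / C(N, n)

and the over-representation p-value is the upper tail P(X >= x), computed
in log space for numerical stability.  Pathway hierarchies (parent -> child
edges) form a directed acyclic graph; each pathway is annotated with its
top-level parents — the ancestor roots with no parents of their own — so
enriched pathways can be grouped into broad biological themes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexp import adjust_bh
from .errors import ParameterError, ValidationError


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_counts(N: int, M: int, n: int, x: int) -> None:
    if not (0 <= M <= N and 0 <= n <= N):
        raise ParameterError(f"infeasible counts N={N}, M={M}, n={n}")
    if not (max(0, n + M - N) <= x <= min(n, M)):
        raise ParameterError(
            f"x={x} infeasible for N={N}, M={M}, n={n} "
            f"(feasible range [{max(0, n + M - N)}, {min(n, M)}])"
        )


def hypergeom_point(N: int, M: int, n: int, x: int) -> float:
    """Exact point probability P(X = x) of the hypergeometric overlap."""
    _check_counts(N, M, n, x)
    logp = (
        _log_choose(np.float64(M), np.float64(x))
        + _log_choose(np.float64(N - M), np.float64(n - x))
        - _log_choose(np.float64(N), np.float64(n))
    )
    return float(np.exp(logp))


def hypergeom_upper_tail(N: int, M: int, n: int, x: int) -> float:
    """Over-representation p-value P(X >= x); exactly 1 when x = 0."""
    _check_counts(N, M, n, x)
    ks = np.arange(x, min(n, M) + 1, dtype=np.float64)
    logs = (
        _log_choose(np.float64(M), ks)
        + _log_choose(np.float64(N - M), n - ks)
        - _log_choose(np.float64(N), np.float64(n))
    )
    return float(min(1.0, np.exp(logsumexp(logs))))


# ---------------------------------------------------------------------------
# pathway database
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Pathway records, protein annotations and the hierarchy DAG.

    ``annotations`` maps protein id -> set of pathway ids; ``top_level``
    maps every pathway to the set of its root ancestors (itself when it has
    no parents or is absent from the relation file).
    """

    pathways: pd.DataFrame  # pathway_id, name, species
    annotations: dict[str, set[str]]
    hierarchy: list[tuple[str, str]] = field(default_factory=list)
    top_level: dict[str, set[str]] = field(default_factory=dict)
    unrooted: set[str] = field(default_factory=set)  # absent from relations
    version_tag: str = "unversioned"

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        relations: Iterable[tuple[str, str]] = (),
        version_tag: str = "unversioned",
    ) -> "PathwayDB":
        """Assemble from annotation records (io layer) + relation edges."""
        pathways = (
            records[["pathway_id", "pathway_name", "species"]]
            .drop_duplicates("pathway_id")
            .rename(columns={"pathway_name": "name"})
            .reset_index(drop=True)
        )
        annotations: dict[str, set[str]] = {}
        for pid, pw in zip(records["protein_id"], records["pathway_id"]):
            annotations.setdefault(pid, set()).add(pw)
        relations = list(relations)
        dag, top = build_hierarchy(relations)
        known = set(pathways["pathway_id"])
        unrooted = {pw for pw in known if pw not in dag}
        top_level = {pw: top.get(pw, {pw}) for pw in known | set(dag.nodes)}
        return cls(
            pathways=pathways,
            annotations=annotations,
            hierarchy=relations,
            top_level=top_level,
            unrooted=unrooted,
            version_tag=version_tag,
        )

    @property
    def universe(self) -> set[str]:
        """All annotated proteins (the default ORA background)."""
        return set(self.annotations)

    def members(self, pathway_id: str) -> set[str]:
        return {p for p, pws in self.annotations.items() if pathway_id in pws}

    def pathway_names(self) -> dict[str, str]:
        return dict(zip(self.pathways["pathway_id"], self.pathways["name"]))


def build_hierarchy(
    edges: Iterable[tuple[str, str]]
) -> tuple[nx.DiGraph, dict[str, set[str]]]:
    """Build the pathway DAG and the top-level (root-ancestor) map.

    ``top_level[v]`` is the set of ancestors of v with in-degree 0, or
    ``{v}`` when v itself is a root.  Cyclic input is rejected with one
    offending cycle named in the error.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = [a for a, _ in nx.find_cycle(dag)]
        raise ValidationError(
            "pathway hierarchy contains a cycle: " + " -> ".join(cycle + [cycle[0]])
        )
    roots = {v for v in dag.nodes if dag.in_degree(v) == 0}
    top: dict[str, set[str]] = {}
    for v in nx.topological_sort(dag):
        if v in roots:
            top[v] = {v}
        else:
            parents = dag.predecessors(v)
            top[v] = set().union(*(top[p] for p in parents))
    return dag, top


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-pathway enrichment table plus the effective query/background."""

    table: pd.DataFrame
    query_size: int
    background_size: int
    warnings: list[str] = field(default_factory=list)


def run_ora(
    query: Iterable[str],
    db: PathwayDB,
    background: Optional[Iterable[str]] = None,
    min_size: int = 3,
    max_size: int = 500,
) -> EnrichmentResult:
    """Hypergeometric over-representation of a protein list in each pathway.

    The background defaults to the database's annotated universe; a supplied
    background (e.g. all quantified proteins) is intersected with the
    universe first, and the query with the background.  Pathways whose
    background membership M falls outside [min_size, max_size] are not
    tested.  BH adjustment runs across tested pathways only; the table is
    sorted by p ascending, ties by x descending then pathway id.
    """
    if min_size < 1 or max_size < min_size:
        raise ParameterError("need 1 <= min_size <= max_size")
    universe = db.universe
    bg = universe if background is None else set(background) & universe
    q = set(query) & bg
    warnings = []
    if not q:
        warnings.append(
            "query has no annotated members in the background; nothing tested"
        )
        empty = pd.DataFrame(
            columns=["pathway_id", "name", "top_level", "N", "M", "n", "x",
                     "expected", "p", "p_adj", "top_level_flagged"]
        )
        return EnrichmentResult(empty, 0, len(bg), warnings)

    N, n = len(bg), len(q)
    names = db.pathway_names()
    rows = []
    for pw in sorted(names):
        members = db.members(pw) & bg
        M = len(members)
        if not min_size <= M <= max_size:
            continue
        x = len(members & q)
        rows.append(
            {
                "pathway_id": pw,
                "name": names[pw],
                "N": N,
                "M": M,
                "n": n,
                "x": x,
                "expected": n * M / N,
                "p": hypergeom_upper_tail(N, M, n, x),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = adjust_bh(table["p"].to_numpy())
        table = table.sort_values(
            by=["p", "x", "pathway_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    else:
        warnings.append("no pathway passed the size bounds")
        table = pd.DataFrame(
            columns=["pathway_id", "name", "N", "M", "n", "x", "expected",
                     "p", "p_adj"]
        )
    table = annotate_top_level(table, db)
    cols = ["pathway_id", "name", "top_level", "N", "M", "n", "x",
            "expected", "p", "p_adj", "top_level_flagged"]
    return EnrichmentResult(table[cols], n, N, warnings)


def annotate_top_level(table: pd.DataFrame, db: PathwayDB) -> pd.DataFrame:
    """Attach each pathway's top-level parents, sorted lexicographically.

    Pathways absent from the relation file label themselves and are flagged
    in the ``top_level_flagged`` column.
    """
    out = table.copy()
    labels, flagged = [], []
    for pw in out.get("pathway_id", []):
        roots = db.top_level.get(pw, {pw})
        labels.append(";".join(sorted(roots)))
        flagged.append(pw in db.unrooted)
    out["top_level"] = labels
    out["top_level_flagged"] = flagged
    return out
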