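"""Ranked correlation network construction and DOT export.

Significant PCIT edges are ordered by |r| descending, a user-supplied list of
well-established (a-priori known) correlations is removed first, and the top
K edges (default 250) are retained.  The graph is undirected — correlation
carries no direction — and serialized as a deterministic Graphviz DOT file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pcit import PcitDecision

DEFAULT_TOP_K = 250


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class NetworkEdge:
    var1: str
    var2: str
    r: float
    rank: int


@dataclass
class NetworkGraph:
    """Top-K correlation network with a record of excluded pairs."""

    nodes: tuple[str, ...]
    edges: tuple[NetworkEdge, ...]
    k: int
    excluded: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.edges) > self.k:
            raise ValueError("more retained edges than k")

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"var1": e.var1, "var2": e.var2, "r": e.r, "rank": e.rank,
                 "significant": True}
                for e in self.edges
            ],
            columns=["var1", "var2", "r", "rank", "significant"],
        )


def rank_and_filter_edges(
    decisions: Sequence[PcitDecision],
    exclusion: Iterable[tuple[str, str]] = (),
    k: int = DEFAULT_TOP_K,
) -> NetworkGraph:
    """Rank significant edges by |r|, drop excluded pairs, keep the top k.

    Exclusion happens before truncation, so a dropped well-established pair
    frees a slot for the next-ranked association.  Ties in |r| break
    lexicographically on the canonical (var1, var2) pair.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    known = {v for d in decisions for v in (d.var_x, d.var_y)}
    excl_set = set()
    for a, b in exclusion:
        if a not in known or b not in known:
            warnings.warn(f"exclusion pair ({a}, {b}) names unknown variables; ignored")
            continue
        excl_set.add(canonical_pair(a, b))
    significant = []
    excluded = []
    for d in decisions:
        if not d.significant:
            continue
        pair = canonical_pair(d.var_x, d.var_y)
        if pair in excl_set:
            excluded.append((pair[0], pair[1], "exclusion_list"))
        else:
            significant.append((pair[0], pair[1], d.r_xy))
    significant.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    retained = [
        NetworkEdge(v1, v2, r, rank)
        for rank, (v1, v2, r) in enumerate(significant[:k], start=1)
    ]
    nodes = tuple(sorted({v for e in retained for v in (e.var1, e.var2)}))
    return NetworkGraph(nodes, tuple(retained), k, tuple(sorted(excluded)))


def dot_string(graph: NetworkGraph, name: str = "correlation_network") -> str:
    """Deterministic undirected DOT description of the retained network.

    One node statement per incident variable (sorted), one edge statement per
    retained edge in rank order; edge weight is |r| to 4 decimals with the
    sign kept in a separate attribute.
    """
    lines = [f"graph {name} {{"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for e in graph.edges:
        sign = "-" if e.r < 0 else "+"
        lines.append(
            f'  "{e.var1}" -- "{e.var2}" '
            f'[label="{abs(e.r):.4f}", sign="{sign}", rank="{e.rank}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot(graph: NetworkGraph, path: str | Path, name: str = "correlation_network") -> None:
    """Write the DOT file; byte-identical across runs for equal input."""
    Path(path).write_text(dot_string(graph, name=name), encoding="utf-8", newline="\n")
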