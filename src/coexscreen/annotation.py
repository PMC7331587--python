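"""Protein-protein interaction mapping and local over-representation analysis.

Module proteins are mapped onto a user-supplied STRING-style weighted edge
list to extract the induced interaction subnetwork, and enriched against
user-supplied GMT gene-set collections with a one-sided Fisher exact
(hypergeometric) test and BH correction.  Identifier matching is exact-string;
no alias or ortholog resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .screen import benjamini_hochberg, hypergeom_upper_tail

logger = logging.getLogger(__name__)

#: STRING-style combined scores run 0-1000; 400 is the usual
#: "medium confidence" cutoff.
DEFAULT_MIN_SCORE = 400.0


def load_edges(path: str | Path, min_score: float = DEFAULT_MIN_SCORE) -> nx.Graph:
    """Load a 3-column (protein_a, protein_b, score) edge list as an undirected graph.

    Edges below ``min_score`` are dropped, duplicate pairs collapse to the
    maximum score, and self-loops are removed with a warning.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            if lineno == 1 and _looks_like_header(parts[2]):
                continue
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
            if a == b:
                logger.warning("%s:%d: self-loop on %s dropped", path, lineno, a)
                continue
            if score < min_score:
                continue
            if g.has_edge(a, b):
                g[a][b]["score"] = max(g[a][b]["score"], score)
            else:
                g.add_edge(a, b, score=score)
    return g


def _looks_like_header(token: str) -> bool:
    try:
        float(token)
        return False
    except ValueError:
        return True


@dataclass
class SubnetworkSummary:
    n_nodes_connected: int
    n_edges: int
    density: float


def induced_subnetwork(net: nx.Graph, proteins: set[str]) -> tuple[nx.Graph, SubnetworkSummary]:
    """Edges of ``net`` with both endpoints in ``proteins``, plus a summary.

    The summary counts nodes with at least one edge, edge count, and the
    density of the induced graph over the mapped proteins.
    """
    sub = net.subgraph(set(proteins) & set(net.nodes)).copy()
    connected = [n for n in sub.nodes if sub.degree(n) > 0]
    n = sub.number_of_nodes()
    possible = n * (n - 1) / 2
    density = sub.number_of_edges() / possible if possible else 0.0
    return sub, SubnetworkSummary(len(connected), sub.number_of_edges(), density)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT gene-set file: name, description, then tab-separated members."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, desc, members = parts[0], parts[1], [x for x in parts[2:] if x]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: empty set {name!r}")
            sets[name] = {"description": desc, "members": set(members)}
    return sets


def ora(
    target: set[str],
    gene_sets: dict[str, dict],
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of ``target`` in each gene set against ``universe``.

    Sets are intersected with the universe before testing; p is the one-sided
    hypergeometric upper tail of the observed overlap and q its BH
    correction across sets.
    """
    if not target:
        raise ValueError("empty target set")
    if not universe:
        raise ValueError("empty universe")
    extra = set(target) - set(universe)
    if extra:
        raise ValueError(f"target proteins outside universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(target)
    rows = []
    for name, info in gene_sets.items():
        inset = info["members"] & universe
        if not inset:
            continue
        k = len(target & inset)
        rows.append(
            {
                "set": name,
                "description": info.get("description", ""),
                "overlap": k,
                "set_size": len(inset),
                "target_size": n,
                "universe": N,
                "p": hypergeom_upper_tail(k, N, len(inset), n),
            }
        )
    tab = pd.DataFrame(rows)
    if not tab.empty:
        tab["q"] = benjamini_hochberg(tab["p"].to_numpy())
    return tab
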