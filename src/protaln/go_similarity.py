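"""Gene Ontology graph, ancestor closures, and the Jaccard accuracy metric.

Functional mapping accuracy is scored by comparing the GO annotation of a
read's true source gene with that of the protein it mapped to.  Each term
set is expanded to its full ancestor closure (is_a edges only, up to the
namespace roots), and the two closures are compared with the Jaccard
coefficient |A∩B| / |A∪B|.  The similarity index of a run is the mean
coefficient over reads that mapped and carry truth terms.
"""

from __future__ import annotations

import math

import networkx as nx
import obonet


class GOGraph:
    """Directed term -> parent graph restricted to is_a edges."""

    def __init__(self, parents: dict[str, set[str]], alt_ids: dict[str, str] | None = None):
        self.parents = parents
        self.alt_ids = alt_ids or {}
        g = nx.DiGraph()
        g.add_nodes_from(parents)
        for child, ps in parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = g
        self.roots = {t for t, ps in parents.items() if not ps}

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.parents

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)


def parse_obo(path) -> GOGraph:
    """Load an OBO 1.2 ontology; obsolete terms skipped, alt_id mapped."""
    net = obonet.read_obo(str(path), ignore_obsolete=True)
    parents: dict[str, set[str]] = {t: set() for t in net.nodes}
    alt_ids: dict[str, str] = {}
    for term, data in net.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, key in net.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return GOGraph(parents, alt_ids)


def closure(graph: GOGraph, terms) -> set[str]:
    """Ancestor closure of a term set: the terms plus everything reachable
    through is_a edges up to the root(s)."""
    out: set[str] = set()
    stack = [graph.canonical(t) for t in terms]
    for t in stack:
        if t not in graph.parents:
            raise KeyError(f"unknown GO term {t!r}")
    while stack:
        t = stack.pop()
        if t in out:
            continue
        out.add(t)
        stack.extend(graph.parents[t])
    return out


def jaccard(a: set[str], b: set[str]) -> float:
    """|a∩b| / |a∪b|; NaN when both sets are empty (excluded from means)."""
    if not a and not b:
        return math.nan
    return len(a & b) / len(a | b)


def similarity_index(
    truth: dict[str, set[str]],
    mapped: dict[str, set[str]],
    graph: GOGraph,
) -> tuple[float, int]:
    """Mean per-read Jaccard over reads present in both tables.

    Returns (mean, n_excluded) where excluded reads are those lacking truth
    terms, lacking a mapped annotation, or with an undefined coefficient.
    """
    values = []
    excluded = 0
    for read_id, true_terms in truth.items():
        if read_id not in mapped or not true_terms:
            excluded += 1
            continue
        j = jaccard(closure(graph, true_terms), closure(graph, mapped[read_id]))
        if math.isnan(j):
            excluded += 1
        else:
            values.append(j)
    if not values:
        raise ValueError("no reads with both truth and mapped GO annotations")
    return sum(values) / len(values), excluded


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """TSV of (id, comma-separated GO ids) -> id -> term set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            terms = fields[1] if len(fields) > 1 else ""
            out[fields[0]] = {t for t in terms.split(",") if t}
    return out
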