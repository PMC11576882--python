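"""Directed-acyclic gene ontologies and Wang graph-based semantic similarity.

The Wang measure scores two terms by how much of their ancestor graphs they
share: each ancestor ``t`` of a term ``A`` contributes an S-value, the maximal
product of edge weights along any path from ``A`` up to ``t`` (``is_a`` edges
decay by 0.8, ``part_of`` by 0.6, and ``S_A(A) = 1``), and

    sim(A, B) = sum_{t in anc(A) & anc(B)} (S_A(t) + S_B(t))
                / (sum_t S_A(t) + sum_t S_B(t)).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

EDGE_TYPES = ("is_a", "part_of")
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class Ontology:
    """A rooted DAG of terms with typed child-to-parent edges."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)  # edges child -> parent
    names: dict[str, str] = field(default_factory=dict)
    namespace: str = "biological_process"

    def add_term(self, term_id: str, name: str = "") -> None:
        self.graph.add_node(term_id)
        self.names[term_id] = name or term_id

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in EDGE_TYPES:
            raise ValueError(f"relation must be one of {EDGE_TYPES}")
        self.graph.add_edge(child, parent, relation=relation)

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def roots(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        roots = self.roots()
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {roots}")
        root = roots[0]
        for n in self.graph.nodes:
            if n != root and not nx.has_path(self.graph, n, root):
                raise ValueError(f"term {n} cannot reach the root")

    def svalues(
        self, term: str, edge_weights: dict[str, float] | None = None
    ) -> dict[str, float]:
        """Max-product S-value of every ancestor of ``term`` (term included)."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        w = edge_weights or DEFAULT_EDGE_WEIGHTS
        sub = nx.descendants(self.graph, term) | {term}  # ancestors in child->parent orientation
        s: dict[str, float] = {term: 1.0}
        # relax in topological order so every child is final before its parents
        for node in nx.topological_sort(self.graph.subgraph(sub)):
            if node not in s:
                continue
            for _, parent, data in self.graph.out_edges(node, data=True):
                cand = s[node] * w[data["relation"]]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        return s


def wang_similarity(
    term_a: str,
    term_b: str,
    ontology: Ontology,
    edge_weights: dict[str, float] | None = None,
) -> float:
    """Wang graph-based semantic similarity between two terms, in (0, 1]."""
    sa = ontology.svalues(term_a, edge_weights)
    sb = ontology.svalues(term_b, edge_weights)
    common = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in common)
    return num / (sum(sa.values()) + sum(sb.values()))


def annotations_with_ancestors(
    ontology: Ontology, direct: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Propagate direct gene annotations up the graph (true-path rule)."""
    full = {t: set(direct.get(t, set())) for t in ontology.graph.nodes}
    for node in nx.topological_sort(ontology.graph):
        for _, parent in ontology.graph.out_edges(node):
            full[parent] |= full[node]
    return full


def write_obo(ontology: Ontology, path) -> None:
    """Write a minimal OBO file ([Term] stanzas with id/name/is_a/part_of)."""
    lines = ["format-version: 1.2", ""]
    for term in ontology.terms:
        lines += [f"[Term]", f"id: {term}", f"name: {ontology.names.get(term, term)}"]
        for _, parent, data in sorted(ontology.graph.out_edges(term, data=True)):
            if data["relation"] == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_obo(path) -> Ontology:
    """Read the minimal OBO subset written by :func:`write_obo`."""
    onto = Ontology()
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id: "):
                current = line[4:]
                onto.add_term(current)
            elif line.startswith("name: ") and current:
                onto.names[current] = line[6:]
            elif line.startswith("is_a: ") and current:
                onto.add_edge(current, line[6:].split(" ")[0], "is_a")
            elif line.startswith("relationship: part_of ") and current:
                onto.add_edge(current, line.split(" ")[2], "part_of")
    return onto


def write_gmt(gene_sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for sid in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[sid]))
            fh.write(f"{sid}\t{descriptions.get(sid, sid)}\t{members}\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets
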