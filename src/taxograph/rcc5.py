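"""Qualitative reasoning over RCC-5 constraint networks.

RCC-5 interprets each node as a non-empty set; the five jointly exhaustive,
pairwise disjoint base relations between two such sets are

* ``EQ``  — equal,
* ``PP``  — proper part (strict subset),
* ``PPI`` — inverse proper part (strict superset),
* ``PO``  — partial overlap (common members plus members unique to each),
* ``DR``  — disjoint (no common member).

An edge of a constraint network holds a *set* of base relations — the
disjunction of what is still possible; the full 5-set is "no information".
Reasoning is composition-based path consistency: sound (it never declares a
satisfiable network inconsistent) but in general incomplete, paired with an
exhaustive finite-model oracle for desk-scale verification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from rdflib import Graph, URIRef

from . import terms as T
from .terms import RDF
from .vocabulary import RCC5

ALL = frozenset(RCC5)

#: Composition table: COMPOSE[(r1, r2)] = set of relations r such that
#: A r1 B and B r2 C admit A r C, under the non-empty-set semantics.
COMPOSE: dict[tuple[RCC5, RCC5], frozenset[RCC5]] = {}


def _f(*rels: RCC5) -> frozenset[RCC5]:
    return frozenset(rels)


def _build_table() -> None:
    EQ, PP, PPI, PO, DR = RCC5.EQ, RCC5.PP, RCC5.PPI, RCC5.PO, RCC5.DR
    for r in RCC5:
        COMPOSE[(EQ, r)] = _f(r)
        COMPOSE[(r, EQ)] = _f(r)
    COMPOSE[(PP, PP)] = _f(PP)
    COMPOSE[(PP, PPI)] = ALL
    COMPOSE[(PP, PO)] = _f(PP, PO, DR)
    COMPOSE[(PP, DR)] = _f(DR)
    COMPOSE[(PPI, PP)] = _f(EQ, PP, PPI, PO)
    COMPOSE[(PPI, PPI)] = _f(PPI)
    COMPOSE[(PPI, PO)] = _f(PPI, PO)
    COMPOSE[(PPI, DR)] = _f(PPI, PO, DR)
    COMPOSE[(PO, PP)] = _f(PP, PO)
    COMPOSE[(PO, PPI)] = _f(PPI, PO, DR)
    COMPOSE[(PO, PO)] = ALL
    COMPOSE[(PO, DR)] = _f(PPI, PO, DR)
    COMPOSE[(DR, PP)] = _f(PP, PO, DR)
    COMPOSE[(DR, PPI)] = _f(DR)
    COMPOSE[(DR, PO)] = _f(PP, PO, DR)
    COMPOSE[(DR, DR)] = ALL


_build_table()


def compose(r1: RCC5, r2: RCC5) -> frozenset[RCC5]:
    """Relations consistent with ∃B: A r1 B ∧ B r2 C."""
    return COMPOSE[(r1, r2)]


def compose_sets(s1: frozenset[RCC5], s2: frozenset[RCC5]) -> frozenset[RCC5]:
    out: set[RCC5] = set()
    for r1 in s1:
        for r2 in s2:
            out |= COMPOSE[(r1, r2)]
            if len(out) == 5:
                return ALL
    return frozenset(out)


def converse_set(s: frozenset[RCC5]) -> frozenset[RCC5]:
    return frozenset(r.converse for r in s)


def relation_between(a: frozenset, b: frozenset) -> RCC5:
    """The base relation holding between two concrete non-empty sets."""
    if a == b:
        return RCC5.EQ
    if a < b:
        return RCC5.PP
    if a > b:
        return RCC5.PPI
    if a & b:
        return RCC5.PO
    return RCC5.DR


class BoundsExceededError(ValueError):
    """The exhaustive oracle was asked for more than it can search."""


class ConstraintNetwork:
    """An RCC-5 constraint network with converse-closed edges.

    Edges are stored once per unordered pair in a canonical direction; the
    converse direction is derived, so converse closure holds by
    construction.  Unconstrained pairs carry the full 5-set.  The diagonal
    is fixed at {EQ}.
    """

    def __init__(self, nodes=()):
        self.nodes: list = list(nodes)
        self._edges: dict[tuple, frozenset[RCC5]] = {}

    def add_node(self, n) -> None:
        if n not in self.nodes:
            self.nodes.append(n)

    @staticmethod
    def _key(i, j):
        return (i, j) if repr(i) <= repr(j) else (j, i)

    def get(self, i, j) -> frozenset[RCC5]:
        if i == j:
            return _f(RCC5.EQ)
        stored = self._edges.get(self._key(i, j), ALL)
        return stored if self._key(i, j) == (i, j) else converse_set(stored)

    def set(self, i, j, rels: frozenset[RCC5]) -> None:
        if i == j:
            raise ValueError("the diagonal is fixed at {EQ}")
        self.add_node(i)
        self.add_node(j)
        rels = frozenset(rels)
        key = self._key(i, j)
        self._edges[key] = rels if key == (i, j) else converse_set(rels)

    def restrict(self, i, j, rels: frozenset[RCC5]) -> frozenset[RCC5]:
        """Intersect edge (i, j) with *rels*; returns the refined set."""
        new = self.get(i, j) & frozenset(rels)
        self.set(i, j, new)
        return new

    def constrained_pairs(self):
        """Unordered pairs carrying information (not the full 5-set)."""
        return {k: v for k, v in self._edges.items() if v != ALL}

    def copy(self) -> "ConstraintNetwork":
        net = ConstraintNetwork(self.nodes)
        net._edges = dict(self._edges)
        return net


@dataclass
class ConsistencyResult:
    consistent: bool
    network: ConstraintNetwork
    empty_edges: list = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "consistent-so-far" if self.consistent else "inconsistent"


def path_consistency(net: ConstraintNetwork) -> ConsistencyResult:
    """Refine a network to path consistency.

    Repeats ``R(i,j) ← R(i,j) ∩ ⋃ R(i,k)∘R(k,j)`` until fixpoint.
    Refinement is monotone (edge sets only shrink), so the fixpoint is
    order-independent.  An empty edge means inconsistency; a non-empty
    fixpoint means consistent-so-far (path consistency can under-detect,
    never over-detect)."""
    out = net.copy()
    nodes = out.nodes
    for i, j in itertools.combinations(nodes, 2):
        if not out.get(i, j):
            return ConsistencyResult(False, out, [(i, j)])
    changed = True
    empty: list = []
    while changed:
        changed = False
        for i, j in itertools.combinations(nodes, 2):
            current = out.get(i, j)
            for k in nodes:
                if k == i or k == j:
                    continue
                refined = current & compose_sets(out.get(i, k), out.get(k, j))
                if refined != current:
                    current = refined
                    out.set(i, j, refined)
                    changed = True
                if not current:
                    empty.append((i, j))
                    return ConsistencyResult(False, out, empty)
    return ConsistencyResult(True, out)


def model_check_oracle(net: ConstraintNetwork, universe_size: int = 4) -> bool:
    """Exhaustively decide satisfiability over a small universe.

    Assigns non-empty subsets of a ``universe_size``-element universe to the
    nodes (backtracking over nodes, pruning on every violated edge) and
    reports whether some assignment realizes one base relation from every
    edge set.  Refuses networks with more than 6 nodes or universes larger
    than 6 — beyond that the search is no longer desk-scale.
    """
    if len(net.nodes) > 6 or universe_size > 6:
        raise BoundsExceededError("oracle bound: at most 6 nodes and universe 6")
    universe = range(universe_size)
    subsets = [frozenset(c)
               for r in range(1, universe_size + 1)
               for c in itertools.combinations(universe, r)]
    nodes = net.nodes

    def extend(idx: int, assignment: list) -> bool:
        if idx == len(nodes):
            return True
        for candidate in subsets:
            ok = True
            for prev_idx in range(idx):
                allowed = net.get(nodes[prev_idx], nodes[idx])
                if relation_between(assignment[prev_idx], candidate) not in allowed:
                    ok = False
                    break
            if ok:
                assignment.append(candidate)
                if extend(idx + 1, assignment):
                    return True
                assignment.pop()
        return False

    if any(not net.get(i, j) for i, j in itertools.combinations(nodes, 2)):
        return False
    return extend(0, [])


def composition_by_enumeration(universe_size: int = 4) -> dict[tuple[RCC5, RCC5], frozenset[RCC5]]:
    """Recompute the composition table by brute-force enumeration of
    triples of non-empty subsets of a small universe (4 elements suffice
    for RCC-5).  Independent cross-check of :data:`COMPOSE`."""
    universe = range(universe_size)
    subsets = [frozenset(c)
               for r in range(1, universe_size + 1)
               for c in itertools.combinations(universe, r)]
    table: dict[tuple[RCC5, RCC5], set[RCC5]] = {
        (r1, r2): set() for r1 in RCC5 for r2 in RCC5
    }
    for a, b in itertools.product(subsets, repeat=2):
        r1 = relation_between(a, b)
        for c in subsets:
            table[(r1, relation_between(b, c))].add(relation_between(a, c))
    return {k: frozenset(v) for k, v in table.items()}


# --- Graph-level checking ---------------------------------------------------

_IRI_TO_RCC5 = {r.iri: r for r in RCC5}


@dataclass
class GraphCheckReport:
    """Outcome of RCC-5 checking over a concept graph."""

    verdict: str                      # "consistent-so-far" | "inconsistent" | "empty"
    refined_edges: dict = field(default_factory=dict)
    culprit_statements: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "refined_edges": {
                f"{s} | {o}": sorted(r.name for r in rels)
                for (s, o), rels in self.refined_edges.items()
            },
            "culprit_statements": [str(s) for s in self.culprit_statements],
            "warnings": list(self.warnings),
        }


def network_from_graph(graph: Graph, import_skos: bool = False):
    """Extract the RCC-5 constraint network from reified statements.

    Malformed statements (missing subject/object, no recognized relation)
    are reported as warnings and excluded.  With ``import_skos=True``, SKOS
    broader/narrower links are additionally read as {PP}/{PPI} edges — off
    by default, the two alignment mechanisms being parallel, not
    equivalent.  Returns (network, pair→statement-IRIs map, warnings).
    """
    net = ConstraintNetwork()
    provenance: dict[tuple, list[URIRef]] = {}
    warnings: list[str] = []
    for stmt in graph.subjects(RDF.type, T.RCC5_STATEMENT):
        subj = graph.value(stmt, T.HAS_SUBJECT_CONCEPT)
        obj = graph.value(stmt, T.HAS_OBJECT_CONCEPT)
        rels = frozenset(
            _IRI_TO_RCC5[r] for r in graph.objects(stmt, T.HAS_RELATION)
            if r in _IRI_TO_RCC5
        )
        if subj is None or obj is None or not rels or subj == obj:
            warnings.append(f"malformed RCC-5 statement {stmt}")
            continue
        net.restrict(subj, obj, rels)
        provenance.setdefault(frozenset((subj, obj)), []).append(stmt)
    if import_skos:
        from .terms import SKOS
        for narrower, broader in graph.subject_objects(SKOS.broader):
            if narrower == broader:
                continue
            net.restrict(narrower, broader, _f(RCC5.PP))
            provenance.setdefault(frozenset((narrower, broader)), [])
    return net, provenance, warnings


def check_graph(graph: Graph, import_skos: bool = False) -> GraphCheckReport:
    """Run path consistency over the RCC-5 statements of a graph.

    Reports the refined edge sets and, on inconsistency, the IRIs of the
    statements contributing to the emptied edge."""
    net, provenance, warnings = network_from_graph(graph, import_skos=import_skos)
    if not net.nodes:
        return GraphCheckReport(verdict="empty", warnings=warnings)
    result = path_consistency(net)
    refined = {k: v for k, v in result.network.constrained_pairs().items()}
    if result.consistent:
        return GraphCheckReport(verdict="consistent-so-far",
                                refined_edges=refined, warnings=warnings)
    culprits: list[URIRef] = []
    for i, j in result.empty_edges:
        culprits.extend(provenance.get(frozenset((i, j)), []))
    if not culprits:  # refinement emptied a derived edge: cite every statement
        for stmts in provenance.values():
            culprits.extend(stmts)
    return GraphCheckReport(verdict="inconsistent", refined_edges=refined,
                            culprit_statements=sorted(set(culprits), key=str),
                            warnings=warnings)
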