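"""Independent oracles and random-instance generators for the test suite.

These deliberately take different computational routes from the package:
heaviest paths by exhaustive simple-path enumeration through networkx, and
GPR evaluation by expansion to disjunctive normal form.
"""

from __future__ import annotations

from math import inf

import networkx as nx
import numpy as np

from mcf.network_model import GPRRule, Metabolite, MetabolicModel, Reaction, parse_gpr


# ---------------------------------------------------------------------------
# Heaviest simple paths by exhaustive enumeration
# ---------------------------------------------------------------------------

def brute_force_heaviest(wg: nx.MultiDiGraph, source: str, max_depth: int,
                         first_hops=None):
    """Max simple-path weight to every node via all_simple_edge_paths."""
    best: dict[str, float] = {}
    for target in wg.nodes:
        if target == source:
            continue
        top = -inf
        for path in nx.all_simple_edge_paths(wg, source, target, cutoff=max_depth):
            if first_hops is not None:
                u0, v0, k0 = path[0]
                if wg.edges[u0, v0, k0].get("reaction", k0) not in first_hops:
                    continue
            w = sum(wg.edges[u, v, k]["weight"] for u, v, k in path)
            if w > top:
                top = w
        if top > -inf:
            best[target] = top
    return best


def random_weighted_digraph(rng: np.random.Generator, n_nodes: int,
                            p_edge: float = 0.25, p_parallel: float = 0.1):
    """Random weighted multidigraph with string node ids and some parallels."""
    g = nx.MultiDiGraph()
    nodes = [f"m{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    ridx = 0
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if rng.random() < p_edge:
                w = float(rng.integers(1, 100))
                g.add_edge(u, v, key=f"r{ridx}", reaction=f"r{ridx}", weight=w)
                ridx += 1
                if rng.random() < p_parallel:
                    w2 = float(rng.integers(1, 100))
                    g.add_edge(u, v, key=f"r{ridx}", reaction=f"r{ridx}", weight=w2)
                    ridx += 1
    return g


# ---------------------------------------------------------------------------
# GPR evaluation by DNF expansion
# ---------------------------------------------------------------------------

def _dnf(node) -> list[frozenset[str]]:
    """Expand an AND/OR tree into its DNF terms (sets of genes)."""
    if node[0] == "gene":
        return [frozenset([node[1]])]
    child_terms = [_dnf(c) for c in node[1]]
    if node[0] == "or":
        return [t for terms in child_terms for t in terms]
    # and: cartesian product of the children's terms
    terms = [frozenset()]
    for child in child_terms:
        terms = [a | b for a in terms for b in child]
    return terms


def _prune_missing(node, measured: set):
    """Remove unmeasured leaves, collapsing nodes left with no children.

    This is the package's stated missing-leaf policy (drop at the node, so
    an OR falls back to its measured isozymes); note it is *not* equivalent
    to dropping missing genes inside flattened DNF terms.
    """
    if node[0] == "gene":
        return node if node[1] in measured else None
    kept = [c for c in (_prune_missing(c, measured) for c in node[1]) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return (node[0], tuple(kept))


def dnf_evaluate(rule: GPRRule, values: dict) -> float | None:
    """Independent route: prune unmeasured leaves, expand the pruned tree to
    DNF, then take max over terms of min over each term's genes.

    For a fully measured tree this checks the min/max composition through
    the min-over-max distributive identity; pruning shares only the missing
    policy, not the evaluation path.
    """
    if rule.root is None:
        return None
    measured = {g for g, v in values.items() if v is not None}
    pruned = _prune_missing(rule.root, measured)
    if pruned is None:
        return None
    return max(min(values[g] for g in term) for term in _dnf(pruned))


def random_gpr_tree(rng: np.random.Generator, genes: list[str], depth: int) -> str:
    """Random rule string with tree depth <= depth."""
    def build(d: int) -> str:
        if d == 0 or rng.random() < 0.35:
            return genes[rng.integers(len(genes))]
        op = " and " if rng.random() < 0.5 else " or "
        n = int(rng.integers(2, 4))
        return "(" + op.join(build(d - 1) for _ in range(n)) + ")"

    return build(depth)


# ---------------------------------------------------------------------------
# Tiny hand-made models
# ---------------------------------------------------------------------------

def tiny_model() -> MetabolicModel:
    """Three metabolites, two reactions; used across the unit tests."""
    mets = [Metabolite("A_c", "A", "c"), Metabolite("B_c", "B", "c"),
            Metabolite("C_c", "C", "c")]
    rxns = [
        Reaction("r1", (("A_c", 1.0), ("B_c", 1.0)), (("C_c", 1.0),),
                 reversible=False, gpr=parse_gpr("gA and gB"), pathway="P1"),
        Reaction("r2", (("A_c", 1.0),), (("C_c", 2.0),),
                 reversible=True, gpr=parse_gpr("gA or gC"), pathway="P2"),
    ]
    return MetabolicModel(mets, rxns, model_id="tiny")


def random_fixture_model(rng: np.random.Generator, n_mets: int = 8,
                         n_rxns: int = 10) -> MetabolicModel:
    """Random small model exercising multi-substrate/product stoichiometry."""
    mets = [Metabolite(f"m{i}_c", "", "c") for i in range(n_mets)]
    ids = [m.id for m in mets]
    rxns = []
    for j in range(n_rxns):
        ns = int(rng.integers(1, 3))
        npr = int(rng.integers(1, 3))
        chosen = rng.choice(len(ids), size=ns + npr, replace=False)
        subs = tuple((ids[int(i)], float(rng.integers(1, 3))) for i in chosen[:ns])
        prods = tuple((ids[int(i)], float(rng.integers(1, 3))) for i in chosen[ns:])
        rxns.append(
            Reaction(f"r{j}", subs, prods, reversible=bool(rng.random() < 0.4),
                     gpr=parse_gpr(f"g{j}"), pathway=f"P{j % 3}")
        )
    return MetabolicModel(mets, rxns, model_id="random")
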