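"""Genome-scale metabolic network models and their graph representation.

A :class:`MetabolicModel` holds compartment-qualified metabolites, reactions
with stoichiometry and reversibility, Boolean gene-protein-reaction (GPR)
rules, and an optional reaction -> canonical-pathway labelling (e.g. the KEGG
subsystems embedded in Recon1).  Models are read either from SBML (via
cobrapy) or from a small JSON fixture dialect defined by this package so that
the full pipeline is testable on generated toy networks.

The hypergraph-to-digraph transform (:func:`to_digraph`) produces a
``networkx.MultiDiGraph`` over metabolite nodes with one directed edge per
(substrate, product, reaction) triple; reversible reactions contribute edges
in both directions.  Parallel edges are retained, keyed by reaction id,
because two reactions linking the same metabolite pair may carry different
expression weights.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "GPRRule",
    "GPRParseError",
    "ModelValidationError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "parse_gpr",
    "load_model",
    "write_json_model",
    "to_digraph",
    "validate_recon1",
    "model_summary",
]

RECON1_N_GENES = 1496
RECON1_N_PATHWAYS = 99


class GPRParseError(ValueError):
    """Raised when a GPR rule string is malformed; carries the position."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRRule:
    """A Boolean gene-protein-reaction rule as an expression tree.

    Internal nodes are ``("and", children)`` or ``("or", children)``; leaves
    are ``("gene", gene_id)``.  ``root is None`` encodes the empty rule (a
    reaction with no gene association).  Numerical evaluation replaces AND
    with min (an enzyme complex is limited by its scarcest subunit) and OR
    with max (isozymes: the strongest route counts).
    """

    root: Optional[tuple] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        """Set of gene ids appearing as leaves."""
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node[0] == "gene":
                out.add(node[1])
            else:
                stack.extend(node[1])
        return frozenset(out)

    def evaluate(self, values: Mapping[str, float]) -> Optional[float]:
        """Evaluate min/max semantics over ``values``.

        Genes missing from ``values`` are ignored; a node all of whose
        children are missing evaluates to missing.  Returns ``None`` when no
        leaf of the rule is measured (the reaction is then *absent*).
        """
        if self.root is None:
            return None
        return _eval_node(self.root, values)

    def to_string(self) -> str:
        if self.root is None:
            return ""
        return _unparse(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _eval_node(node: tuple, values: Mapping[str, float]) -> Optional[float]:
    kind = node[0]
    if kind == "gene":
        v = values.get(node[1])
        return None if v is None else float(v)
    child_vals = [_eval_node(c, values) for c in node[1]]
    present = [v for v in child_vals if v is not None]
    if not present:
        return None
    return min(present) if kind == "and" else max(present)


def _unparse(node: tuple) -> str:
    if node[0] == "gene":
        return node[1]
    op = f" {node[0]} "
    parts = []
    for child in node[1]:
        s = _unparse(child)
        if child[0] != "gene":
            s = f"({s})"
        parts.append(s)
    return op.join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse a GPR rule string into a :class:`GPRRule`.

    Accepts gene identifiers, parentheses and the connectives ``and`` /
    ``or`` (case-insensitive).  ``or`` binds weaker than ``and``.  An empty
    or whitespace-only string yields the empty rule.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or a dangling connective, with the
        character position of the offence.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        return GPRRule(None)

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(rule_text))

    def parse_or() -> tuple:
        nonlocal idx
        children = [parse_and()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", tuple(children))

    def parse_and() -> tuple:
        nonlocal idx
        children = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", tuple(children))

    def parse_atom() -> tuple:
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule at position {pos}")
        if tok == "(":
            idx += 1
            node = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRParseError(f"unbalanced parenthesis at position {pos2}")
            idx += 1
            return node
        if tok == ")":
            raise GPRParseError(f"unbalanced parenthesis at position {pos}")
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"dangling connective {tok!r} at position {pos}")
        idx += 1
        return ("gene", tok)

    root = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GPRParseError(f"unexpected token {tok!r} at position {pos}")
    return GPRRule(root)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    """A compartment-qualified metabolite (e.g. ``atp_c`` vs ``atp_m``).

    The same chemical in two compartments is two distinct metabolites; no
    cross-compartment merging is ever performed.
    """

    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    """A biochemical reaction with stoichiometry, reversibility and GPR.

    ``substrates`` and ``products`` are ``(metabolite_id, coefficient)``
    pairs with positive coefficients.  Boundary/exchange reactions (one side
    empty) are representable but contribute no edges to the metabolite graph.
    """

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = False
    gpr: GPRRule = field(default_factory=GPRRule)
    pathway: Optional[str] = None

    @property
    def is_boundary(self) -> bool:
        return not self.substrates or not self.products


class MetabolicModel:
    """A validated metabolic network model.

    Parameters
    ----------
    metabolites, reactions
        Model content; ids must be unique.
    compartments
        Declared compartment tags; defaults to those used by metabolites.
    model_id
        Free-text identifier, retained for reports.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        compartments: Optional[Iterable[str]] = None,
        model_id: str = "model",
    ):
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            self.reactions[r.id] = r
        if compartments is None:
            compartments = {m.compartment for m in self.metabolites.values()}
        self.compartments: frozenset[str] = frozenset(compartments)
        self.model_id = model_id
        self._validate()

    # -- derived sets ------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        """Union of GPR leaf genes over all reactions."""
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.gpr.genes()
        return frozenset(out)

    @property
    def pathway_labels(self) -> frozenset[str]:
        return frozenset(
            r.pathway for r in self.reactions.values() if r.pathway is not None
        )

    def reactions_by_pathway(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid in sorted(self.reactions):
            p = self.reactions[rid].pathway
            if p is not None:
                out.setdefault(p, []).append(rid)
        return out

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        for r in self.reactions.values():
            for side in (r.substrates, r.products):
                for mid, coeff in side:
                    if mid not in self.metabolites:
                        raise ModelValidationError(
                            f"reaction {r.id!r} references unknown metabolite {mid!r}"
                        )
                    if coeff <= 0:
                        raise ModelValidationError(
                            f"reaction {r.id!r} has non-positive coefficient for {mid!r}"
                        )
        for m in self.metabolites.values():
            if m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id!r} uses undeclared compartment {m.compartment!r}"
                )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.model_id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes, "
            f"{len(self.pathway_labels)} pathways>"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_model(
    path: Union[str, Path], format: str = "auto", pathway_key: str = "SUBSYSTEM"
) -> MetabolicModel:
    """Load a metabolic model from SBML or from the JSON fixture dialect.

    ``format`` is one of ``sbml``, ``json_fixture`` or ``auto`` (by file
    extension: ``.xml``/``.sbml`` -> SBML, ``.json`` -> fixture).
    ``pathway_key`` names the SBML reaction-notes entry holding the
    canonical pathway label (Recon-style models store it under
    ``SUBSYSTEM``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "auto":
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json_fixture"
    if format == "sbml":
        return _load_sbml(path, pathway_key)
    if format == "json_fixture":
        return _load_json(path)
    raise ValueError(f"unknown model format {format!r}")


def _load_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"unparseable JSON fixture {path}: {exc}") from exc
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                substrates=tuple((s[0], float(s[1])) for s in r.get("substrates", [])),
                products=tuple((p[0], float(p[1])) for p in r.get("products", [])),
                reversible=bool(r.get("reversible", False)),
                gpr=parse_gpr(r.get("gpr", "")),
                pathway=r.get("pathway"),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:
        raise ModelValidationError(f"fixture {path} missing required key {exc}") from exc
    return MetabolicModel(
        mets, rxns, data.get("compartments"), data.get("id", path.stem)
    )


def write_json_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize a model to the JSON fixture dialect (round-trip safe)."""
    data = {
        "id": model.model_id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in (model.metabolites[k] for k in sorted(model.metabolites))
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": [[mid, c] for mid, c in r.substrates],
                "products": [[mid, c] for mid, c in r.products],
                "reversible": r.reversible,
                "gpr": r.gpr.to_string(),
                "pathway": r.pathway,
            }
            for r in (model.reactions[k] for k in sorted(model.reactions))
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def _load_sbml(path: Path, pathway_key: str = "SUBSYSTEM") -> MetabolicModel:
    # cobrapy handles SBML level/version and fbc quirks; the subsystem/notes
    # field carries the canonical pathway label in Recon-style models.
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various types
        raise ModelValidationError(f"unparseable SBML {path}: {exc}") from exc
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        subs = tuple(
            (m.id, abs(float(c))) for m, c in r.metabolites.items() if c < 0
        )
        prods = tuple(
            (m.id, abs(float(c))) for m, c in r.metabolites.items() if c > 0
        )
        pathway = r.subsystem or r.notes.get(pathway_key) or None
        rxns.append(
            Reaction(
                id=r.id,
                substrates=subs,
                products=prods,
                reversible=bool(r.reversibility),
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                pathway=pathway,
            )
        )
    return MetabolicModel(mets, rxns, model_id=cm.id or path.stem)


# ---------------------------------------------------------------------------
# Graph transform
# ---------------------------------------------------------------------------

def to_digraph(model: MetabolicModel, emit_reverse: bool = True) -> nx.MultiDiGraph:
    """Transform the reaction hypergraph into a metabolite multidigraph.

    Every (substrate, product) pair of a reaction contributes a directed
    edge labelled with the reaction id; a reversible reaction additionally
    contributes the reversed edges (disable with ``emit_reverse=False``).
    Boundary reactions contribute nothing.  Self-loop edges (a metabolite on
    both sides of one reaction) are emitted but are never traversed by the
    path search.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(model.metabolites)
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        if r.is_boundary:
            continue
        for smid, _ in r.substrates:
            for pmid, _ in r.products:
                g.add_edge(smid, pmid, key=rid, reaction=rid)
                if r.reversible and emit_reverse:
                    g.add_edge(pmid, smid, key=rid, reaction=rid)
    return g


def expected_edge_count(model: MetabolicModel) -> int:
    """Closed-form edge count of :func:`to_digraph` (reverse edges included)."""
    total = 0
    for r in model.reactions.values():
        if r.is_boundary:
            continue
        total += len(r.substrates) * len(r.products) * (2 if r.reversible else 1)
    return total


# ---------------------------------------------------------------------------
# Reports / checks
# ---------------------------------------------------------------------------

def validate_recon1(model: MetabolicModel) -> None:
    """Structural sanity check for a loaded Recon1 model.

    Recon1 annotates 1,496 genes and 99 canonical (KEGG-derived) pathway
    labels; a model claiming to be Recon1 must reproduce both counts.
    """
    n_genes = len(model.genes)
    n_paths = len(model.pathway_labels)
    if n_genes != RECON1_N_GENES or n_paths != RECON1_N_PATHWAYS:
        raise ModelValidationError(
            f"model does not match Recon1: {n_genes} genes (expected "
            f"{RECON1_N_GENES}), {n_paths} pathway labels (expected "
            f"{RECON1_N_PATHWAYS})"
        )


def model_summary(model: MetabolicModel) -> pd.DataFrame:
    """Per-reaction summary table (id, sizes, reversibility, pathway)."""
    rows = []
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rows.append(
            {
                "reaction": rid,
                "n_substrates": len(r.substrates),
                "n_products": len(r.products),
                "reversible": r.reversible,
                "n_genes": len(r.gpr.genes()),
                "pathway": r.pathway if r.pathway is not None else "",
            }
        )
    return pd.DataFrame(rows).set_index("reaction")
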