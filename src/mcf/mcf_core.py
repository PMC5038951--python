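"""Composite pathway discovery: seeds, heaviest paths, target selection.

Finding the simple path whose summed edge weights differ most between two
groups of weighted networks is NP-hard (reduction from longest path), so the
search is restricted in two ways, mirroring the method's own tractability
devices plus one explicit budget of this implementation:

* the first reaction of a path must be differentially expressed (the seed
  metabolites are *reporter metabolites*: substrates of at least ``k``
  significant reactions);
* paths are simple (no repeated metabolite) and bounded to ``max_depth``
  edges.  Within that budget ``exact_bounded`` is an exhaustive
  depth-bounded DFS, i.e. exact; ``beam`` is a breadth-limited alternative
  keeping the ``beam_width`` heaviest partial paths per depth.

For each seed, the targets whose heaviest distance separates cancerous from
noncancerous samples best (smallest Wilcoxon rank-sum p-values) become that
seed's composite pathway features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import inf
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import rank_sum_pvalue
from .expression_mapping import CANCER, NORMAL, DifferentialReactionSet
from .network_model import MetabolicModel

__all__ = [
    "SearchConfig",
    "SeedSet",
    "HeaviestDistanceTable",
    "CompositeFeatureSet",
    "find_seeds",
    "heaviest_distances",
    "select_targets",
    "build_features",
    "extract_pathway_reactions",
    "compute_seed_features",
]

UP_IN_CANCER = "up_in_cancer"
DOWN_IN_CANCER = "down_in_cancer"


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the heaviest-simple-path search.

    max_depth bounds composite pathways to interpretable lengths (default 6
    reactions); beam_width only matters for ``strategy="beam"``.
    """

    strategy: str = "exact_bounded"
    max_depth: int = 6
    beam_width: int = 50
    restrict_first_hop_to_de: bool = True
    record_paths: bool = False
    coverage: float = 0.8
    exclude_targets: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("exact_bounded", "beam"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.max_depth < 1 or self.beam_width < 1:
            raise ValueError("max_depth and beam_width must be >= 1")


@dataclass(frozen=True)
class SeedSet:
    """Substrate-incidence counts over significant reactions and the
    metabolites selected at threshold ``k``."""

    counts: pd.Series
    selected: tuple[str, ...]
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "selected": self.counts.index.isin(self.selected)}
        )


@dataclass(frozen=True)
class HeaviestDistanceTable:
    """Best simple-path weights from one source in one sample's graph.

    ``distances`` maps reached target -> weight; unreachable metabolites are
    simply missing.  ``paths`` (when recorded) maps target -> tuple of
    (reaction id, node) steps realizing the optimum.
    """

    source: str
    distances: dict[str, float]
    paths: Optional[dict[str, tuple[tuple[str, str], ...]]] = None

    def path_reactions(self, target: str) -> frozenset[str]:
        if self.paths is None:
            raise ValueError("path recording was disabled for this search")
        steps = self.paths.get(target)
        return frozenset(rid for rid, _ in steps) if steps else frozenset()


@dataclass(frozen=True)
class CompositeFeatureSet:
    """Composite pathways of one seed: targets, selection stats, features.

    ``features`` is a samples x targets matrix of heaviest distances with
    unreachable entries filled with 0; ``missing`` is the companion mask.
    ``first_hop_reactions`` freezes the significant-reaction set used to
    restrict first hops, so the identical path family can be evaluated on an
    unseen cohort.
    """

    seed: str
    targets: tuple[str, ...]
    pvalues: pd.Series
    directions: pd.Series
    features: pd.DataFrame
    missing: pd.DataFrame
    first_hop_reactions: Optional[frozenset[str]]
    config: SearchConfig

    @property
    def n_targets(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# Seeds
# ---------------------------------------------------------------------------

def find_seeds(
    de: DifferentialReactionSet, model: MetabolicModel, k: int = 5
) -> SeedSet:
    """Reporter metabolites: substrates of >= k significant reactions.

    For reversible reactions both sides count as substrates (either side can
    be consumed).  A metabolite appearing on both sides of one reaction is
    counted once for that reaction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not len(de.pvalues):
        raise ValueError("empty differential reaction set")
    counts: dict[str, int] = {}
    for rid in de.significant:
        r = model.reactions[rid]
        substrate_side = {mid for mid, _ in r.substrates}
        if r.reversible:
            substrate_side |= {mid for mid, _ in r.products}
        for mid in substrate_side:
            counts[mid] = counts.get(mid, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    selected = tuple(series.index[series >= k])
    return SeedSet(series, selected, k)


# ---------------------------------------------------------------------------
# Heaviest simple paths
# ---------------------------------------------------------------------------

def _adjacency(wg) -> dict[str, list[tuple[str, float, str]]]:
    """Per-node successor list with parallel edges collapsed to the heaviest.

    Collapsing is lossless for path search: any simple path through the
    lighter of two parallel edges is dominated by the same path through the
    heavier one.  Ties break on reaction id for determinism.  Self-loops are
    dropped (never traversed).
    """
    best: dict[str, dict[str, tuple[float, str]]] = {}
    for u, v, key, data in wg.edges(keys=True, data=True):
        if u == v:
            continue
        w = float(data["weight"])
        rid = data.get("reaction", key)
        slot = best.setdefault(u, {})
        cur = slot.get(v)
        if cur is None or (w, _neg_str(rid)) > (cur[0], _neg_str(cur[1])):
            slot[v] = (w, rid)
    adj: dict[str, list[tuple[str, float, str]]] = {}
    for u, slot in best.items():
        adj[u] = sorted(
            ((v, w, rid) for v, (w, rid) in slot.items()), key=lambda t: (t[0], t[2])
        )
    return adj


class _neg_str(str):
    """String with reversed ordering, so max-weight/min-id tie-breaks compose."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def heaviest_distances(
    wg,
    source: str,
    cfg: SearchConfig = SearchConfig(),
    de: Optional[DifferentialReactionSet] = None,
) -> HeaviestDistanceTable:
    """Heaviest simple-path weights from ``source`` to every reached node.

    ``wg`` is a weighted metabolite multidigraph (edge attribute ``weight``
    = the reaction's expression rank in one sample).  With
    ``cfg.restrict_first_hop_to_de`` (the default) the first edge's reaction
    must belong to ``de``'s significant set; a source with no admissible
    first hop yields an empty table.

    ``exact_bounded`` returns the true optimum over simple paths of at most
    ``cfg.max_depth`` edges; ``beam`` a lower bound of it.
    """
    if source not in wg:
        raise KeyError(f"source {source!r} not in graph")
    first_hops: Optional[frozenset[str]] = None
    if cfg.restrict_first_hop_to_de:
        if de is None:
            raise ValueError("restrict_first_hop_to_de requires a differential set")
        first_hops = frozenset(de.significant)
    adj = _adjacency(wg)
    return _search(adj, source, cfg, first_hops)


def _search(
    adj: Mapping[str, list[tuple[str, float, str]]],
    source: str,
    cfg: SearchConfig,
    first_hops: Optional[frozenset[str]],
) -> HeaviestDistanceTable:
    if cfg.strategy == "exact_bounded":
        return _dfs_exact(adj, source, cfg, first_hops)
    return _beam(adj, source, cfg, first_hops)


def _dfs_exact(adj, source, cfg, first_hops) -> HeaviestDistanceTable:
    best: dict[str, float] = {}
    best_path: Optional[dict] = {} if cfg.record_paths else None
    visited = {source}
    path_steps: list[tuple[str, str]] = []
    max_depth = cfg.max_depth

    def visit(u: str, depth: int, weight: float) -> None:
        for v, w, rid in adj.get(u, ()):
            if v in visited:
                continue
            if depth == 0 and first_hops is not None and rid not in first_hops:
                continue
            nw = weight + w
            if nw > best.get(v, -inf):
                best[v] = nw
                if best_path is not None:
                    best_path[v] = tuple(path_steps) + ((rid, v),)
            if depth + 1 < max_depth:
                visited.add(v)
                path_steps.append((rid, v))
                visit(v, depth + 1, nw)
                path_steps.pop()
                visited.remove(v)

    visit(source, 0, 0.0)
    return HeaviestDistanceTable(source, best, best_path)


def _beam(adj, source, cfg, first_hops) -> HeaviestDistanceTable:
    best: dict[str, float] = {}
    best_path: Optional[dict] = {} if cfg.record_paths else None
    # partial path = (weight, nodes tuple, steps tuple)
    beams = [(0.0, (source,), ())]
    for depth in range(cfg.max_depth):
        candidates = []
        for weight, nodes, steps in beams:
            u = nodes[-1]
            for v, w, rid in adj.get(u, ()):
                if v in nodes:
                    continue
                if depth == 0 and first_hops is not None and rid not in first_hops:
                    continue
                nw = weight + w
                candidates.append((nw, nodes + (v,), steps + ((rid, v),)))
                if nw > best.get(v, -inf):
                    best[v] = nw
                    if best_path is not None:
                        best_path[v] = steps + ((rid, v),)
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        beams = candidates[: cfg.beam_width]
    return HeaviestDistanceTable(source, best, best_path)


# ---------------------------------------------------------------------------
# Target selection
# ---------------------------------------------------------------------------

def select_targets(
    tables: Mapping[str, HeaviestDistanceTable],
    labels: pd.Series,
    L: int = 10,
    coverage: float = 0.8,
    cfg: SearchConfig = SearchConfig(),
    exclude: Sequence[str] = (),
) -> CompositeFeatureSet:
    """Pick the L targets whose distances separate the two classes best.

    ``tables`` maps sample id -> that sample's distance table (all sharing
    one source).  Targets reachable in fewer than ``coverage`` of samples
    are ineligible.  Unreachable entries become feature value 0 (mask
    retained); p-values are computed on those 0-filled vectors.  Ties on p
    break lexicographically by metabolite id; the direction flag compares
    group means.
    """
    labels = labels.astype(str)
    samples = [s for s in labels.index if s in tables]
    if len(samples) < len(labels.index):
        missing = set(labels.index) - set(samples)
        raise KeyError(f"no distance table for samples: {sorted(missing)[:5]}")
    cancer_ids = [s for s in samples if labels[s] == CANCER]
    normal_ids = [s for s in samples if labels[s] == NORMAL]
    if len(cancer_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need >= 2 samples per class for target selection")
    sources = {t.source for t in tables.values()}
    if len(sources) != 1:
        raise ValueError("tables mix different sources")
    source = sources.pop()

    all_targets = sorted(
        {t for table in tables.values() for t in table.distances}
        - {source}
        - set(exclude)
    )
    feat = pd.DataFrame(0.0, index=pd.Index(samples, name="sample"), columns=all_targets)
    miss = pd.DataFrame(True, index=feat.index, columns=all_targets)
    for s in samples:
        d = tables[s].distances
        for t, w in d.items():
            if t in miss.columns:
                feat.at[s, t] = w
                miss.at[s, t] = False

    reach_frac = 1.0 - miss.mean(axis=0)
    eligible = [t for t in all_targets if reach_frac[t] >= coverage]
    if not eligible:
        raise ValueError("no target passes the reachability coverage filter")

    pvals = {}
    for t in eligible:
        pvals[t] = rank_sum_pvalue(
            feat.loc[normal_ids, t].to_numpy(), feat.loc[cancer_ids, t].to_numpy()
        )
    order = sorted(eligible, key=lambda t: (pvals[t], t))
    if len(order) < L:
        warnings.warn(
            f"only {len(order)} eligible targets for seed {source!r} (L={L})"
        )
    chosen = tuple(order[:L])
    pseries = pd.Series({t: pvals[t] for t in chosen}, dtype=float).loc[list(chosen)]
    directions = pd.Series(
        {
            t: UP_IN_CANCER
            if feat.loc[cancer_ids, t].mean() > feat.loc[normal_ids, t].mean()
            else DOWN_IN_CANCER
            for t in chosen
        }
    ).loc[list(chosen)]
    return CompositeFeatureSet(
        seed=source,
        targets=chosen,
        pvalues=pseries,
        directions=directions,
        features=feat[list(chosen)],
        missing=miss[list(chosen)],
        first_hop_reactions=None,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# End-to-end feature building
# ---------------------------------------------------------------------------

def _tables_for_samples(
    graph,
    rxn: pd.DataFrame,
    samples: Sequence[str],
    source: str,
    cfg: SearchConfig,
    first_hops: Optional[frozenset[str]],
) -> dict[str, HeaviestDistanceTable]:
    """Distance tables for many samples, sharing one adjacency skeleton."""
    base_edges = [
        (u, v, data.get("reaction", key))
        for u, v, key, data in graph.edges(keys=True, data=True)
        if u != v
    ]
    tables = {}
    for s in samples:
        weights = rxn[s]
        best: dict[str, dict[str, tuple[float, str]]] = {}
        for u, v, rid in base_edges:
            w = weights.get(rid)
            if w is None or np.isnan(w):
                continue
            slot = best.setdefault(u, {})
            cur = slot.get(v)
            w = float(w)
            if cur is None or (w, _neg_str(rid)) > (cur[0], _neg_str(cur[1])):
                slot[v] = (w, rid)
        adj = {
            u: sorted(((v, w, rid) for v, (w, rid) in slot.items()),
                      key=lambda t: (t[0], t[2]))
            for u, slot in best.items()
        }
        tables[s] = _search(adj, source, cfg, first_hops)
    return tables


def build_features(
    model: MetabolicModel,
    graph,
    rxn: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    L: int = 10,
    cfg: SearchConfig = SearchConfig(),
    de: Optional[DifferentialReactionSet] = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[CompositeFeatureSet]:
    """Full composite-feature construction on a labelled training cohort.

    Detect differential reactions (unless ``de`` is given), find seeds at
    threshold ``k``, compute per-sample heaviest distances from each seed,
    and select each seed's ``L`` most separating targets.  Seeds for which
    no target passes the coverage filter are skipped with a warning.
    """
    from .expression_mapping import differential_reactions

    if de is None:
        de = differential_reactions(rxn, labels, alpha=alpha, correction=correction)
    seeds = find_seeds(de, model, k=k)
    if not seeds.selected:
        raise ValueError(
            f"no seed metabolite is a substrate of >= {k} differential reactions; "
            "consider lowering k"
        )
    first_hops = frozenset(de.significant) if cfg.restrict_first_hop_to_de else None
    samples = list(labels.index)
    out = []
    for seed in seeds.selected:
        if seed not in graph:
            continue
        tables = _tables_for_samples(graph, rxn, samples, seed, cfg, first_hops)
        try:
            fs = select_targets(
                tables, labels, L=L, coverage=cfg.coverage, cfg=cfg,
                exclude=cfg.exclude_targets,
            )
        except ValueError as exc:
            warnings.warn(f"seed {seed!r} skipped: {exc}")
            continue
        out.append(replace(fs, first_hop_reactions=first_hops))
    if not out:
        raise ValueError("no seed yielded any eligible composite pathway")
    return out


def compute_seed_features(
    feature_set: CompositeFeatureSet,
    graph,
    rxn: pd.DataFrame,
    samples: Sequence[str],
    cfg: Optional[SearchConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate a trained feature set's distances on (new) samples.

    Uses the frozen seed, targets and first-hop restriction; no re-selection
    happens.  Returns (features, missing-mask), features 0-filled.
    """
    cfg = cfg or feature_set.config
    tables = _tables_for_samples(
        graph, rxn, samples, feature_set.seed, cfg, feature_set.first_hop_reactions
    )
    feat = pd.DataFrame(
        0.0, index=pd.Index(samples, name="sample"), columns=list(feature_set.targets)
    )
    miss = pd.DataFrame(True, index=feat.index, columns=feat.columns)
    for s in samples:
        for t, w in tables[s].distances.items():
            if t in feat.columns:
                feat.at[s, t] = w
                miss.at[s, t] = False
    return feat, miss


def extract_pathway_reactions(
    feature_set: CompositeFeatureSet,
    graph,
    rxn: pd.DataFrame,
    samples: Sequence[str],
) -> dict[tuple[str, str], dict[str, frozenset[str]]]:
    """Reaction ids on the realized heaviest path, per (seed, target), per sample.

    Re-runs the search with path recording on.  Samples where a target is
    unreachable map to an empty set.  The union across samples is the input
    to canonical-pathway enrichment.
    """
    cfg = replace(feature_set.config, record_paths=True)
    tables = _tables_for_samples(
        graph, rxn, samples, feature_set.seed, cfg, feature_set.first_hop_reactions
    )
    out: dict[tuple[str, str], dict[str, frozenset[str]]] = {}
    for t in feature_set.targets:
        per_sample = {}
        for s in samples:
            table = tables[s]
            if table.paths is not None and t in table.paths:
                per_sample[s] = table.path_reactions(t)
            else:
                per_sample[s] = frozenset()
        out[(feature_set.seed, t)] = per_sample
    return out
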