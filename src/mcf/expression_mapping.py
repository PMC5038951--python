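"""From gene expression to reaction and pathway expression.

The pipeline's first stage: rank-transform each sample's gene expression
(midranks, ascending — the most highly expressed gene gets rank G), evaluate
every reaction's GPR rule with AND -> min and OR -> max over the gene ranks,
test each reaction for differential expression between cancerous and
noncancerous samples (Wilcoxon rank-sum), and aggregate reaction ranks into
canonical pathway expression (sum by default; mean available).

Expression matrices are pandas DataFrames with genes as rows and samples as
columns; labels are a pandas Series over samples with values ``"cancer"`` /
``"normal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from ._stats import bonferroni, rank_sum_pvalue
from .network_model import MetabolicModel

CANCER = "cancer"
NORMAL = "normal"

__all__ = [
    "CANCER",
    "NORMAL",
    "DifferentialReactionSet",
    "rank_transform",
    "reactions_from_genes",
    "differential_reactions",
    "pathway_expression",
    "sample_weighted_graph",
    "merge_ranked_cohorts",
    "load_expression_tsv",
    "load_labels_tsv",
]


def load_expression_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def load_labels_tsv(path: Union[str, Path]) -> pd.Series:
    """Read a two-column (sample id, label) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = df.iloc[:, 0].astype(str)
    bad = set(labels.unique()) - {CANCER, NORMAL}
    if bad:
        raise ValueError(f"unknown labels in {path}: {sorted(bad)}")
    return labels


def rank_transform(
    expr: pd.DataFrame,
    model: Optional[MetabolicModel] = None,
    restrict_to_model: bool = True,
) -> pd.DataFrame:
    """Within-sample ascending midranks of gene expression.

    Each sample (column) is ranked independently, so downstream per-sample
    quantities never mix information across samples.  With a ``model`` given
    and ``restrict_to_model`` true (the default), the ranking universe is the
    intersection of the matrix's genes with the model's gene set, which keeps
    ranks comparable across cohorts measured on different platforms.

    Raises on NaN values, listing offending cells.
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    if model is not None and restrict_to_model:
        keep = expr.index.intersection(sorted(model.genes))
        if keep.empty:
            raise ValueError("no overlap between expression genes and model genes")
        expr = expr.loc[keep]
    if expr.isna().any().any():
        rows, cols = np.where(expr.isna().to_numpy())
        offending = [f"({expr.index[r]}, {expr.columns[c]})" for r, c in zip(rows[:10], cols[:10])]
        raise ValueError(f"NaN expression values at cells: {', '.join(offending)}")
    return expr.rank(axis=0, method="average", ascending=True)


def merge_ranked_cohorts(*ranked: pd.DataFrame) -> pd.DataFrame:
    """Concatenate rank-transformed cohorts on their gene intersection.

    Ranks are the unit that survives platform differences, so merging
    happens after the per-sample rank transform.  Sample ids must be unique
    across cohorts.
    """
    if not ranked:
        raise ValueError("no cohorts given")
    genes = ranked[0].index
    for r in ranked[1:]:
        genes = genes.intersection(r.index)
    if genes.empty:
        raise ValueError("empty gene intersection across cohorts")
    merged = pd.concat([r.loc[genes] for r in ranked], axis=1)
    if merged.columns.has_duplicates:
        raise ValueError("duplicate sample ids across cohorts")
    return merged


# ---------------------------------------------------------------------------
# GPR evaluation over a ranked matrix
# ---------------------------------------------------------------------------

def _eval_tree_matrix(node, ranked: pd.DataFrame) -> Optional[np.ndarray]:
    # vectorized over the sample axis; None = no measured leaf below node
    if node[0] == "gene":
        gene = node[1]
        if gene not in ranked.index:
            return None
        return ranked.loc[gene].to_numpy(dtype=float)
    parts = [_eval_tree_matrix(c, ranked) for c in node[1]]
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    stacked = np.vstack(parts)
    return stacked.min(axis=0) if node[0] == "and" else stacked.max(axis=0)


def reactions_from_genes(
    ranked: pd.DataFrame, model: MetabolicModel
) -> pd.DataFrame:
    """Evaluate every reaction's GPR over the ranked matrix.

    AND -> min, OR -> max, recursively.  GPR leaves absent from the matrix
    are ignored; a reaction none of whose leaves are measured — or with an
    empty GPR — is *absent* and carries NaN for every sample.

    Returns a reactions x samples DataFrame.
    """
    rows = {}
    n_present = 0
    for rid in sorted(model.reactions):
        gpr = model.reactions[rid].gpr
        if gpr.is_empty:
            rows[rid] = np.full(ranked.shape[1], np.nan)
            continue
        vals = _eval_tree_matrix(gpr.root, ranked)
        if vals is None:
            rows[rid] = np.full(ranked.shape[1], np.nan)
        else:
            rows[rid] = vals
            n_present += 1
    if n_present == 0:
        raise ValueError("no reaction has any measured GPR gene")
    return pd.DataFrame.from_dict(rows, orient="index", columns=ranked.columns)


# ---------------------------------------------------------------------------
# Differential reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialReactionSet:
    """Per-reaction Wilcoxon p-values and the significant subset.

    ``adjusted`` holds the multiplicity-corrected p-values actually compared
    with ``alpha`` (identical to ``pvalues`` when ``correction='none'``).
    """

    pvalues: pd.Series
    adjusted: pd.Series
    significant: frozenset[str]
    alpha: float
    correction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": self.pvalues,
                "p_adjusted": self.adjusted,
                "significant": self.pvalues.index.isin(self.significant),
            }
        )


def differential_reactions(
    rxn: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> DifferentialReactionSet:
    """Two-sided Wilcoxon rank-sum test per reaction, cancer vs normal.

    Only reactions present (non-NaN) in all of ``labels``' samples are
    tested.  ``correction`` is ``"bonferroni"`` or ``"none"``.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = labels.astype(str)
    samples = labels.index
    cancer_ids = labels.index[labels == CANCER]
    normal_ids = labels.index[labels == NORMAL]
    if len(cancer_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need >= 2 samples in each class")
    sub = rxn[samples]
    present = sub.dropna(axis=0, how="any")
    pvals = {}
    for rid, row in present.iterrows():
        pvals[rid] = rank_sum_pvalue(
            row[normal_ids].to_numpy(), row[cancer_ids].to_numpy()
        )
    pseries = pd.Series(pvals, dtype=float).sort_index()
    if correction == "bonferroni":
        reject, adjusted = bonferroni(pseries.to_numpy(), alpha)
    else:
        adjusted = pseries.to_numpy()
        reject = adjusted < alpha
    adj = pd.Series(adjusted, index=pseries.index)
    sig = frozenset(pseries.index[reject])
    return DifferentialReactionSet(pseries, adj, sig, alpha, correction)


# ---------------------------------------------------------------------------
# Pathway expression
# ---------------------------------------------------------------------------

def pathway_expression(
    rxn: pd.DataFrame, model: MetabolicModel, aggregator: str = "sum"
) -> pd.DataFrame:
    """Aggregate reaction ranks into canonical pathway expression.

    For each pathway label, the sum (default; best-performing variant) or
    mean of its member reactions' ranks, per sample.  Absent reactions are
    skipped; a pathway with no evaluable reaction is dropped with a warning.
    """
    if aggregator not in ("sum", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    rows = {}
    for pathway, rids in model.reactions_by_pathway().items():
        members = rxn.loc[[r for r in rids if r in rxn.index]]
        members = members.dropna(axis=0, how="all")
        if members.empty:
            warnings.warn(f"pathway {pathway!r} has no evaluable reaction; dropped")
            continue
        agg = members.sum(axis=0, skipna=True) if aggregator == "sum" else members.mean(
            axis=0, skipna=True
        )
        rows[pathway] = agg
    if not rows:
        raise ValueError("no pathway has any evaluable reaction")
    return pd.DataFrame(rows).T.sort_index()


# ---------------------------------------------------------------------------
# Patient-specific weighted graphs
# ---------------------------------------------------------------------------

def sample_weighted_graph(graph, rxn: pd.DataFrame, sample: str):
    """Copy the metabolite graph with this sample's reaction ranks as weights.

    Edges of reactions absent in this sample are dropped.
    """
    import networkx as nx

    if sample not in rxn.columns:
        raise KeyError(f"unknown sample {sample!r}")
    weights = rxn[sample]
    wg = nx.MultiDiGraph()
    wg.add_nodes_from(graph.nodes)
    for u, v, rid in graph.edges(keys=True):
        w = weights.get(rid)
        if w is None or (isinstance(w, float) and np.isnan(w)):
            continue
        wg.add_edge(u, v, key=rid, reaction=rid, weight=float(w))
    return wg
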