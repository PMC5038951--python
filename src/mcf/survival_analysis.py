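"""Pathway-based survival scoring and evaluation.

Pathway definitions learned on a labelled training cohort (either canonical
pathway label sets or MCF composite (seed, target) pairs) are transferred to
an unseen cohort: each patient's pathway *weight* is the sum of ranks of the
reactions constituting the pathway — for composite pathways, the heaviest
distance realized on that patient's weighted graph.  Pathways are split into
P_c (mean weight higher in cancer on the training cohort) and P_n (higher in
noncancerous tissue), and each patient is scored by the ratio

    score(patient_i) = sum_{p in P_c} weight_i(p) / sum_{p in P_n} weight_i(p)

Higher scores indicate more cancer-like pathway utilization and are treated
as higher risk.  Evaluation: Kaplan-Meier curves of the top/bottom score
deciles with a log-rank test and a normalized area between the curves
(delta-AUC), Harrell's concordance index, per-pathway log-rank tests with
Benjamini-Hochberg FDR, and hypergeometric enrichment of composite-pathway
reactions in canonical pathways (Bonferroni-corrected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, bonferroni
from .expression_mapping import CANCER, NORMAL
from .mcf_core import CompositeFeatureSet, SearchConfig, compute_seed_features
from .network_model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "DirectionAssignment",
    "KMExtremesResult",
    "load_survival_tsv",
    "composite_pathway_weights",
    "assign_directions",
    "patient_scores",
    "km_extremes",
    "per_pathway_km",
    "concordance_index",
    "classification_survival_correlation",
    "canonical_enrichment",
]


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up times and event flags (1 = death observed, 0 = censored)."""

    time: pd.Series
    event: pd.Series

    def __post_init__(self):
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event must share the same patient index")
        if (self.time < 0).any():
            raise ValueError("negative follow-up times")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event flags must be 0/1")

    @property
    def patients(self) -> pd.Index:
        return self.time.index

    def subset(self, ids: Sequence[str]) -> "SurvivalData":
        ids = list(ids)
        return SurvivalData(self.time.loc[ids], self.event.loc[ids])


def load_survival_tsv(path: Union[str, Path]) -> SurvivalData:
    """Read a (patient id, time, event) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return SurvivalData(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(int))


# ---------------------------------------------------------------------------
# Pathway weights on an unseen cohort
# ---------------------------------------------------------------------------

def composite_pathway_weights(
    feature_sets: Sequence[CompositeFeatureSet],
    graph,
    rxn: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    cfg: Optional[SearchConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patients x composite-pathways weight matrix on a (new) cohort.

    Each trained (seed, target) pair is evaluated as the heaviest distance
    on every patient's weighted graph — no re-selection of seeds or targets
    occurs.  Columns are named ``"seed->target"``.  Returns (weights,
    missing-mask); unreachable pairs carry weight 0 and a True mask entry.
    A pair unreachable for every patient triggers a warning.
    """
    if samples is None:
        samples = list(rxn.columns)
    samples = list(samples)
    weight_cols = {}
    miss_cols = {}
    for fs in feature_sets:
        feat, miss = compute_seed_features(fs, graph, rxn, samples, cfg)
        for t in fs.targets:
            name = f"{fs.seed}->{t}"
            weight_cols[name] = feat[t]
            miss_cols[name] = miss[t]
            if miss[t].all():
                warnings.warn(f"composite pathway {name} unreachable for all patients")
    weights = pd.DataFrame(weight_cols, index=pd.Index(samples, name="patient"))
    missing = pd.DataFrame(miss_cols, index=weights.index)
    return weights, missing


# ---------------------------------------------------------------------------
# Directions and patient scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionAssignment:
    """Disjoint split of pathways into cancer-high (P_c) and normal-high (P_n)."""

    p_c: tuple[str, ...]
    p_n: tuple[str, ...]

    def __post_init__(self):
        if set(self.p_c) & set(self.p_n):
            raise ValueError("P_c and P_n overlap")
        if not self.p_n:
            raise ValueError("P_n is empty: the ratio score would be undefined")


def assign_directions(
    weights: pd.DataFrame, labels: pd.Series
) -> DirectionAssignment:
    """Split pathways by comparing group mean weights on a labelled cohort.

    A pathway goes to P_c iff its mean weight in cancer samples exceeds the
    mean in normal samples; exact equality goes to P_n with a warning.
    """
    labels = labels.astype(str)
    cancer_ids = labels.index[labels == CANCER]
    normal_ids = labels.index[labels == NORMAL]
    if len(cancer_ids) == 0 or len(normal_ids) == 0:
        raise ValueError("both classes required to assign directions")
    p_c, p_n = [], []
    for col in weights.columns:
        mc = weights.loc[cancer_ids, col].mean()
        mn = weights.loc[normal_ids, col].mean()
        if mc > mn:
            p_c.append(col)
        else:
            if mc == mn:
                warnings.warn(f"pathway {col!r} has equal group means; assigned to P_n")
            p_n.append(col)
    return DirectionAssignment(tuple(p_c), tuple(p_n))


def patient_scores(
    weights: pd.DataFrame, dirs: DirectionAssignment
) -> pd.Series:
    """Ratio of summed P_c weights to summed P_n weights, per patient.

    Missing weights are treated as 0.  A zero denominator yields NaN; such
    patients are excluded downstream and logged.
    """
    num = weights[list(dirs.p_c)].sum(axis=1) if dirs.p_c else pd.Series(
        0.0, index=weights.index
    )
    den = weights[list(dirs.p_n)].sum(axis=1)
    scores = num / den.where(den > 0)
    n_bad = int(scores.isna().sum())
    if n_bad:
        logger.warning("%d patients have zero P_n weight; scores undefined", n_bad)
    return scores


# ---------------------------------------------------------------------------
# Kaplan-Meier extremes
# ---------------------------------------------------------------------------

def _km_area(time: pd.Series, event: pd.Series, horizon: float) -> float:
    """Area under the Kaplan-Meier curve from 0 to ``horizon``.

    The step function is carried forward beyond the last observation.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_.iloc[:, 0]
    times = np.asarray(sf.index, dtype=float)
    vals = sf.to_numpy(dtype=float)
    grid = np.concatenate([times[times <= horizon], [horizon]])
    area = 0.0
    prev_t, prev_v = 0.0, 1.0
    for t, v in zip(times, vals):
        if t > horizon:
            break
        if t > prev_t:
            area += prev_v * (t - prev_t)
        prev_t, prev_v = t, v
    area += prev_v * (horizon - prev_t)
    return float(area)


@dataclass(frozen=True)
class KMExtremesResult:
    """Log-rank test and delta-AUC between top/bottom score groups."""

    chi2: float
    p: float
    delta_auc: float
    horizon: float
    top_patients: tuple[str, ...]
    bottom_patients: tuple[str, ...]


def _extreme_groups(scores: pd.Series, fraction: float) -> tuple[list, list]:
    scores = scores.dropna()
    n = len(scores)
    n_ext = max(int(np.floor(n * fraction)), 1)
    # deterministic order: score, then patient id, so quantile-boundary ties
    # resolve identically across runs
    order = sorted(scores.index, key=lambda i: (scores[i], str(i)))
    bottom = order[:n_ext]
    top = order[-n_ext:]
    return top, bottom


def km_extremes(
    scores: pd.Series, surv: SurvivalData, fraction: float = 0.10
) -> KMExtremesResult:
    """Compare survival of the top vs bottom score fractions.

    The top-score group is the predicted worst-prognosis group.  delta-AUC
    is (area under the better-surviving KM curve minus the other) divided by
    the common follow-up horizon (the largest observed time in the two
    groups), i.e. a number in [0, 1].
    """
    from lifelines.statistics import logrank_test

    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    scores = scores.dropna()
    top, bottom = _extreme_groups(scores, fraction)
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("need >= 2 patients per extreme group")
    s_top = surv.subset(top)
    s_bot = surv.subset(bottom)
    horizon = float(max(s_top.time.max(), s_bot.time.max()))
    res = logrank_test(
        s_top.time, s_bot.time, event_observed_A=s_top.event,
        event_observed_B=s_bot.event,
    )
    a_top = _km_area(s_top.time, s_top.event, horizon)
    a_bot = _km_area(s_bot.time, s_bot.event, horizon)
    delta = abs(a_bot - a_top) / horizon if horizon > 0 else 0.0
    return KMExtremesResult(
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        delta_auc=float(delta),
        horizon=horizon,
        top_patients=tuple(top),
        bottom_patients=tuple(bottom),
    )


def per_pathway_km(
    weights: pd.DataFrame,
    surv: SurvivalData,
    fraction: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Log-rank test of top vs bottom weight groups for every pathway.

    Benjamini-Hochberg FDR over the pathway family; returns a frame with
    columns p, p_adjusted, significant.
    """
    from lifelines.statistics import logrank_test

    if weights.shape[1] < 2:
        raise ValueError("need >= 2 pathways for the FDR family")
    pvals = {}
    for col in weights.columns:
        top, bottom = _extreme_groups(weights[col], fraction)
        s_top, s_bot = surv.subset(top), surv.subset(bottom)
        res = logrank_test(
            s_top.time, s_bot.time, event_observed_A=s_top.event,
            event_observed_B=s_bot.event,
        )
        pvals[col] = float(res.p_value)
    ps = pd.Series(pvals).loc[list(weights.columns)]
    reject, adjusted = benjamini_hochberg(ps.to_numpy(), alpha)
    return pd.DataFrame(
        {"p": ps, "p_adjusted": adjusted, "significant": reject}
    )


# ---------------------------------------------------------------------------
# Concordance and correlation
# ---------------------------------------------------------------------------

def concordance_index(scores: pd.Series, surv: SurvivalData) -> float:
    """Harrell's C for a *risk* score (higher score -> earlier failure).

    Ties in score count 0.5.  Raises when no pair is comparable.
    """
    from lifelines.utils import concordance_index as _ci
    from lifelines.exceptions import ConvergenceError  # noqa: F401

    scores = scores.dropna()
    ids = scores.index.intersection(surv.patients)
    if len(ids) < 2:
        raise ValueError("need >= 2 scored patients")
    t = surv.time.loc[ids].to_numpy()
    e = surv.event.loc[ids].to_numpy()
    if e.sum() == 0:
        raise ValueError("no events: zero comparable pairs")
    # lifelines' convention: higher prediction = longer survival, so negate
    return float(_ci(t, -scores.loc[ids].to_numpy(), e))


def classification_survival_correlation(
    aucs: pd.Series, cindices: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between per-pathway CV AUCs and C-indices."""
    common = aucs.index.intersection(cindices.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched pathways")
    rho, p = stats.spearmanr(aucs.loc[common], cindices.loc[common])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Canonical enrichment of composite-pathway reactions
# ---------------------------------------------------------------------------

def canonical_enrichment(
    composite_reactions: Iterable[str],
    model: MetabolicModel,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric enrichment of composite reactions in canonical pathways.

    Universe = the model's pathway-labelled reactions; draws = the union of
    reactions on realized composite paths.  One-sided upper tail per
    canonical pathway, Bonferroni-corrected over the pathway family by
    default.
    """
    by_pathway = model.reactions_by_pathway()
    universe = sorted({rid for rids in by_pathway.values() for rid in rids})
    draw = sorted(set(composite_reactions) & set(universe))
    if not draw:
        raise ValueError("composite reaction set is empty (within the universe)")
    M, N = len(universe), len(draw)
    rows = {}
    for pathway, rids in by_pathway.items():
        n = len(rids)
        k = len(set(rids) & set(draw))
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows[pathway] = {"n_pathway": n, "n_overlap": k, "p": p}
    df = pd.DataFrame(rows).T.sort_index()
    df["n_pathway"] = df["n_pathway"].astype(int)
    df["n_overlap"] = df["n_overlap"].astype(int)
    if correction == "bonferroni":
        reject, adjusted = bonferroni(df["p"].to_numpy(), alpha)
    elif correction == "fdr_bh":
        reject, adjusted = benjamini_hochberg(df["p"].to_numpy(), alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df["p_adjusted"] = adjusted
    df["significant"] = reject
    return df


# ---------------------------------------------------------------------------
# Plotting (optional, matplotlib)
# ---------------------------------------------------------------------------

def plot_km_extremes(scores: pd.Series, surv: SurvivalData, fraction: float = 0.10,
                     ax=None):
    """KM curves of the predicted best/worst prognosis groups."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    if ax is None:
        _, ax = plt.subplots()
    top, bottom = _extreme_groups(scores.dropna(), fraction)
    for ids, name in ((bottom, "predicted best prognosis"),
                      (top, "predicted worst prognosis")):
        s = surv.subset(ids)
        KaplanMeierFitter().fit(s.time, s.event, label=name).plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    return ax
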