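"""SVM classifiers and the balanced repeated cross-validation protocol.

Three classifiers are compared throughout:

* **MGE-SVM** — a single SVM on individual metabolic gene expression ranks;
* **pathway SVM** — a single SVM on canonical pathway expression;
* **MCF** — an ensemble of per-seed SVMs, each trained on the heaviest
  distances from one seed to its L selected targets.  A test sample is
  classified by majority vote; the continuous MCF score is the sum of the
  members' decision values, f_i(x) summed over i = 1..N.

The evaluation protocol repeats (default 100 times): down-sample the
majority class to the minority size, then stratified 5-fold CV with seed
and target selection refit inside each training fold (the leakage-safe
reading of the protocol).  Kernel and regularization default to a linear
kernel with C = 1 and per-fold feature standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expression_mapping import CANCER, NORMAL
from .mcf_core import CompositeFeatureSet, SearchConfig, build_features, compute_seed_features
from .network_model import MetabolicModel

__all__ = [
    "EvalProtocol",
    "CVResult",
    "MCFEnsemble",
    "MatrixSVMSpec",
    "MCFSpec",
    "train_mge_svm",
    "train_pathway_svm",
    "train_mcf",
    "predict_majority",
    "mcf_score",
    "cross_validate",
    "compare_classifiers",
]


def _to_y(labels: pd.Series) -> np.ndarray:
    """cancer -> +1, normal -> -1."""
    return np.where(labels.astype(str).to_numpy() == CANCER, 1, -1)


def make_svm(kernel: str = "linear", C: float = 1.0) -> Pipeline:
    """Standardized SVM pipeline (the package-wide default classifier)."""
    return make_pipeline(StandardScaler(), SVC(kernel=kernel, C=C))


def _check_two_classes(labels: pd.Series) -> None:
    classes = set(labels.astype(str).unique())
    if classes != {CANCER, NORMAL}:
        raise ValueError(f"need both classes present, got {sorted(classes)}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class to fit an SVM")


def train_mge_svm(
    ranked: pd.DataFrame, labels: pd.Series, kernel: str = "linear", C: float = 1.0
) -> Pipeline:
    """SVM over individual (metabolic) gene expression ranks.

    ``ranked`` is genes x samples already restricted to the model genes.
    """
    _check_two_classes(labels)
    X = ranked[labels.index].T.to_numpy()
    clf = make_svm(kernel, C)
    clf.fit(X, _to_y(labels))
    return clf


def train_pathway_svm(
    pw: pd.DataFrame, labels: pd.Series, kernel: str = "linear", C: float = 1.0
) -> Pipeline:
    """SVM over canonical pathway expression (pathways x samples input)."""
    _check_two_classes(labels)
    X = pw[labels.index].T.to_numpy()
    clf = make_svm(kernel, C)
    clf.fit(X, _to_y(labels))
    return clf


# ---------------------------------------------------------------------------
# The MCF ensemble
# ---------------------------------------------------------------------------

@dataclass
class MCFEnsemble:
    """N per-seed SVMs plus the vote and score rules."""

    feature_sets: list[CompositeFeatureSet]
    members: list[Pipeline]
    cfg: SearchConfig

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def seeds(self) -> tuple[str, ...]:
        return tuple(fs.seed for fs in self.feature_sets)

    def decision_matrix(self, graph, rxn: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
        """Per-member decision values f_i(x), samples x members."""
        cols = {}
        for fs, clf in zip(self.feature_sets, self.members):
            feat, _ = compute_seed_features(fs, graph, rxn, samples, self.cfg)
            cols[fs.seed] = clf.decision_function(feat.to_numpy())
        return pd.DataFrame(cols, index=pd.Index(samples, name="sample"))

    def score(self, graph, rxn, samples) -> pd.Series:
        """MCFscore(x) = sum of the N members' decision values."""
        return self.decision_matrix(graph, rxn, samples).sum(axis=1)

    def predict(self, graph, rxn, samples) -> pd.Series:
        dm = self.decision_matrix(graph, rxn, samples)
        return _majority_from_decisions(dm)


def _majority_from_decisions(dm: pd.DataFrame) -> pd.Series:
    votes = (dm.to_numpy() > 0).sum(axis=1)
    n = dm.shape[1]
    labels = np.where(votes * 2 > n, CANCER, NORMAL)
    # exact tie (even N): fall back to the sign of the summed score
    ties = votes * 2 == n
    if ties.any():
        score = dm.to_numpy().sum(axis=1)
        labels = np.where(ties, np.where(score > 0, CANCER, NORMAL), labels)
    return pd.Series(labels, index=dm.index)


def predict_majority(decision_values: Sequence[float]) -> str:
    """Majority vote over one sample's member decision values."""
    dm = pd.DataFrame([list(decision_values)])
    return _majority_from_decisions(dm).iloc[0]


def mcf_score(decision_values: Sequence[float]) -> float:
    """Sum of the ensemble members' decision values for one sample."""
    return float(np.sum(decision_values))


def train_mcf(
    model: MetabolicModel,
    graph,
    rxn: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    L: int = 10,
    cfg: SearchConfig = SearchConfig(),
    kernel: str = "linear",
    C: float = 1.0,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> MCFEnsemble:
    """Build composite features and fit one SVM per seed."""
    _check_two_classes(labels)
    feature_sets = build_features(
        model, graph, rxn, labels, k=k, L=L, cfg=cfg, alpha=alpha,
        correction=correction,
    )
    members = []
    y = _to_y(labels)
    for fs in feature_sets:
        X = fs.features.loc[labels.index].to_numpy()
        clf = make_svm(kernel, C)
        clf.fit(X, y)
        members.append(clf)
    return MCFEnsemble(feature_sets, members, cfg)


# ---------------------------------------------------------------------------
# Classifier specs (refit-per-fold interface for cross-validation)
# ---------------------------------------------------------------------------

class _FittedMatrix:
    def __init__(self, clf, features: pd.DataFrame):
        self._clf = clf
        self._features = features

    def scores(self, samples: Sequence[str]) -> pd.Series:
        X = self._features.loc[list(samples)].to_numpy()
        return pd.Series(self._clf.decision_function(X), index=list(samples))

    def predict(self, samples: Sequence[str]) -> pd.Series:
        return pd.Series(
            np.where(self.scores(samples) > 0, CANCER, NORMAL), index=list(samples)
        )


@dataclass
class MatrixSVMSpec:
    """CV spec for a plain SVM over a fixed samples x features matrix.

    Covers both MGE-SVM (gene ranks) and the canonical pathway SVM.
    """

    features: pd.DataFrame  # samples x features
    kernel: str = "linear"
    C: float = 1.0

    def fit(self, train_labels: pd.Series) -> _FittedMatrix:
        _check_two_classes(train_labels)
        X = self.features.loc[train_labels.index].to_numpy()
        clf = make_svm(self.kernel, self.C)
        clf.fit(X, _to_y(train_labels))
        return _FittedMatrix(clf, self.features)


class _ConstantClassifier:
    """Fallback when no seed survives in a training fold: scores all zero.

    With tied scores ROC AUC is exactly 0.5 and the (balanced-fold)
    accuracy that of always predicting one class.
    """

    def __init__(self, label: str = NORMAL):
        self._label = label

    def scores(self, samples) -> pd.Series:
        return pd.Series(0.0, index=list(samples))

    def predict(self, samples) -> pd.Series:
        return pd.Series(self._label, index=list(samples))


class _FittedMCF:
    def __init__(self, ensemble: MCFEnsemble, graph, rxn: pd.DataFrame):
        self.ensemble = ensemble
        self._graph = graph
        self._rxn = rxn

    def scores(self, samples) -> pd.Series:
        return self.ensemble.score(self._graph, self._rxn, list(samples))

    def predict(self, samples) -> pd.Series:
        return self.ensemble.predict(self._graph, self._rxn, list(samples))


@dataclass
class MCFSpec:
    """CV spec that refits the whole MCF pipeline inside each training fold.

    Differential reactions, seeds and targets are all re-derived from the
    training labels only, so held-out labels can never leak into feature
    selection.  Folds where no seed (or no eligible target) emerges fall
    back to an uninformative constant classifier.
    """

    model: MetabolicModel
    graph: object
    rxn: pd.DataFrame
    k: int = 5
    L: int = 10
    cfg: SearchConfig = field(default_factory=SearchConfig)
    kernel: str = "linear"
    C: float = 1.0
    alpha: float = 0.05
    correction: str = "bonferroni"

    def fit(self, train_labels: pd.Series):
        import warnings as _w

        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                ens = train_mcf(
                    self.model, self.graph, self.rxn, train_labels,
                    k=self.k, L=self.L, cfg=self.cfg, kernel=self.kernel,
                    C=self.C, alpha=self.alpha, correction=self.correction,
                )
        except ValueError:
            return _ConstantClassifier()
        return _FittedMCF(ens, self.graph, self.rxn)


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalProtocol:
    """Balanced repeated k-fold CV (default 100 repetitions x 5 folds)."""

    n_repetitions: int = 100
    n_folds: int = 5
    balanced: bool = True
    seed: int = 0


@dataclass
class CVResult:
    """Per-fold AUC/accuracy across repetitions, plus aggregates."""

    table: pd.DataFrame  # columns: repetition, fold, auc, accuracy
    protocol: EvalProtocol

    @property
    def mean_auc(self) -> float:
        return float(self.table["auc"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.table["accuracy"].mean())

    def per_repetition(self) -> pd.DataFrame:
        return self.table.groupby("repetition")[["auc", "accuracy"]].mean()


def _downsample(labels: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Down-sample the majority class uniformly to the minority size."""
    counts = labels.value_counts()
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        return labels
    keep_major = rng.choice(
        np.asarray(labels.index[labels == majority]),
        size=int(counts[minority]),
        replace=False,
    )
    keep = sorted(set(keep_major) | set(labels.index[labels == minority]))
    return labels.loc[keep]


def cross_validate(
    spec, labels: pd.Series, protocol: EvalProtocol = EvalProtocol()
) -> CVResult:
    """Run the balanced repeated CV protocol on a classifier spec.

    ``spec.fit(train_labels)`` must return an object with ``scores`` and
    ``predict`` over sample ids.  Per repetition: down-sample the majority
    class, split into stratified folds, refit on each training fold
    (including any feature selection the spec performs), and record the
    test-fold AUC and accuracy.
    """
    labels = labels.astype(str)
    _check_two_classes(labels)
    counts = labels.value_counts()
    if counts.min() < protocol.n_folds:
        raise ValueError(
            f"minority class ({counts.min()}) smaller than n_folds ({protocol.n_folds})"
        )
    ss = np.random.SeedSequence(protocol.seed)
    rep_seeds = ss.generate_state(protocol.n_repetitions * 2)
    rows = []
    for rep in range(protocol.n_repetitions):
        rng = np.random.default_rng(rep_seeds[2 * rep])
        sub = _downsample(labels, rng) if protocol.balanced else labels
        ids = np.asarray(sub.index)
        y = sub.to_numpy()
        skf = StratifiedKFold(
            n_splits=protocol.n_folds,
            shuffle=True,
            random_state=int(rep_seeds[2 * rep + 1] % (2**31)),
        )
        for fold, (tr, te) in enumerate(skf.split(ids, y)):
            train_labels = sub.iloc[tr]
            test_labels = sub.iloc[te]
            fitted = spec.fit(train_labels)
            test_ids = list(test_labels.index)
            s = fitted.scores(test_ids)
            pred = fitted.predict(test_ids)
            y_true = (test_labels == CANCER).astype(int).to_numpy()
            auc = roc_auc_score(y_true, s.to_numpy()) if len(set(y_true)) == 2 else np.nan
            acc = accuracy_score(test_labels.to_numpy(), pred.to_numpy())
            rows.append({"repetition": rep, "fold": fold, "auc": auc, "accuracy": acc})
    return CVResult(pd.DataFrame(rows), protocol)


def compare_classifiers(
    cv_a: CVResult, cv_b: CVResult, metric: str = "auc"
) -> tuple[float, float, bool]:
    """One-sided paired t-test that classifier A beats classifier B.

    Folds are matched on (repetition, fold); both results must come from
    the same protocol seed so the splits coincide.  Returns
    ``(t, p, degenerate)`` where ``degenerate`` flags a zero-variance
    difference vector (p is then 0.5 for a zero mean difference, else ~0
    reported as the smallest positive float).
    """
    if cv_a.protocol != cv_b.protocol:
        raise ValueError("CV results use different protocols; folds not matched")
    a = cv_a.table.set_index(["repetition", "fold"])[metric]
    b = cv_b.table.set_index(["repetition", "fold"])[metric]
    if not a.index.equals(b.index):
        raise ValueError("mismatched fold structure")
    diff = (a - b).to_numpy()
    if np.allclose(diff.std(ddof=1) if diff.size > 1 else 0.0, 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 0.5, True
        return (np.inf if diff.mean() > 0 else -np.inf,
                np.finfo(float).tiny if diff.mean() > 0 else 1.0, True)
    t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy(), alternative="greater")
    return float(t), float(p), False
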