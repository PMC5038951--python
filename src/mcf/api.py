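"""High-level model/results interface.

:class:`MCFModel` bundles a labelled expression cohort with a metabolic
network and the algorithm's parameters; :meth:`MCFModel.fit` runs the whole
feature-construction + ensemble-training pipeline and returns an
:class:`MCFResults` carrying the learned seeds, targets, selection p-values
and fitted SVMs, with prediction, cross-validation, survival transfer and a
``summary()`` table hanging off it.

Example
-------
>>> from mcf import synthetic_data as syn
>>> from mcf.api import MCFModel
>>> spec = syn.SimulationSpec(seed=0)
>>> network = syn.make_toy_model(spec)
>>> expr, labels = syn.simulate_expression(network, spec)
>>> res = MCFModel(expr, labels, network).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import expression_mapping as em
from . import mcf_core as core
from . import classification as cls
from . import survival_analysis as sa
from .network_model import MetabolicModel, load_model, to_digraph

__all__ = ["MCFModel", "MCFResults"]


class MCFModel:
    """The metabolic classifier and feature generator, as a fittable model.

    Parameters
    ----------
    expression : DataFrame, genes x samples
        Raw expression values (any monotone scale; only within-sample ranks
        are used).
    labels : Series
        Per-sample class, ``"cancer"`` / ``"normal"``.
    network : MetabolicModel
        The metabolic network supplying GPR rules and topology.
    k : int
        Seed threshold: a reporter metabolite must be a substrate of at
        least ``k`` differentially expressed reactions (default 5).
    L : int
        Number of target metabolites per seed (default 10).
    alpha, correction
        Significance level (default 0.05) and multiplicity correction for
        differential reactions (default Bonferroni).
    search : SearchConfig
        Heaviest-path search budget and strategy.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        labels: pd.Series,
        network: MetabolicModel,
        k: int = 5,
        L: int = 10,
        alpha: float = 0.05,
        correction: str = "bonferroni",
        search: Optional[core.SearchConfig] = None,
        kernel: str = "linear",
        C: float = 1.0,
    ):
        self.network = network
        self.k, self.L = k, L
        self.alpha, self.correction = alpha, correction
        self.search = search or core.SearchConfig()
        self.kernel, self.C = kernel, C
        self.labels = labels.astype(str)
        self.expression = expression
        self.ranked = em.rank_transform(expression, network)
        self.reaction_expression = em.reactions_from_genes(self.ranked, network)
        self.graph = to_digraph(network)

    @classmethod
    def from_files(
        cls_,
        expression_path: Union[str, Path],
        labels_path: Union[str, Path],
        model_path: Union[str, Path],
        model_format: str = "auto",
        **kwargs,
    ) -> "MCFModel":
        expr = em.load_expression_tsv(expression_path)
        labels = em.load_labels_tsv(labels_path)
        network = load_model(model_path, model_format)
        return cls_(expr, labels.loc[expr.columns], network, **kwargs)

    def fit(self) -> "MCFResults":
        """Train the per-seed SVM ensemble on the full labelled cohort."""
        ensemble = cls.train_mcf(
            self.network, self.graph, self.reaction_expression, self.labels,
            k=self.k, L=self.L, cfg=self.search, kernel=self.kernel, C=self.C,
            alpha=self.alpha, correction=self.correction,
        )
        return MCFResults(self, ensemble)

    def cv_spec(self) -> cls.MCFSpec:
        """Spec that refits the pipeline per training fold (leakage-safe)."""
        return cls.MCFSpec(
            self.network, self.graph, self.reaction_expression,
            k=self.k, L=self.L, cfg=self.search, kernel=self.kernel, C=self.C,
            alpha=self.alpha, correction=self.correction,
        )

    def cross_validate(
        self, protocol: cls.EvalProtocol = cls.EvalProtocol()
    ) -> cls.CVResult:
        """Balanced repeated CV of the full pipeline."""
        return cls.cross_validate(self.cv_spec(), self.labels, protocol)


@dataclass
class MCFResults:
    """Fitted MCF ensemble plus everything needed to reuse it."""

    model: MCFModel
    ensemble: cls.MCFEnsemble

    @property
    def feature_sets(self) -> list[core.CompositeFeatureSet]:
        return self.ensemble.feature_sets

    @property
    def seeds(self) -> tuple[str, ...]:
        return self.ensemble.seeds

    @property
    def n_composite_pathways(self) -> int:
        return sum(fs.n_targets for fs in self.feature_sets)

    # -- prediction --------------------------------------------------------
    def predict(self, samples: Optional[Sequence[str]] = None) -> pd.Series:
        """Majority-vote class labels on the training cohort's samples."""
        samples = list(samples) if samples is not None else list(self.model.labels.index)
        return self.ensemble.predict(self.model.graph, self.model.reaction_expression, samples)

    def score_samples(self, samples: Optional[Sequence[str]] = None) -> pd.Series:
        """Continuous MCF scores (sum of member decision values)."""
        samples = list(samples) if samples is not None else list(self.model.labels.index)
        return self.ensemble.score(self.model.graph, self.model.reaction_expression, samples)

    # -- survival transfer -------------------------------------------------
    def transfer_weights(
        self, expression: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Composite pathway weights for an unseen cohort.

        Ranks the new cohort per sample over the shared gene universe,
        evaluates reaction expression, and computes the trained (seed,
        target) heaviest distances — no re-selection.
        """
        ranked = em.rank_transform(expression, self.model.network)
        rxn = em.reactions_from_genes(ranked, self.model.network)
        return sa.composite_pathway_weights(
            self.feature_sets, self.model.graph, rxn
        )

    def training_weights(self) -> pd.DataFrame:
        """Composite pathway weights on the training cohort itself."""
        weights, _ = sa.composite_pathway_weights(
            self.feature_sets, self.model.graph, self.model.reaction_expression,
            samples=list(self.model.labels.index),
        )
        return weights

    def directions(self) -> sa.DirectionAssignment:
        """P_c / P_n split of the composite pathways on the training cohort."""
        return sa.assign_directions(self.training_weights(), self.model.labels)

    def survival_scores(self, expression: pd.DataFrame) -> pd.Series:
        """Pathway-ratio prognosis scores for an unseen cohort."""
        weights, _ = self.transfer_weights(expression)
        return sa.patient_scores(weights, self.directions())

    # -- reporting ---------------------------------------------------------
    def composite_pathways_frame(self) -> pd.DataFrame:
        rows = []
        for fs in self.feature_sets:
            for t in fs.targets:
                rows.append(
                    {
                        "seed": fs.seed,
                        "target": t,
                        "p": fs.pvalues[t],
                        "direction": fs.directions[t],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the fitted ensemble."""
        lines = [
            "MCF ensemble fit",
            "=" * 50,
            f"samples: {len(self.model.labels)} "
            f"({(self.model.labels == em.CANCER).sum()} cancer / "
            f"{(self.model.labels == em.NORMAL).sum()} normal)",
            f"network: {len(self.model.network.metabolites)} metabolites, "
            f"{len(self.model.network.reactions)} reactions, "
            f"{len(self.model.network.genes)} genes",
            f"parameters: k={self.model.k}, L={self.model.L}, "
            f"alpha={self.model.alpha} ({self.model.correction}), "
            f"search={self.model.search.strategy} depth {self.model.search.max_depth}",
            f"seeds (N={self.ensemble.n_members}): {', '.join(self.seeds)}",
            f"composite pathways: {self.n_composite_pathways}",
            "",
            "seed                 targets  min p        max p",
            "-" * 50,
        ]
        for fs in self.feature_sets:
            lines.append(
                f"{fs.seed:<20} {fs.n_targets:>7}  {fs.pvalues.min():<11.3g} "
                f"{fs.pvalues.max():<.3g}"
            )
        return "\n".join(lines)
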