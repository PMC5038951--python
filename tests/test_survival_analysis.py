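"""Pathway weights, direction assignment, patient scores and survival stats."""

import numpy as np
import pandas as pd
import pytest

from mcf import synthetic_data as syn
from mcf.expression_mapping import CANCER, NORMAL
from mcf.survival_analysis import (
    DirectionAssignment,
    SurvivalData,
    assign_directions,
    canonical_enrichment,
    classification_survival_correlation,
    composite_pathway_weights,
    concordance_index,
    km_extremes,
    patient_scores,
    per_pathway_km,
)
from oracles import tiny_model


def surv(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return SurvivalData(
        pd.Series(times, index=ids, dtype=float),
        pd.Series(events, index=ids, dtype=int),
    )


class TestDirectionsAndScores:
    def weights(self):
        idx = ["n0", "n1", "c0", "c1"]
        return pd.DataFrame(
            {"pw_up": [200, 200, 300, 300], "pw_down": [300, 300, 200, 200],
             "pw_tie": [100, 100, 100, 100]},
            index=idx, dtype=float,
        )

    def labels(self):
        return pd.Series([NORMAL, NORMAL, CANCER, CANCER],
                         index=["n0", "n1", "c0", "c1"])

    def test_mean_comparison_split(self):
        with pytest.warns(UserWarning, match="pw_tie"):
            dirs = assign_directions(self.weights(), self.labels())
        assert dirs.p_c == ("pw_up",)
        assert set(dirs.p_n) == {"pw_down", "pw_tie"}

    def test_ratio_score_arithmetic(self):
        w = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [15.0]}, index=["p0"])
        dirs = DirectionAssignment(("a", "b"), ("c",))
        assert patient_scores(w, dirs)["p0"] == pytest.approx(2.0)

    def test_zero_numerator_and_zero_denominator(self):
        w = pd.DataFrame({"a": [0.0, 5.0], "c": [15.0, 0.0]}, index=["p0", "p1"])
        dirs = DirectionAssignment(("a",), ("c",))
        s = patient_scores(w, dirs)
        assert s["p0"] == 0.0
        assert np.isnan(s["p1"])  # excluded downstream

    def test_empty_pn_rejected_at_assignment(self):
        with pytest.raises(ValueError, match="P_n"):
            DirectionAssignment(("a",), ())

    def test_scale_invariance(self):
        w = pd.DataFrame({"a": [10.0, 4.0], "c": [5.0, 8.0]}, index=["p0", "p1"])
        dirs = DirectionAssignment(("a",), ("c",))
        pd.testing.assert_series_equal(
            patient_scores(w, dirs), patient_scores(w * 7.3, dirs)
        )


class TestKMExtremes:
    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(0)
        times = np.tile(rng.exponential(10, size=10), 2)
        events = np.ones(20, dtype=int)
        scores = pd.Series(np.r_[np.zeros(10), np.ones(10)] + rng.normal(0, 1e-6, 20),
                           index=[f"p{i}" for i in range(20)])
        res = km_extremes(scores, surv(times, events), fraction=0.5)
        assert res.p > 0.9
        assert res.delta_auc == pytest.approx(0.0, abs=1e-12)

    def test_hand_computable_delta_auc(self):
        # bottom group all die at t=1; top group all censored at t=10
        # areas 1 and 10 over horizon 10 -> delta-AUC 0.9
        scores = pd.Series([0, 0, 0, 1, 1, 1],
                           index=[f"p{i}" for i in range(6)], dtype=float)
        sd = surv([10, 10, 10, 1, 1, 1], [0, 0, 0, 1, 1, 1])
        res = km_extremes(scores, sd, fraction=0.5)
        assert res.delta_auc == pytest.approx(0.9)

    def test_invalid_fraction(self):
        scores = pd.Series([1.0, 2.0], index=["p0", "p1"])
        with pytest.raises(ValueError):
            km_extremes(scores, surv([1, 2], [1, 1]), fraction=0.7)

    def test_coupled_survival_detected(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=300),
                           index=[f"p{i}" for i in range(300)])
        sd = syn.simulate_survival(scores, beta=1.0, censor_rate=0.2, seed=8)
        res = km_extremes(scores, sd, fraction=0.10)
        assert res.p < 0.01


class TestPerPathwayKM:
    def test_bh_family(self):
        rng = np.random.default_rng(2)
        n = 60
        ids = [f"p{i}" for i in range(n)]
        risky = pd.Series(rng.normal(size=n), index=ids)
        sd = syn.simulate_survival(risky, beta=2.0, censor_rate=0.0, seed=1)
        weights = pd.DataFrame(
            {"informative": risky, "noise1": rng.normal(size=n),
             "noise2": rng.normal(size=n)}, index=ids,
        )
        out = per_pathway_km(weights, sd, fraction=0.2)
        assert set(out.columns) == {"p", "p_adjusted", "significant"}
        assert out.loc["informative", "p"] < 0.05

    def test_single_pathway_rejected(self):
        sd = surv([1, 2, 3, 4], [1, 1, 1, 1])
        w = pd.DataFrame({"only": [1.0, 2, 3, 4]}, index=sd.patients)
        with pytest.raises(ValueError):
            per_pathway_km(w, sd)


class TestConcordance:
    def test_perfect_and_reversed(self):
        sd = surv([1, 2, 3], [1, 1, 1])
        assert concordance_index(pd.Series([3, 2, 1], index=sd.patients), sd) == 1.0
        assert concordance_index(pd.Series([1, 2, 3], index=sd.patients), sd) == 0.0

    def test_symmetry_under_negation(self):
        rng = np.random.default_rng(1)
        sd = surv(rng.exponential(5, 50), np.ones(50, dtype=int))
        s = pd.Series(rng.normal(size=50), index=sd.patients)
        c = concordance_index(s, sd)
        assert concordance_index(-s, sd) == pytest.approx(1 - c)

    def test_no_events_rejected(self):
        sd = surv([1, 2], [0, 0])
        with pytest.raises(ValueError):
            concordance_index(pd.Series([1.0, 2.0], index=sd.patients), sd)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        sd = surv(rng.exponential(5, 1000), np.ones(1000, dtype=int))
        s = pd.Series(rng.normal(size=1000), index=sd.patients)
        assert abs(concordance_index(s, sd) - 0.5) < 0.03


class TestCorrelation:
    def test_identical_and_reversed_rankings(self):
        a = pd.Series([0.6, 0.7, 0.8, 0.9], index=list("abcd"))
        rho, _ = classification_survival_correlation(a, a * 2)
        assert rho == pytest.approx(1.0)
        rho, _ = classification_survival_correlation(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        idx = [f"pw{i}" for i in range(80)]
        rho, _ = classification_survival_correlation(
            pd.Series(rng.normal(size=80), index=idx),
            pd.Series(rng.normal(size=80), index=idx),
        )
        assert abs(rho) < 0.25  # ~2 null SDs at n=80

    def test_too_few_pathways(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            classification_survival_correlation(a, a)


class TestEnrichment:
    def ten_reaction_model(self):
        from mcf.network_model import Metabolite, MetabolicModel, Reaction

        mets = [Metabolite("a", "", "c"), Metabolite("b", "", "c")]
        rxns = [
            Reaction(f"r{i}", (("a", 1.0),), (("b", 1.0),),
                     pathway=("A" if i < 5 else "B"))
            for i in range(10)
        ]
        return MetabolicModel(mets, rxns)

    def test_printed_toy_tail(self):
        model = self.ten_reaction_model()
        out = canonical_enrichment({"r0", "r1", "r2", "r3"}, model)
        assert out.loc["A", "p"] == pytest.approx(5 / 210)

    def test_disjoint_pathway_p_one(self):
        model = self.ten_reaction_model()
        out = canonical_enrichment({"r5", "r6"}, model)
        assert out.loc["A", "p"] == pytest.approx(1.0)

    def test_uniform_draws_rarely_significant(self):
        rng = np.random.default_rng(3)
        from mcf.network_model import Metabolite, MetabolicModel, Reaction

        mets = [Metabolite("a", "", "c"), Metabolite("b", "", "c")]
        rxns = [Reaction(f"r{i}", (("a", 1.0),), (("b", 1.0),),
                         pathway=f"P{i % 10}") for i in range(100)]
        model = MetabolicModel(mets, rxns)
        hits = 0
        for _ in range(30):
            draw = rng.choice(100, size=15, replace=False)
            out = canonical_enrichment({f"r{i}" for i in draw}, model)
            hits += int(out["significant"].any())
        assert hits <= 4  # family-level false positives stay rare


class TestCompositeWeightsTransfer:
    def test_shape_and_determinism(self, planted_model, planted_results):
        rxn = planted_model.reaction_expression
        samples = list(planted_model.labels.index)[:10]
        w1, m1 = composite_pathway_weights(
            planted_results.feature_sets, planted_model.graph, rxn, samples
        )
        w2, _ = composite_pathway_weights(
            planted_results.feature_sets, planted_model.graph, rxn, samples
        )
        n_pairs = sum(fs.n_targets for fs in planted_results.feature_sets)
        assert w1.shape == (10, n_pairs)
        pd.testing.assert_frame_equal(w1, w2)

    def test_training_sample_reproduces_training_feature(self, planted_model,
                                                         planted_results):
        fs = planted_results.feature_sets[0]
        s = fs.features.index[0]
        w, _ = composite_pathway_weights(
            [fs], planted_model.graph, planted_model.reaction_expression, [s]
        )
        for t in fs.targets:
            assert w.loc[s, f"{fs.seed}->{t}"] == pytest.approx(fs.features.loc[s, t])
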