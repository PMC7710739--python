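import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmedyn.io import CohortError, build_pairs
from tmedyn.simulate import simulate_state_cohort
from tmedyn.states import (
    integrative_cluster,
    label_states,
    select_k_bic,
    state_feature_anova,
    transition_percentages,
    transition_table,
)


@pytest.fixture(scope="module")
def planted_states():
    return simulate_state_cohort(n_patients=60, separation=5.0, seed=0)


class TestIntegrativeCluster:
    def test_planted_clusters_recovered(self, planted_states):
        sig, frac, truth = planted_states
        model = integrative_cluster([sig, frac], k=3, seed=17)
        assert adjusted_rand_score(truth.state_level, model.assignments) > 0.9

    def test_duplicated_block_matches_single_block(self, planted_states):
        sig, _, _ = planted_states
        single = integrative_cluster([sig], k=3, seed=17)
        double = integrative_cluster([sig, sig.copy()], k=3, seed=17)
        assert adjusted_rand_score(single.assignments, double.assignments) == pytest.approx(1.0)

    def test_infinite_penalty_degenerates(self, planted_states):
        sig, frac, _ = planted_states
        model = integrative_cluster([sig, frac], k=3, penalty=1e6, seed=17)
        assert model.degenerate
        assert model.assignments.nunique() == 1

    def test_within_block_feature_permutation_invariance(self, planted_states):
        sig, frac, _ = planted_states
        base = integrative_cluster([sig, frac], k=3, seed=17)
        permuted = integrative_cluster([sig[sig.columns[::-1]], frac], k=3, seed=17)
        assert adjusted_rand_score(base.assignments, permuted.assignments) == pytest.approx(1.0)

    def test_k_exceeding_samples_errors(self, planted_states):
        sig, frac, _ = planted_states
        with pytest.raises(CohortError):
            integrative_cluster([sig.iloc[:4], frac.iloc[:4]], k=10)


class TestSelectK:
    def test_planted_three_clusters(self, planted_states):
        sig, frac, _ = planted_states
        k, _ = select_k_bic([sig, frac], (2, 3, 4, 5, 6))
        assert k == 3

    def test_single_blob_prefers_smallest_k(self):
        rng = np.random.default_rng(1)
        index = [f"s{i}" for i in range(50)]
        b1 = pd.DataFrame(rng.normal(0, 1, (50, 12)), index=index)
        b2 = pd.DataFrame(rng.normal(0, 1, (50, 8)), index=index)
        k, _ = select_k_bic([b1, b2], (2, 3, 4))
        assert k == 2

    def test_empty_range_errors(self, planted_states):
        sig, frac, _ = planted_states
        with pytest.raises(CohortError):
            select_k_bic([sig, frac], ())


class TestLabelStates:
    def test_means_order_to_cwh(self, planted_states):
        sig, frac, truth = planted_states
        model = integrative_cluster([sig, frac], k=3, seed=17)
        intensity = pd.Series(sig.mean(axis=1), index=sig.index)
        labels = label_states(model, intensity)
        level_by_state = pd.DataFrame(
            {"label": labels, "level": truth.set_index("sample_id").state_level}
        ).groupby("label")["level"].mean()
        assert level_by_state["C"] < level_by_state["W"] < level_by_state["H"]

    def test_wrong_k_errors(self, planted_states):
        sig, frac, _ = planted_states
        model = integrative_cluster([sig, frac], k=2, seed=17)
        with pytest.raises(CohortError):
            label_states(model, pd.Series(sig.mean(axis=1), index=sig.index))

    def test_tied_means_error(self, planted_states):
        sig, frac, _ = planted_states
        model = integrative_cluster([sig, frac], k=3, seed=17)
        constant = pd.Series(1.0, index=sig.index)
        with pytest.raises(CohortError, match="tied"):
            label_states(model, constant)


class TestTransitions:
    def make_pairs(self, n):
        return pd.DataFrame(
            {"sample_a": [f"P{i}_T1" for i in range(n)],
             "sample_b": [f"P{i}_T2" for i in range(n)]},
            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
        )

    def test_printed_transition_percentages(self):
        # 26 warm baseline tumors, 20 of which warm into hot -> 77%;
        # 11 hot on-treatment tumors, 10 of which leave hot -> 91%
        assignments = {}
        for i in range(26):
            assignments[f"P{i}_T1"] = "W"
            assignments[f"P{i}_T2"] = "H" if i < 20 else "W"
        table = transition_table(pd.Series(assignments), self.make_pairs(26))
        pct = transition_percentages(table).set_index(["from_state", "to_state"])
        assert pct.loc[("W", "H"), "percent"] == 77

        assignments = {}
        for i in range(11):
            assignments[f"P{i}_T1"] = "H"
            assignments[f"P{i}_T2"] = "W" if i < 10 else "H"
        table = transition_table(pd.Series(assignments), self.make_pairs(11))
        pct = transition_percentages(table).set_index(["from_state", "to_state"])
        leaving = pct.loc[("H", "W"), "percent"] + pct.loc[("H", "C"), "percent"]
        assert leaving == 91

    def test_identity_assignments_are_diagonal(self):
        assignments = {}
        for i, state in enumerate(["C", "W", "H"] * 4):
            assignments[f"P{i}_T1"] = state
            assignments[f"P{i}_T2"] = state
        table = transition_percentages(
            transition_table(pd.Series(assignments), self.make_pairs(12))
        )
        diag = table[table.from_state == table.to_state]
        off = table[table.from_state != table.to_state]
        assert (diag["percent"] == 100).all()
        assert (off["count"] == 0).all()

    def test_margins_conserved(self, planted_states):
        sig, frac, truth = planted_states
        model = integrative_cluster([sig, frac], k=3, seed=17)
        labels = label_states(model, pd.Series(sig.mean(axis=1), index=sig.index))
        clinical = truth.rename(columns={"state": "_s"}).assign(
            subtype="TN", purity=0.5, pcr="RD"
        )
        pairs = build_pairs(clinical, "T1", "T2")
        table = transition_table(labels, pairs)
        margins = table.groupby("from_state")["count"].sum()
        for state, margin in margins.items():
            recorded = table[table.from_state == state]["from_margin"].iloc[0]
            assert recorded == margin
        assert margins.sum() == len(pairs)


class TestStateFeatureAnova:
    def make_inputs(self, effect, seed=0, n=90):
        rng = np.random.default_rng(seed)
        index = [f"s{i}" for i in range(n)]
        states = pd.Series(np.repeat(["C", "W", "H"], n // 3), index=index)
        purity = pd.Series(rng.uniform(0.2, 0.9, n), index=index)
        subtype = pd.Series(rng.choice(["TN", "ER+/HER2-"], n), index=index)
        level = states.map({"C": 0, "W": 1, "H": 2}).astype(float)
        feature = pd.Series(effect * level + rng.normal(0, 1, n), index=index)
        return feature, states, purity, subtype

    def test_null_feature_not_significant(self):
        pvals = [
            state_feature_anova(*self.make_inputs(0.0, seed=s)) for s in range(20)
        ]
        assert np.mean(pvals) > 0.3  # roughly uniform under the null

    def test_separated_feature_significant(self):
        feature, states, purity, subtype = self.make_inputs(0.0, seed=1)
        feature = states.map({"C": 0.0, "W": 5.0, "H": 10.0}) + feature * 0.01
        p = state_feature_anova(feature, states, purity, subtype)
        assert p < 1e-6

    def test_constant_shift_invariance(self):
        feature, states, purity, subtype = self.make_inputs(1.0, seed=2)
        p1 = state_feature_anova(feature, states, purity, subtype)
        p2 = state_feature_anova(feature + 100.0, states, purity, subtype)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_aliased_design_errors(self):
        feature, states, purity, subtype = self.make_inputs(1.0, seed=3)
        aliased_purity = states.map({"C": 0.2, "W": 0.5, "H": 0.8})
        subtype_const = pd.Series("TN", index=states.index)
        with pytest.raises(CohortError):
            state_feature_anova(feature, states, aliased_purity, subtype_const)
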