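import numpy as np
import pytest

from svbn.inference import query
from svbn.model import exact_structure_search
from svbn.synthetic import (
    LATENT_SUFFIX,
    GaussianEmission,
    PRESETS,
    SyntheticSpec,
    build_preset_network,
    random_network,
    sample_continuous_scores,
    sample_discrete,
    sample_discrete_cohort,
)
from conftest import markov_class


class TestPresets:
    def test_svr_core_published_prevalences(self):
        net = build_preset_network("svr_core")
        assert query(net, "dGV").distribution["true"] == pytest.approx(0.44)
        assert query(net, "SYNDR").distribution["true"] == pytest.approx(0.14)

    def test_collider_preset_cpt(self):
        net = build_preset_network("collider_test")
        np.testing.assert_allclose(
            net.cpts["C"][:, 0], [0.9, 0.1, 0.1, 0.1]
        )

    def test_svr_core_interaction_is_supra_multiplicative(self):
        """At the outcome CPT the joint genotype effect exceeds the product
        of the single-variant effects (each measured with the other variant
        absent): a planted epistatic interaction."""
        net = build_preset_network("svr_core")
        cpt = net.cpts["MDI_low"][:, 0]  # rows (SYNDR, dGV): tt, tf, ft, ff
        p_tt, p_syndr, p_dgv, p_base = cpt
        assert p_tt / p_base > (p_dgv / p_base) * (p_syndr / p_base)

    def test_svr_clinical_extends_core(self):
        core = build_preset_network("svr_core")
        clin = build_preset_network("svr_clinical")
        assert set(core.nodes) < set(clin.nodes)
        assert {"BWT_low", "VENT_prolonged", "PRETERM", "SES_low"} <= set(clin.nodes)

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="svr_core"):
            build_preset_network("nope")

    def test_all_presets_build(self):
        for name in PRESETS:
            build_preset_network(name)


class TestDiscreteSampling:
    def test_same_seed_identical_tables(self):
        truth = build_preset_network("svr_core")
        spec = SyntheticSpec(truth=truth, n_subjects=100, seed=42)
        a = sample_discrete_cohort(spec)
        b = sample_discrete_cohort(spec)
        assert a.data.equals(b.data)

    def test_empirical_prevalence_near_truth(self):
        truth = build_preset_network("svr_core")
        disc = sample_discrete(SyntheticSpec(truth=truth, n_subjects=10_000, seed=7))
        p_hat = (disc.data["dGV"] == "true").mean()
        assert abs(p_hat - 0.44) <= 3 * np.sqrt(0.44 * 0.56 / 10_000)

    def test_deterministic_cpts_collapse_rows(self):
        from svbn.model import BayesianNetwork, DAGStructure

        structure = DAGStructure(
            nodes=("A", "B"),
            state_sets={"A": ("true", "false"), "B": ("true", "false")},
            parents={"A": (), "B": ("A",)},
        )
        net = BayesianNetwork(
            structure=structure,
            cpts={"A": np.array([[1.0, 0.0]]), "B": np.array([[1.0, 0.0], [0.0, 1.0]])},
        )
        disc = sample_discrete(SyntheticSpec(truth=net, n_subjects=50, seed=1))
        assert (disc.data["A"] == "true").all()
        assert (disc.data["B"] == "true").all()

    def test_missingness_injected_at_requested_rate(self):
        truth = build_preset_network("svr_core")
        spec = SyntheticSpec(
            truth=truth, n_subjects=5000, seed=3,
            missing_rate=0.2, missing_columns=("dGV",),
        )
        table = sample_discrete_cohort(spec)
        rate = table.data["dGV"].isna().mean()
        assert abs(rate - 0.2) < 0.03
        assert not table.data["SYNDR"].isna().any()


class TestContinuousEmission:
    def test_class_means_recovered(self):
        truth = build_preset_network("svr_core")
        spec = SyntheticSpec(
            truth=truth, n_subjects=1000, seed=5,
            continuous_emission={"MDI_low": GaussianEmission(60, 7, 100, 10)},
        )
        table = sample_continuous_scores(spec, "MDI_low")
        latent = table.data["MDI_low" + LATENT_SUFFIX].astype(bool).to_numpy()
        scores = table.data["MDI_low"].to_numpy()
        n_low = latent.sum()
        assert abs(scores[latent].mean() - 60) <= 3 * 7 / np.sqrt(n_low)
        assert abs(scores[~latent].mean() - 100) <= 3 * 10 / np.sqrt(1000 - n_low)

    def test_monotone_relation_between_latent_and_scores(self):
        truth = build_preset_network("svr_core")
        for seed in range(5):
            spec = SyntheticSpec(
                truth=truth, n_subjects=300, seed=seed,
                continuous_emission={"MDI_low": GaussianEmission(60, 7, 100, 10)},
            )
            table = sample_continuous_scores(spec, "MDI_low")
            latent = table.data["MDI_low" + LATENT_SUFFIX].astype(bool).to_numpy()
            scores = table.data["MDI_low"].to_numpy()
            assert scores[latent].mean() < scores[~latent].mean()

    def test_degenerate_sd_emits_class_means(self):
        truth = build_preset_network("svr_core")
        spec = SyntheticSpec(
            truth=truth, n_subjects=100, seed=2,
            continuous_emission={"MDI_low": GaussianEmission(60, 1e-6, 100, 1e-6)},
        )
        table = sample_continuous_scores(spec, "MDI_low")
        assert set(np.round(table.data["MDI_low"], 3)) <= {60.0, 100.0}

    def test_undefined_emission_rejected(self):
        truth = build_preset_network("svr_core")
        spec = SyntheticSpec(truth=truth, n_subjects=10, seed=1)
        with pytest.raises(ValueError, match="emission"):
            sample_continuous_scores(spec, "MDI_low")

    def test_zero_sd_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GaussianEmission(60, 0.0, 100, 10)


class TestStructureRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_chain_recovered_up_to_markov_equivalence(self, seed):
        truth = build_preset_network("chain_test")
        disc = sample_discrete(SyntheticSpec(truth=truth, n_subjects=5000, seed=seed))
        got = exact_structure_search(disc, max_parents=3)
        assert markov_class(got) == markov_class(truth.structure)


class TestRiskRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_learned_rr_near_truth_at_large_n(self, seed):
        """The relative risk computed from a network learned on n=10,000
        svr_core samples is within 10% of the generator's exact value."""
        from svbn.model import learn_network
        from svbn.risk import RiskScenario, relative_risk

        truth = build_preset_network("svr_core")
        scenario = RiskScenario("MDI_low", "true", (("dGV", "true"),))
        rr_true = relative_risk(truth, scenario)
        disc = sample_discrete(SyntheticSpec(truth=truth, n_subjects=10_000, seed=seed))
        rr_hat = relative_risk(learn_network(disc), scenario)
        assert abs(rr_hat - rr_true) / rr_true <= 0.10


class TestRandomNetwork:
    def test_seeded_and_valid(self):
        a = random_network(6, seed=3)
        b = random_network(6, seed=3)
        assert a.structure.parents == b.structure.parents
        for v in a.nodes:
            np.testing.assert_array_equal(a.cpts[v], b.cpts[v])
            assert (a.cpts[v] > 0).all()  # no zero-probability assignments

    def test_respects_parent_cap(self):
        net = random_network(8, seed=5, max_parents=2)
        assert max(len(p) for p in net.structure.parents.values()) <= 2
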