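import json

import numpy as np
import pytest

from svbn.model import (
    DAGStructure,
    ModelError,
    exact_structure_search,
    family_score_bic,
    fit_parameters,
    load_network,
    network_score,
    save_network,
)
from conftest import all_dags, make_discrete, random_binary_cohort


def two_column_copy_cohort(n=8):
    """Child identically equal to its parent, balanced."""
    half = ["a"] * (n // 2) + ["b"] * (n // 2)
    return make_discrete({"p": half, "c": list(half)})


class TestFamilyScore:
    def test_parentless_multinomial_mle(self):
        cohort = make_discrete({"x": ["a"] * 6 + ["b"] * 4})
        fs = family_score_bic("x", (), cohort)
        expected_ll = 6 * np.log(0.6) + 4 * np.log(0.4)
        assert fs.loglik == pytest.approx(expected_ll, abs=1e-12)
        assert fs.n_params == 1
        assert fs.bic == pytest.approx(expected_ll - 0.5 * np.log(10), abs=1e-12)

    def test_constant_child_is_point_mass(self):
        cohort = make_discrete({"x": ["a"] * 7})
        fs = family_score_bic("x", (), cohort)
        assert fs.loglik == 0.0
        assert fs.bic == pytest.approx(-0.5 * np.log(7), abs=1e-15)

    def test_deterministic_copy_prefers_parent(self):
        cohort = two_column_copy_cohort(8)
        with_parent = family_score_bic("c", ("p",), cohort)
        without = family_score_bic("c", (), cohort)
        assert with_parent.bic == pytest.approx(-0.5 * np.log(8) * 2, abs=1e-12)
        assert without.bic == pytest.approx(
            8 * np.log(0.5) - 0.5 * np.log(8), abs=1e-12
        )
        assert with_parent.bic > without.bic

    def test_child_among_parents_rejected(self):
        cohort = make_discrete({"x": ["a", "b"]})
        with pytest.raises(ModelError):
            family_score_bic("x", ("x",), cohort)

    def test_param_count_grows_multiplicatively(self):
        cohort = make_discrete(
            {"x": ["a", "b"] * 8, "p": ["a", "a", "b", "b"] * 4, "q": ["a", "b", "b", "a"] * 4}
        )
        one = family_score_bic("x", ("p",), cohort)
        two = family_score_bic("x", ("p", "q"), cohort)
        assert one.n_params == 2
        assert two.n_params == 4


class TestNetworkScore:
    def test_decomposes_into_family_scores(self):
        cohort = random_binary_cohort(["x", "y", "z"], 60, seed=5)
        structure = DAGStructure(
            nodes=("x", "y", "z"),
            state_sets={v: ("a", "b") for v in "xyz"},
            parents={"x": (), "y": ("x",), "z": ("y",)},
        )
        total = network_score(structure, cohort)
        parts = sum(
            family_score_bic(v, structure.parent_tuple(v), cohort).bic
            for v in "xyz"
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_cycle_rejected(self):
        with pytest.raises(ModelError, match="cycle"):
            DAGStructure(
                nodes=("x", "y"),
                state_sets={"x": ("a", "b"), "y": ("a", "b")},
                parents={"x": ("y",), "y": ("x",)},
            )

    def test_likelihood_equivalent_orientations_tie(self):
        cohort = random_binary_cohort(["x", "y"], 200, seed=9)
        ss = {v: ("a", "b") for v in "xy"}
        fwd = DAGStructure(("x", "y"), ss, {"x": (), "y": ("x",)})
        rev = DAGStructure(("x", "y"), ss, {"x": ("y",), "y": ()})
        assert network_score(fwd, cohort) == pytest.approx(
            network_score(rev, cohort), abs=1e-12
        )


class TestExactSearch:
    def test_single_variable_gives_empty_dag(self):
        cohort = make_discrete({"x": ["a", "b", "a"]})
        got = exact_structure_search(cohort)
        assert got.parents == {"x": ()}

    def test_two_independent_variables_give_empty_dag(self):
        rng = np.random.default_rng(3)
        cohort = make_discrete(
            {
                "x": list(rng.choice(["a", "b"], 500)),
                "y": list(rng.choice(["a", "b"], 500)),
            }
        )
        got = exact_structure_search(cohort)
        assert got.n_edges() == 0
        best = max(network_score(g, cohort) for g in all_dags(["x", "y"]))
        assert network_score(got, cohort) == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_dag_enumeration_on_four_nodes(self, seed):
        names = ["w", "x", "y", "z"]
        cohort = random_binary_cohort(names, 200, seed=seed)
        got = exact_structure_search(cohort, max_parents=3)
        best = max(network_score(g, cohort) for g in all_dags(names))
        assert network_score(got, cohort) == pytest.approx(best, abs=1e-9)

    def test_row_permutation_leaves_result_unchanged(self):
        names = ["w", "x", "y", "z"]
        cohort = random_binary_cohort(names, 150, seed=21)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_subjects)
        shuffled = make_discrete(
            {v: list(cohort.data[v].iloc[perm]) for v in names}
        )
        a = exact_structure_search(cohort)
        b = exact_structure_search(shuffled)
        assert a.parents == b.parents
        assert network_score(a, cohort) == pytest.approx(
            network_score(b, shuffled), abs=1e-9
        )

    def test_node_count_guard(self):
        cohort = make_discrete({f"v{i:02d}": ["a", "b"] for i in range(21)})
        with pytest.raises(ModelError, match="exceeds"):
            exact_structure_search(cohort)

    def test_negative_max_parents_rejected(self):
        cohort = make_discrete({"x": ["a", "b"]})
        with pytest.raises(ModelError):
            exact_structure_search(cohort, max_parents=-1)


class TestFitParameters:
    def test_dirichlet_posterior_mean_root(self):
        cohort = make_discrete({"x": ["a"] * 6 + ["b"] * 4})
        structure = exact_structure_search(cohort)
        net = fit_parameters(structure, cohort, pseudocount=1.0)
        assert net.cpts["x"][0, 0] == pytest.approx(7 / 12, abs=1e-12)

    def test_pure_mle_with_zero_pseudocount(self):
        cohort = make_discrete({"x": ["a"] * 5 + ["b"] * 5})
        structure = exact_structure_search(cohort)
        net = fit_parameters(structure, cohort, pseudocount=0.0)
        assert net.cpts["x"][0, 0] == 0.5

    def test_unseen_parent_config_uniform_under_prior(self):
        cohort = make_discrete({"p": ["a"] * 6, "c": ["a", "b"] * 3})
        structure = DAGStructure(
            nodes=("p", "c"),
            state_sets={"p": ("a", "b"), "c": ("a", "b")},
            parents={"p": (), "c": ("p",)},
        )
        net = fit_parameters(structure, cohort, pseudocount=1.0)
        np.testing.assert_allclose(net.cpts["c"][1], [0.5, 0.5])

    def test_unseen_parent_config_rejected_at_mle(self):
        cohort = make_discrete({"p": ["a"] * 6, "c": ["a", "b"] * 3})
        structure = DAGStructure(
            nodes=("p", "c"),
            state_sets={"p": ("a", "b"), "c": ("a", "b")},
            parents={"p": (), "c": ("p",)},
        )
        with pytest.raises(ModelError, match="unseen"):
            fit_parameters(structure, cohort, pseudocount=0.0)


class TestSerialization:
    def test_json_round_trip_preserves_everything(self, tmp_path):
        cohort = random_binary_cohort(["x", "y", "z"], 120, seed=4)
        structure = exact_structure_search(cohort)
        net = fit_parameters(structure, cohort, pseudocount=1.0)
        path = tmp_path / "net.json"
        save_network(net, path)
        back = load_network(path)
        assert back.structure.nodes == net.structure.nodes
        assert dict(back.structure.parents) == dict(net.structure.parents)
        for v in net.structure.nodes:
            np.testing.assert_array_equal(back.cpts[v], net.cpts[v])
        # writing again is byte-identical
        path2 = tmp_path / "net2.json"
        save_network(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_cpt_rows_are_lexicographic_in_sorted_parents(self, tmp_path):
        from svbn.synthetic import build_preset_network

        net = build_preset_network("collider_test")
        path = tmp_path / "net.json"
        save_network(net, path)
        data = json.loads(path.read_text())
        c = next(nd for nd in data["nodes"] if nd["name"] == "C")
        assert c["parents"] == ["A", "B"]
        # rows (A,B): tt, tf, ft, ff with states (true, false)
        assert [row[0] for row in c["cpt"]] == [0.9, 0.1, 0.1, 0.1]
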