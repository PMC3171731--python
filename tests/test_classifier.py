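"""Score feedback features and the two-step estimator contract."""

import copy

import numpy as np
import pytest

from vorsite.env import ContactGraph
from vorsite.errors import ConsistencyError, InputError, TrainingError
from vorsite.feedback import (
    contact_score_vector,
    environmental_score,
    feedback_table,
    max_min_scores,
)
from vorsite.model import TwoStepInterfacePredictor
from vorsite.synthetic import generate_point_cloud

from conftest import heldout_auc_pair, make_chain_dataset


@pytest.fixture()
def scored_cloud():
    st = generate_point_cloud(12, seed=6)
    rng = np.random.default_rng(1)
    from vorsite.env import EnvConfig, sphere_neighbours

    graph = sphere_neighbours(st, 9.0, EnvConfig(mode="sphere", exposed_only=False))
    scores = {r.key: float(rng.uniform()) for r in st.residues}
    return st, graph, scores


class TestFeedback:
    def test_environmental_score_weighted_example(self):
        st = generate_point_cloud(3, seed=7)
        i, j, k = (r.key for r in st.residues)
        graph = ContactGraph(nodes=[i], adjacency={i: {j: 3, k: 1}}, mode="voronoi")
        scores = {i: 0.5, j: 0.8, k: 0.2}
        assert environmental_score(scores, graph, i) == pytest.approx(0.65)

    def test_environmental_score_identity_for_uniform_neighbours(self, scored_cloud):
        st, graph, scores = scored_cloud
        flat = {k: 0.42 for k in scores}
        for key in graph.nodes:
            if graph.adjacency[key]:
                assert environmental_score(flat, graph, key) == pytest.approx(0.42)

    def test_environmental_score_within_neighbour_envelope(self, scored_cloud):
        st, graph, scores = scored_cloud
        for key in graph.nodes:
            nbrs = graph.neighbours(key)
            if not nbrs:
                continue
            es = environmental_score(scores, graph, key)
            vals = [scores[j] for j in nbrs]
            assert min(vals) - 1e-12 <= es <= max(vals) + 1e-12

    def test_csv_examples_and_identity(self, scored_cloud):
        st, graph, scores = scored_cloud
        # single Gly neighbour with c=1, s=0.7
        g_st = generate_point_cloud(2, seed=8)
        g_st.residues[1].res_type = "GLY"
        i, j = (r.key for r in g_st.residues)
        g = ContactGraph(nodes=[i], adjacency={i: {j: 5}}, mode="voronoi")
        csv = contact_score_vector({i: 0.1, j: 0.7}, g, g_st, i)
        from vorsite.constants import AMINO_ACIDS

        assert csv[AMINO_ACIDS.index("GLY")] == pytest.approx(0.7)
        assert np.count_nonzero(csv) == 1
        # sum identity on a random fixture
        for key in graph.nodes:
            csv = contact_score_vector(scores, graph, st, key)
            es = environmental_score(scores, graph, key)
            if graph.adjacency[key]:
                assert csv.sum() == pytest.approx(es, abs=1e-12)

    def test_two_ala_neighbours_aggregate(self):
        st = generate_point_cloud(3, seed=9)
        st.residues[1].res_type = "ALA"
        st.residues[2].res_type = "ALA"
        i, j, k = (r.key for r in st.residues)
        g = ContactGraph(nodes=[i], adjacency={i: {j: 1, k: 1}}, mode="voronoi")
        csv = contact_score_vector({i: 0.0, j: 0.4, k: 0.8}, g, st, i)
        from vorsite.constants import AMINO_ACIDS

        assert csv[AMINO_ACIDS.index("ALA")] == pytest.approx(0.6)

    def test_max_min_scores_adopted_definition(self):
        st = generate_point_cloud(3, seed=10)
        i, j, k = (r.key for r in st.residues)
        g = ContactGraph(nodes=[i], adjacency={i: {j: 1, k: 9}}, mode="voronoi")
        scores = {i: 0.5, j: 0.9, k: 0.2}
        wmax, wmin, smax, smin = max_min_scores(scores, g, i)
        assert (wmax, wmin) == pytest.approx((0.18, 0.09))
        assert (smax, smin) == pytest.approx((0.9, 0.2))

    def test_max_min_degenerate_single_neighbour(self):
        st = generate_point_cloud(2, seed=11)
        i, j = (r.key for r in st.residues)
        g = ContactGraph(nodes=[i], adjacency={i: {j: 2}}, mode="voronoi")
        assert max_min_scores({i: 0.1, j: 0.5}, g, i) == pytest.approx(
            (0.5, 0.5, 0.5, 0.5)
        )

    def test_weighted_bounded_by_raw(self, scored_cloud):
        st, graph, scores = scored_cloud
        for key in graph.nodes:
            wmax, wmin, smax, smin = max_min_scores(scores, graph, key)
            assert wmax <= smax + 1e-12
            assert wmin <= smin + 1e-12

    def test_isolated_residue_falls_back_to_own_score(self):
        st = generate_point_cloud(2, seed=12)
        i, j = (r.key for r in st.residues)
        g = ContactGraph(nodes=[i, j], adjacency={i: {}, j: {}}, mode="none")
        assert environmental_score({i: 0.3, j: 0.6}, g, i) == pytest.approx(0.3)
        fb = feedback_table({i: 0.3, j: 0.6}, g, st)
        assert (fb["score_isolated"] == 1.0).all()

    def test_unscored_neighbour_rejected(self, scored_cloud):
        st, graph, scores = scored_cloud
        incomplete = dict(scores)
        connected = next(k for k in graph.nodes if graph.adjacency[k])
        del incomplete[graph.neighbours(connected)[0]]
        with pytest.raises(ConsistencyError):
            environmental_score(incomplete, graph, connected)


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        model = TwoStepInterfacePredictor(n_estimators=10, random_state=3)
        params = model.get_params()
        assert params["n_estimators"] == 10
        clone = TwoStepInterfacePredictor(**params)
        assert clone.get_params() == params

    def test_requires_two_structures_and_two_classes(self):
        structures, msas, _ = make_chain_dataset(1, base_seed=50)
        model = TwoStepInterfacePredictor(n_estimators=10, random_state=0)
        with pytest.raises(TrainingError):
            model.fit(structures[:1], msas=msas[:1])
        # force single-class labels
        st_all, msa_all, _ = make_chain_dataset(2, base_seed=51)
        for st in st_all:
            for r in st.residues:
                r.interface_label = False
        with pytest.raises(TrainingError):
            model.fit(st_all, msas=msa_all)

    def test_training_is_deterministic(self):
        structures, msas, _ = make_chain_dataset(2, base_seed=60, n_residues=20)
        scores = []
        for _ in range(2):
            model = TwoStepInterfacePredictor(
                n_estimators=30, inner_folds=2, random_state=5
            )
            model.fit(copy.deepcopy(structures), msas=msas)
            ss = model.score_structure(copy.deepcopy(structures[0]), msa=msas[0])
            scores.append(ss.table["final_score"].to_numpy())
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_planted_interface_scores_higher(self, trained_model_and_test_set):
        model, _, _, test_s, test_m = trained_model_and_test_set
        pos, neg = [], []
        for st, m in zip(test_s, test_m):
            ss = model.score_structure(st, msa=m)
            for k, v in ss.final_scores().items():
                (pos if st.get(k).interface_label else neg).append(v)
        assert np.mean(pos) > np.mean(neg)

    def test_prediction_is_deterministic_and_bundle_roundtrips(
        self, tmp_path, trained_model_and_test_set
    ):
        model, _, _, test_s, test_m = trained_model_and_test_set
        a = model.score_structure(copy.deepcopy(test_s[0]), msa=test_m[0])
        b = model.score_structure(copy.deepcopy(test_s[0]), msa=test_m[0])
        np.testing.assert_array_equal(
            a.table["final_score"].to_numpy(), b.table["final_score"].to_numpy()
        )
        path = tmp_path / "bundle.joblib"
        model.save(path)
        loaded = TwoStepInterfacePredictor.load(path)
        c = loaded.score_structure(copy.deepcopy(test_s[0]), msa=test_m[0])
        np.testing.assert_array_equal(
            a.table["final_score"].to_numpy(), c.table["final_score"].to_numpy()
        )

    def test_scores_bounded_and_cover_exposed_residues(
        self, trained_model_and_test_set
    ):
        model, _, _, test_s, test_m = trained_model_and_test_set
        st = copy.deepcopy(test_s[0])
        ss = model.score_structure(st, msa=test_m[0])
        exposed = [r.key for r in st.exposed_residues()]
        assert set(ss.final_scores()) == set(exposed)
        vals = ss.table[["first_step_score", "final_score"]].to_numpy()
        assert ((vals >= 0.0) & (vals <= 1.0)).all()

    def test_missing_msa_for_conservation_model(self, trained_model_and_test_set):
        model, _, _, test_s, _ = trained_model_and_test_set
        with pytest.raises(InputError, match="conservation"):
            model.score_structure(copy.deepcopy(test_s[0]), msa=None)

    def test_no_exposed_residues_warns_and_returns_empty(
        self, trained_model_and_test_set
    ):
        model, _, _, test_s, test_m = trained_model_and_test_set
        st = copy.deepcopy(test_s[0])
        from vorsite.structure import compute_rsasa

        compute_rsasa(st)
        for r in st.residues:
            r.exposed = False
        with pytest.warns(UserWarning):
            ss = model.score_structure(st, msa=test_m[0])
        assert len(ss) == 0

    def test_second_step_not_worse_than_first_on_planted_patches(self):
        """Directional two-step property on spatially contiguous interfaces."""
        deltas = []
        for seed in range(3):
            structures, msas, _ = make_chain_dataset(
                5, base_seed=700 + 13 * seed, n_residues=30
            )
            auc1, auc2 = heldout_auc_pair(
                structures[:6], msas[:6], structures[6:], msas[6:],
                n_estimators=60, inner_folds=3, random_state=seed,
            )
            deltas.append(auc2 - auc1)
        assert min(deltas) >= -0.02
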