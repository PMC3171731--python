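"""Residue features, conservation, and the EF/CDV/EDM descriptors."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from vorsite.constants import AMINO_ACIDS
from vorsite.env import ContactGraph, EnvConfig, sphere_neighbours
from vorsite.errors import ConservationError, ConsistencyError, InputError
from vorsite.features import (
    EDM_COLUMNS,
    assemble_design_matrix,
    contact_description_vector,
    environment_description_matrix,
    environment_features,
    edm_table,
    feature_registry,
    key_index,
    residue_features,
)
from vorsite.structure import compute_rsasa
from vorsite.synthetic import build_complex, FixtureSpec, generate_point_cloud


@pytest.fixture(scope="module")
def chain_with_sasa(planted_complex):
    st, _, _ = planted_complex
    chain = st.subset(["A"])
    return compute_rsasa(chain)


class TestResidueFeatures:
    def test_registry_contains_only_requested_groups(self):
        reg = feature_registry(("s", "b"))
        groups = {g for _, g in reg}
        assert groups == {"s", "b"}
        with pytest.raises(InputError):
            feature_registry(("s", "x"))

    def test_uniform_bfactors_give_zero_zscores(self, chain_with_sasa):
        st = copy.deepcopy(chain_with_sasa)
        for r in st.residues:
            for a in r.atoms:
                a.b_factor = 25.0
        fv = residue_features(st, groups=("b",))
        assert (fv["bfactor_z"] == 0.0).all()

    def test_missing_groups_absent_not_zero_filled(self, chain_with_sasa):
        fv = residue_features(chain_with_sasa, groups=("s",))
        assert "bfactor_z" not in fv.columns
        assert "desolvation" not in fv.columns

    def test_conservation_requires_alignment(self, chain_with_sasa):
        with pytest.raises(InputError):
            residue_features(chain_with_sasa, groups=("c",))

    def test_mismatched_alignment_rejected(self, chain_with_sasa):
        n = len(chain_with_sasa.residues)
        rows = ["A" * n] * 5  # will not match the chain sequence
        with pytest.raises(ConservationError):
            residue_features(chain_with_sasa, msa={"A": rows}, groups=("c",))

    def test_entropy_limits(self, chain_with_sasa, planted_complex):
        _, _, msas = planted_complex
        st = chain_with_sasa
        seq = msas["A"][0]
        # fully conserved alignment -> entropy 0 everywhere
        fv = residue_features(st, msa={"A": [seq] * 30}, groups=("c",))
        assert np.allclose(fv["cons_entropy"], 0.0)
        # uniform column over the 20 types -> entropy log2(20) at that column
        letters = "ACDEFGHIKLMNPQRSTVWY"
        rows = [seq] + [letters[i] + seq[1:] for i in range(20) for _ in (0,)]
        fv = residue_features(st, msa={"A": rows}, groups=("c",))
        first_key = st.residues[0].key
        ent = fv.loc[tuple(first_key), "cons_entropy"]
        # 21 rows: the reference letter appears twice among 21
        col = [r[0] for r in rows]
        p = np.array([col.count(ch) / len(col) for ch in set(col)])
        expected = -(p * np.log2(p)).sum()
        assert ent == pytest.approx(expected, abs=1e-12)

    def test_max_entropy_is_log2_20(self):
        from vorsite.features import _column_stats

        letters = "ACDEFGHIKLMNPQRSTVWY"
        ent, rel = _column_stats(letters)
        assert ent == pytest.approx(math.log2(20), abs=1e-12)


def uniform_graph(structure, radius=8.0):
    return sphere_neighbours(
        structure, radius, EnvConfig(mode="sphere", exposed_only=False)
    )


class TestEnvironmentFeatures:
    def test_weighted_average_example(self, point_cloud_50):
        st = generate_point_cloud(3, seed=1)
        i, j, k = (r.key for r in st.residues)
        graph = ContactGraph(
            nodes=[i], adjacency={i: {j: 3, k: 1}}, mode="voronoi"
        )
        fv = pd.DataFrame(
            {"f": [0.0, 2.0, 4.0]}, index=key_index([i, j, k])
        )
        ef = environment_features(fv, graph)
        assert ef.loc[tuple(i), "f"] == pytest.approx(0.75 * 2 + 0.25 * 4)

    def test_constant_field_is_reproduced(self, point_cloud_50):
        graph = uniform_graph(point_cloud_50)
        keys = [r.key for r in point_cloud_50.residues]
        fv = pd.DataFrame({"f": 3.25}, index=key_index(keys))
        ef = environment_features(fv, graph)
        for key in graph.nodes:
            if graph.adjacency[key]:
                assert ef.loc[tuple(key), "f"] == pytest.approx(3.25, abs=1e-12)

    def test_matches_double_loop_oracle(self, point_cloud_50):
        rng = np.random.default_rng(0)
        graph = uniform_graph(point_cloud_50)
        keys = [r.key for r in point_cloud_50.residues]
        fv = pd.DataFrame(
            rng.normal(size=(len(keys), 3)),
            index=key_index(keys),
            columns=["a", "b", "c"],
        )
        ef = environment_features(fv, graph)
        for key in graph.nodes:
            expected = np.zeros(3)
            for j, c in graph.strengths(key).items():
                expected += c * fv.loc[tuple(j)].to_numpy()
            np.testing.assert_allclose(
                ef.loc[tuple(key)].to_numpy(), expected, atol=1e-12
            )

    def test_missing_neighbour_features_rejected(self, point_cloud_50):
        graph = uniform_graph(point_cloud_50)
        keys = [r.key for r in point_cloud_50.residues][:10]
        fv = pd.DataFrame({"f": 1.0}, index=key_index(keys))
        with pytest.raises(ConsistencyError):
            environment_features(fv, graph)


class TestCdv:
    def test_type_aggregation(self):
        st = generate_point_cloud(4, seed=2)
        st.residues[1].res_type = "ALA"
        st.residues[2].res_type = "ALA"
        st.residues[3].res_type = "GLY"
        i, j, k, l = (r.key for r in st.residues)
        graph = ContactGraph(
            nodes=[i], adjacency={i: {j: 3, k: 2, l: 5}}, mode="voronoi"
        )
        cdv = contact_description_vector(graph, st)
        assert cdv.loc[tuple(i), "cdv_ALA"] == pytest.approx(0.5)
        assert cdv.loc[tuple(i), "cdv_GLY"] == pytest.approx(0.5)
        assert cdv.loc[tuple(i)].sum() == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one_or_zero(self, point_cloud_50):
        graph = uniform_graph(point_cloud_50)
        cdv = contact_description_vector(graph, point_cloud_50)
        for key in graph.nodes:
            total = cdv.loc[tuple(key)].sum()
            expected = 1.0 if graph.adjacency[key] else 0.0
            assert total == pytest.approx(expected, abs=1e-12)


class TestEdm:
    def test_worked_example(self):
        st = generate_point_cloud(4, seed=3)
        st.residues[1].res_type = "ALA"
        st.residues[2].res_type = "ALA"
        st.residues[3].res_type = "GLY"
        i, j, k, l = (r.key for r in st.residues)
        # environment {Ala(j), Ala(k), Gly(l)}: N(j,k)=2 (Ala-Ala),
        # N(j,l)=2 (Ala-Gly), the (k,l) pair not in contact
        adjacency = {
            i: {j: 1, k: 1, l: 1},
            j: {i: 1, k: 2, l: 2},
            k: {i: 1, j: 2},
            l: {i: 1, j: 2},
        }
        graph = ContactGraph(nodes=[i, j, k, l], adjacency=adjacency, mode="voronoi")
        edm = environment_description_matrix(graph, st, i)
        ala = AMINO_ACIDS.index("ALA")
        gly = AMINO_ACIDS.index("GLY")
        assert edm[ala, ala] == pytest.approx(0.5)
        assert edm[ala, gly] == pytest.approx(0.5)
        assert edm[gly, ala] == pytest.approx(0.5)  # symmetric storage
        triu = edm[np.triu_indices(20)]
        assert triu.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_contact_pair(self):
        st = generate_point_cloud(3, seed=4)
        i, j, k = (r.key for r in st.residues)
        graph = ContactGraph(
            nodes=[i, j, k],
            adjacency={i: {j: 1, k: 1}, j: {i: 1, k: 4}, k: {i: 1, j: 4}},
            mode="voronoi",
        )
        edm = environment_description_matrix(graph, st, i)
        assert edm[np.triu_indices(20)].sum() == pytest.approx(1.0)
        assert np.count_nonzero(edm[np.triu_indices(20)]) == 1

    def test_unordered_type_pairs_sum_to_one(self, point_cloud_50):
        graph = uniform_graph(point_cloud_50, radius=10.0)
        table = edm_table(graph, point_cloud_50)
        for key in graph.nodes:
            nbrs = graph.neighbours(key)
            internal = sum(
                1
                for a in range(len(nbrs))
                for b in range(a + 1, len(nbrs))
                if graph.facet_count(nbrs[a], nbrs[b])
            )
            total = table.loc[tuple(key)].sum()
            assert total == pytest.approx(1.0 if internal else 0.0, abs=1e-12)


class TestDesignMatrix:
    def test_no_environment_block_in_none_mode(self, chain_with_sasa):
        from vorsite.env import empty_neighbours

        graph = empty_neighbours(chain_with_sasa)
        X = assemble_design_matrix(chain_with_sasa, graph, groups=("s", "b"))
        assert not any(c.startswith(("ef_", "cdv_", "edm_")) for c in X.columns)

    def test_environment_blocks_present_and_finite(self, chain_with_sasa):
        from vorsite.env import voronoi_neighbours

        graph = voronoi_neighbours(chain_with_sasa, EnvConfig())
        X = assemble_design_matrix(chain_with_sasa, graph, groups=("s", "e", "b"))
        assert any(c.startswith("ef_") for c in X.columns)
        assert sum(c.startswith("cdv_") for c in X.columns) == 20
        assert sum(c.startswith("edm_") for c in X.columns) == len(EDM_COLUMNS) == 210
        assert np.isfinite(X.to_numpy()).all()
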