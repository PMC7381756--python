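import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import procrustes

from phylostruct import (
    CommunityMatrix,
    cophenetic_matrix,
    fuzzy_weights,
    matrix_p,
    parse_newick,
    pcoa,
    pcps_analysis,
    species_and_clade_scores,
)
from phylostruct.pcps import EUCLIDEAN
from phylostruct.trees import DistanceMatrix

from conftest import random_binary_newick


class TestFuzzyWeights:
    def test_equidistant_star_gives_identity(self):
        dm = cophenetic_matrix(parse_newick("(A:1,B:1,C:1);"))
        fw = fuzzy_weights(dm)
        assert np.allclose(fw.Q, np.eye(3))

    def test_zero_distance_pair(self):
        # A and B identical (d=0), C at d_max from both
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0.0, 0.0, 4.0], [0.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        fw = fuzzy_weights(dm)
        assert np.allclose(fw.Q[0], [0.5, 0.5, 0.0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        dm = cophenetic_matrix(parse_newick(random_binary_newick(rng, 15)))
        fw = fuzzy_weights(dm)
        assert np.allclose(fw.Q.sum(axis=1), 1.0, atol=1e-12)
        assert fw.Q.min() >= 0 and fw.Q.max() <= 1

    def test_diagonal_is_row_max(self):
        rng = np.random.default_rng(2)
        dm = cophenetic_matrix(parse_newick(random_binary_newick(rng, 10)))
        Q = fuzzy_weights(dm).Q
        assert np.all(np.argmax(Q, axis=1) == np.arange(10))

    def test_all_zero_distances_error(self):
        dm = DistanceMatrix(labels=["A", "B"], values=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="d_max"):
            fuzzy_weights(dm)


class TestMatrixP:
    def test_identity_weights_give_row_normalized_w(self, two_clade_community):
        n = 6
        labels = two_clade_community.species_names
        dm = DistanceMatrix(
            labels=labels, values=(np.ones((n, n)) - np.eye(n)) * 2.0
        )
        fw = fuzzy_weights(dm)  # equidistant -> identity
        P = matrix_p(two_clade_community, fw)
        W = two_clade_community.incidence.to_numpy(dtype=float)
        assert np.allclose(P.to_numpy(), W / W.sum(axis=1, keepdims=True))

    def test_single_species_site_equals_q_row(self, two_clade_tree):
        inc = pd.DataFrame(
            [[1, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 1, 1]],
            index=["solo", "s2", "s3"],
            columns=["u1", "u2", "u3", "v1", "v2", "v3"],
        )
        cm = CommunityMatrix(incidence=inc)
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        P = matrix_p(cm, fw)
        j = fw.labels.index("u1")
        order = [fw.labels.index(s) for s in cm.species_names]
        assert np.allclose(P.loc["solo"].to_numpy(), fw.Q[j, order])

    def test_clade_mass_concentrates(self, two_clade_tree, two_clade_community):
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        P = matrix_p(two_clade_community, fw)
        clade_u = [c for c in P.columns if c.startswith("u")]
        assert P.loc["s0", clade_u].sum() > 0.5  # site of u-species only

    def test_rows_sum_to_one(self, two_clade_tree, two_clade_community):
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        P = matrix_p(two_clade_community, fw)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_species_mismatch_error(self, two_clade_tree):
        inc = pd.DataFrame([[1, 1]], index=["s"], columns=["u1", "zz"])
        cm = CommunityMatrix(incidence=inc)
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        with pytest.raises(ValueError, match="mismatch"):
            matrix_p(cm, fw)


class TestPCoA:
    def test_two_groups_separate_on_axis_1(self):
        P = pd.DataFrame(
            [[0.9, 0.1, 0.0], [0.9, 0.1, 0.0], [0.0, 0.1, 0.9], [0.0, 0.1, 0.9]],
            index=["a1", "a2", "b1", "b2"],
            columns=["x", "y", "z"],
        )
        eig, pct, scores = pcoa(P)
        z = scores["pcps_1"]
        assert z["a1"] == pytest.approx(z["a2"], abs=1e-9)
        assert z["b1"] == pytest.approx(z["b2"], abs=1e-9)
        assert abs(z["a1"] - z["b1"]) > 0.1

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        P = pd.DataFrame(X, index=[f"s{i:02d}" for i in range(12)])
        eig, pct, scores = pcoa(P, distance=EUCLIDEAN)
        _, _, disparity = procrustes(X, scores.to_numpy()[:, :2])
        assert disparity < 1e-16

    def test_percentages_sum_to_100(self, two_clade_tree, two_clade_community):
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        P = matrix_p(two_clade_community, fw)
        eig, pct, _ = pcoa(P)
        assert pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(eig) <= 1e-12)  # non-increasing

    def test_degenerate_ordination_error(self):
        P = pd.DataFrame(np.tile([0.5, 0.5], (4, 1)), index=list("abcd"))
        with pytest.raises(ValueError, match="degenerate"):
            pcoa(P)

    def test_site_order_invariance(self, two_clade_tree, two_clade_community):
        # compare eigenvalues on all axes but scores only on well-separated
        # leading axes; near-degenerate trailing pairs rotate freely
        fw = fuzzy_weights(cophenetic_matrix(two_clade_tree))
        P = matrix_p(two_clade_community, fw)
        e1, _, s1 = pcoa(P)
        e2, _, s2 = pcoa(P.iloc[::-1])
        assert np.allclose(e1, e2, atol=1e-9)
        lead = ["pcps_1", "pcps_2"]
        pd.testing.assert_frame_equal(
            s1[lead], s2.loc[s1.index, lead], atol=1e-8, rtol=0
        )


class TestSpeciesCladeScores:
    def test_single_occurrence_species_with_identity_q(self):
        n = 4
        inc = pd.DataFrame(
            np.eye(n, dtype=int), index=[f"s{i}" for i in range(n)],
            columns=[f"sp{i}" for i in range(n)],
        )
        cm = CommunityMatrix(incidence=inc)
        dm = DistanceMatrix(
            labels=list(inc.columns), values=(np.ones((n, n)) - np.eye(n)) * 2.0
        )
        P = matrix_p(cm, fuzzy_weights(dm))
        _, _, site_scores = pcoa(P, distance=EUCLIDEAN)
        sp_scores, _ = species_and_clade_scores(P, site_scores)
        for i in range(n):
            assert np.allclose(
                sp_scores.loc[f"sp{i}"].to_numpy(),
                site_scores.loc[f"s{i}"].to_numpy(),
                atol=1e-9,
            )

    def test_singleton_clade_centroid(self, two_clade_tree, two_clade_community):
        res = pcps_analysis(
            cophenetic_matrix(two_clade_tree),
            two_clade_community,
            clade_map={"u1": "solo", "u2": "rest", "u3": "rest",
                       "v1": "rest", "v2": "rest", "v3": "rest"},
        )
        assert np.allclose(
            res.clade_centroids.loc["solo"].to_numpy(),
            res.species_scores.loc["u1"].to_numpy(),
        )

    def test_two_clade_centroids_oppose_on_axis_1(self, two_clade_tree, two_clade_community):
        clade_map = {f"u{i}": "cladeU" for i in (1, 2, 3)}
        clade_map.update({f"v{i}": "cladeV" for i in (1, 2, 3)})
        res = pcps_analysis(
            cophenetic_matrix(two_clade_tree), two_clade_community, clade_map=clade_map
        )
        c = res.clade_centroids["pcps_1"]
        assert c["cladeU"] * c["cladeV"] < 0


@given(seed=st.integers(0, 5_000))
@settings(max_examples=15, deadline=None)
def test_q_and_p_row_stochastic_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 12))
    tree = parse_newick(random_binary_newick(rng, n))
    dm = cophenetic_matrix(tree)
    fw = fuzzy_weights(dm)
    assert np.allclose(fw.Q.sum(axis=1), 1.0, atol=1e-12)
    n_sites = int(rng.integers(3, 8))
    inc = (rng.random((n_sites, n)) < 0.5).astype(int)
    inc[inc.sum(axis=1) == 0, 0] = 1
    keep = inc.sum(axis=0) > 0
    cm = CommunityMatrix(
        incidence=pd.DataFrame(
            inc[:, keep],
            index=[f"s{i}" for i in range(n_sites)],
            columns=np.array(dm.labels)[keep],
        )
    )
    sub = DistanceMatrix(
        labels=list(np.array(dm.labels)[keep]),
        values=dm.values[np.ix_(keep.nonzero()[0], keep.nonzero()[0])],
    )
    P = matrix_p(cm, fuzzy_weights(sub))
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
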