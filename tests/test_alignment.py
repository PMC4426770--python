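import itertools

import numpy as np
import pytest

from pnetalign import (
    IterationConfig,
    SeqSimilarity,
    SimilarityVector,
    UncertainNetwork,
    align,
    deterministic_support_matrix,
    expected_support_matrix,
    extract_alignment,
    normalize_seqsim,
    power_iterate,
)


def brute_force_matching_weight(weights: np.ndarray) -> float:
    """Independent oracle: maximum over all injections of the smaller side."""
    m, n = weights.shape
    if m > n:
        return brute_force_matching_weight(weights.T)
    best = -np.inf
    for cols in itertools.permutations(range(n), m):
        best = max(best, sum(weights[i, j] for i, j in enumerate(cols)))
    return float(best)


class TestNormalizeSeqsim:
    def test_l1_scaling(self):
        sim = SeqSimilarity({("a", "x"): 3.0, ("b", "y"): 1.0})
        vec = normalize_seqsim(sim, ["a", "b"], ["x", "y"])
        assert vec.values == pytest.approx(np.array([[0.75, 0.0], [0.0, 0.25]]))

    def test_empty_table_uniform_fallback(self):
        vec = normalize_seqsim(SeqSimilarity(), ["a", "b"], ["x", "y"])
        assert vec.values == pytest.approx(np.full((2, 2), 0.25))

    def test_all_zero_table_uniform_fallback(self):
        sim = SeqSimilarity({("a", "x"): 0.0})
        vec = normalize_seqsim(sim, ["a", "b"], ["x", "y"])
        assert vec.values == pytest.approx(np.full((2, 2), 0.25))

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            SeqSimilarity({("a", "x"): -1.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_output_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        nodes1 = [f"a{i}" for i in range(4)]
        nodes2 = [f"b{i}" for i in range(3)]
        sim = SeqSimilarity({(a, b): float(rng.random())
                             for a in nodes1 for b in nodes2})
        vec = normalize_seqsim(sim, nodes1, nodes2)
        assert vec.flat.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_pairs_ignored(self):
        sim = SeqSimilarity({("zzz", "x"): 5.0, ("a", "x"): 1.0})
        vec = normalize_seqsim(sim, ["a"], ["x"])
        assert vec.values == pytest.approx(np.array([[1.0]]))


class TestIterationConfig:
    def test_defaults(self):
        cfg = IterationConfig()
        assert cfg.alpha == 0.6 and cfg.eps == 1e-6 and cfg.max_iter == 1000

    @pytest.mark.parametrize("kwargs", [
        {"alpha": -0.1}, {"alpha": 1.1}, {"eps": 0.0}, {"max_iter": 0},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            IterationConfig(**kwargs)


class TestPowerIterate:
    def test_alpha_zero_returns_seqsim_vector(self, star_net):
        g2 = UncertainNetwork(edges=[("x", "y", 0.7)])
        EA = expected_support_matrix(star_net, g2)
        rng = np.random.default_rng(0)
        grid = rng.random((3, 2))
        evec = SimilarityVector(grid / grid.sum())
        R, info = power_iterate(EA, evec, IterationConfig(alpha=0.0))
        assert np.array_equal(R.values, evec.values)
        assert info.converged

    def test_dimension_mismatch_rejected(self, star_net):
        g2 = UncertainNetwork(edges=[("x", "y", 0.7)])
        EA = expected_support_matrix(star_net, g2)
        with pytest.raises(ValueError, match="mismatch"):
            power_iterate(EA, SimilarityVector.uniform(2, 2))

    def test_non_convergence_flagged_not_raised(self, star_net):
        g2 = UncertainNetwork(edges=[("x", "y", 0.7), ("y", "z", 0.4)])
        EA = expected_support_matrix(star_net, g2)
        R, info = power_iterate(EA, SimilarityVector.uniform(3, 3),
                                IterationConfig(eps=1e-15, max_iter=2))
        assert not info.converged
        assert R.flat.sum() == pytest.approx(1.0)

    def test_residual_contract(self, star_net):
        g2 = UncertainNetwork(edges=[("x", "y", 0.7), ("y", "z", 0.4)])
        EA = expected_support_matrix(star_net, g2)
        evec = SimilarityVector.uniform(3, 3)
        for alpha in (0.3, 0.6, 0.9):
            cfg = IterationConfig(alpha=alpha)
            R, info = power_iterate(EA, evec, cfg)
            assert info.converged
            fixed_point = alpha * EA.matvec(R.flat) + (1 - alpha) * evec.flat
            residual = np.abs(R.flat - fixed_point).sum()
            assert residual <= cfg.eps * (1 + alpha)

    def test_self_alignment_symmetry(self):
        # identical copies with uniform seqsim: R must be symmetric under the
        # automorphism exchanging the two copies (R[i,j] == R[j,i])
        g = UncertainNetwork(
            edges=[("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        EA = expected_support_matrix(g, g)
        R, _ = power_iterate(EA, SimilarityVector.uniform(4, 4))
        assert R.values == pytest.approx(R.values.T, abs=1e-9)


class TestExtractAlignment:
    def test_diagonal_dominance(self):
        R = SimilarityVector(np.array([[2.0, 1.0], [1.0, 2.0]]))
        a = extract_alignment(R, ["r1", "r2"], ["c1", "c2"])
        assert a.pairs == [("r1", "c1"), ("r2", "c2")]
        assert a.total_weight == pytest.approx(4.0)

    def test_recovers_permutation(self):
        perm = [2, 0, 3, 1]
        W = np.zeros((4, 4))
        for i, j in enumerate(perm):
            W[i, j] = 1.0
        a = extract_alignment(SimilarityVector(W))
        assert a.as_mapping() == {str(i): str(j) for i, j in enumerate(perm)}

    def test_rectangular_cardinality(self):
        rng = np.random.default_rng(1)
        a = extract_alignment(SimilarityVector(rng.random((3, 5))))
        assert len(a.pairs) == 3

    def test_one_to_one_enforced(self):
        rng = np.random.default_rng(2)
        a = extract_alignment(SimilarityVector(rng.random((5, 5))))
        assert len({p[0] for p in a.pairs}) == 5
        assert len({p[1] for p in a.pairs}) == 5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 7))
        n = int(rng.integers(1, 7))
        W = rng.random((m, n))
        a = extract_alignment(SimilarityVector(W))
        assert a.total_weight == pytest.approx(
            brute_force_matching_weight(W), abs=1e-9)

    def test_tie_break_is_lexicographic(self):
        # all-equal weights: every matching is optimal; the identity pairing
        # is the lexicographically smallest
        W = np.ones((3, 3))
        a = extract_alignment(SimilarityVector(W))
        assert a.pairs == [("0", "0"), ("1", "1"), ("2", "2")]

    def test_deterministic_repeatability(self):
        rng = np.random.default_rng(3)
        W = rng.random((6, 6))
        a1 = extract_alignment(SimilarityVector(W.copy()))
        a2 = extract_alignment(SimilarityVector(W.copy()))
        assert a1.pairs == a2.pairs


class TestAlignPipeline:
    def test_identical_triangles_full_cardinality(self, triangle_det):
        res = align(triangle_det, triangle_det)
        assert len(res.alignment.pairs) == 3
        assert res.info.converged

    def test_all_p_one_matches_deterministic_path(self, triangle_det):
        g2 = UncertainNetwork(
            edges=[("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0), ("z", "w", 1.0)])
        res = align(triangle_det, g2)
        det = deterministic_support_matrix(
            triangle_det.to_deterministic(), g2.to_deterministic())
        evec = normalize_seqsim(None, triangle_det.nodes, g2.nodes)
        R_det, _ = power_iterate(det, evec)
        assert np.array_equal(res.similarity.values, R_det.values)
        assert res.alignment.pairs == extract_alignment(
            R_det, triangle_det.nodes, g2.nodes).pairs

    def test_planted_mapping_recovered_with_strong_seqsim(self):
        from pnetalign.synthetic import (GeneratorConfig, generate_seqsim,
                                         generate_uncertain_network,
                                         perturb_network)

        cfg = GeneratorConfig(n_nodes=10, density=0.3,
                              prob_law=("uniform", 0.4, 1.0), seed=5)
        g1 = generate_uncertain_network(cfg)
        g2, mapping = perturb_network(g1, 0.0, 0.0, seed=6)
        sim = generate_seqsim(mapping, signal=50.0, noise=0.5, seed=7,
                              nodes1=g1.nodes, nodes2=g2.nodes)
        res = align(g1, g2, sim)
        assert res.alignment.as_mapping() == mapping

    def test_seqsim_scale_invariance(self, star_net):
        g2 = UncertainNetwork(edges=[("x", "y", 0.7), ("y", "z", 0.4)])
        base = SeqSimilarity({("a", "x"): 2.0, ("b", "y"): 1.0, ("c", "z"): 3.0})
        scaled = SeqSimilarity({k: 17.5 * v for k, v in base.items()})
        r1 = align(star_net, g2, base)
        r2 = align(star_net, g2, scaled)
        assert np.array_equal(r1.similarity.values, r2.similarity.values)
        assert r1.alignment.pairs == r2.alignment.pairs
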