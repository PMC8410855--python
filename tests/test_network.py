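"""Adjacency/TOM closed forms, eigengene SVD oracle, soft-threshold
selection, and planted-module detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modflex.expression import ExpressionMatrix
from modflex.network import (
    build_adjacency,
    build_network,
    compute_tom,
    detect_modules,
    module_eigengene,
    pick_soft_threshold,
)
from modflex.simulate import SimulationConfig, simulate_study


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


# two genes with exact Pearson correlation 0.5
_HALF_COR = _em([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        em = _em([[1, 2, 3, 4], [2, 4, 6, 8]])
        a = build_adjacency(em, power=7)
        assert a[0, 1] == pytest.approx(1.0)

    def test_unsigned_closed_form(self):
        a = build_adjacency(_HALF_COR, power=6, signed=False)
        assert a[0, 1] == pytest.approx(0.5**6, abs=1e-12)  # 0.015625

    def test_signed_closed_form(self):
        a = build_adjacency(_HALF_COR, power=6, signed=True)
        assert a[0, 1] == pytest.approx(0.75**6, abs=1e-12)  # 0.177978515625

    def test_zero_variance_gene_named(self):
        em = _em([[1, 1, 1], [1, 2, 3]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            build_adjacency(em, power=6)

    def test_power_below_one_rejected(self, noise_matrix):
        with pytest.raises(ValueError):
            build_adjacency(noise_matrix, power=0.5)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
    def test_raising_power_weakly_decreases_entries(self, beta, seed):
        rng = np.random.default_rng(seed)
        em = _em(rng.standard_normal((8, 10)))
        lo = build_adjacency(em, power=beta)
        hi = build_adjacency(em, power=beta + 1)
        off = ~np.eye(8, dtype=bool)
        assert (hi[off] <= lo[off] + 1e-12).all()


class TestTOM:
    def test_hand_evaluated_three_gene_case(self):
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        tom = compute_tom(a)
        # (0.2*0.4 + 0.5) / (min(0.7, 0.9) + 1 - 0.5) = 0.58 / 1.2
        assert tom[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)

    def test_identical_neighbor_profiles_give_unit_overlap(self):
        # genes 0 and 1: fully adjacent with identical (binary) neighborhoods
        a = np.array(
            [
                [1.0, 1.0, 1.0, 0.0],
                [1.0, 1.0, 1.0, 0.0],
                [1.0, 1.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        assert compute_tom(a)[0, 1] == pytest.approx(1.0)

    def test_empty_adjacency_gives_zero_overlap(self):
        a = np.eye(5)
        tom = compute_tom(a)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(tom[off], 0.0)
        assert np.allclose(np.diag(tom), 1.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_and_symmetry_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0, 1, size=(10, 10))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = compute_tom(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(tom), 1.0)


class TestEigengene:
    def test_identical_genes_give_shared_profile(self):
        profile = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        em = _em(np.tile(profile, (4, 1)))
        ev = module_eigengene(em, em.gene_ids)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(ev.to_numpy(), z, atol=1e-10)

    def test_single_gene_module_is_zscore(self):
        g = np.array([2.0, 7.0, 1.0, 4.0])
        em = _em(g[None, :])
        ev = module_eigengene(em, ["G0"])
        np.testing.assert_allclose(ev.to_numpy(), (g - g.mean()) / g.std(ddof=1), atol=1e-12)

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(5)
        em = _em(rng.standard_normal((2, 8)))
        v = em.values
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1, keepdims=True)
        # independent route: eigenvector of the samples x samples Gram matrix
        w, vecs = np.linalg.eigh(z.T @ z)
        pc = vecs[:, np.argmax(w)]
        pc = pc / pc.std(ddof=1)
        if np.corrcoef(pc, z.mean(axis=0))[0, 1] < 0:
            pc = -pc
        ev = module_eigengene(em, em.gene_ids)
        np.testing.assert_allclose(ev.to_numpy(), pc, atol=1e-10)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        em = _em(rng.standard_normal((6, 9)))
        a = module_eigengene(em, em.gene_ids)
        b = module_eigengene(em, em.gene_ids[::-1])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_zero_variance_gene_excluded(self):
        em = _em([[1, 1, 1, 1], [1, 2, 3, 4], [2, 4, 6, 8]])
        ev = module_eigengene(em, em.gene_ids)
        g = np.array([1.0, 2, 3, 4])
        np.testing.assert_allclose(ev.to_numpy(), (g - g.mean()) / g.std(ddof=1), atol=1e-10)


class TestSoftThreshold:
    def test_single_candidate_returned(self, noise_matrix):
        assert pick_soft_threshold(noise_matrix, candidate_powers=[9]) == 9.0

    def test_noise_falls_back_with_warning(self, caplog):
        # moderate powers cannot make null correlations look scale-free
        # (very aggressive powers can, by inflating the |r| tail), so the
        # selector must fall back to the best-fitting candidate and warn
        rng = np.random.default_rng(0)
        big_noise = _em(rng.standard_normal((250, 40)))
        with caplog.at_level("WARNING"):
            beta = pick_soft_threshold(big_noise, candidate_powers=(2, 4, 6, 8))
        assert any("falling back" in r.message for r in caplog.records)
        assert beta in (2, 4, 6, 8)

    def test_strong_one_factor_data_needs_small_power(self):
        study = simulate_study(
            SimulationConfig(n_genes=300, module_sizes=(60, 50, 40),
                             within_module_cor=0.95, deg_genes=0, seed=0)
        )
        beta = pick_soft_threshold(study.samples_for("DHI", "Day0"))
        assert beta <= 6

    def test_constant_expression_rejected(self):
        em = ExpressionMatrix(
            pd.DataFrame(np.ones((5, 6)), index=[f"G{i}" for i in range(5)],
                         columns=[f"S{i}" for i in range(6)])
        )
        with pytest.raises(ValueError):
            pick_soft_threshold(em)


class TestDetectModules:
    def test_planted_modules_recovered(self, small_study, small_partition):
        from sklearn.metrics import adjusted_rand_score

        x, net, part = small_partition
        truth = [small_study.truth["assignment"][g] for g in x.gene_ids]
        pred = [part.assignment[g] for g in x.gene_ids]
        assert adjusted_rand_score(truth, pred) >= 0.8
        assert len(part.module_labels) == 3

    def test_modules_ordered_by_size(self, small_partition):
        _, _, part = small_partition
        sizes = [len(part.genes_in(l)) for l in sorted(part.module_labels,
                                                       key=lambda l: int(l[1:]))]
        assert sizes == sorted(sizes, reverse=True)

    def test_eigengenes_unit_variance(self, small_partition):
        _, _, part = small_partition
        assert part.eigengenes is not None
        np.testing.assert_allclose(part.eigengenes.std(ddof=1), 1.0, atol=1e-8)

    def test_noise_matrix_yields_no_modules(self, noise_matrix):
        net = build_network(noise_matrix, 6)
        part = detect_modules(net.tom, expression=noise_matrix, min_module_size=10)
        assert len(part.module_labels) <= 1

    def test_single_module_spanning_all_genes(self):
        study = simulate_study(
            SimulationConfig(n_genes=60, module_sizes=(60,), dissolved_modules=(), deg_genes=0, seed=2)
        )
        x = study.samples_for("DHI", "Day0")
        net = build_network(x, 6)
        part = detect_modules(net.tom, expression=x, min_module_size=10)
        assert part.module_labels == ["M1"]
        assert (part.assignment == "M1").all()

    def test_min_module_size_guard(self, noise_matrix):
        net = build_network(noise_matrix, 6)
        with pytest.raises(ValueError):
            detect_modules(net.tom, min_module_size=2)

    def test_correlated_submodules_are_merged(self):
        # two halves of one factor-driven block: detection at a fine cut plus
        # eigengene merging must not split them
        rng = np.random.default_rng(8)
        f = rng.standard_normal(30)
        values = 0.9 * f + 0.2 * rng.standard_normal((40, 30))
        em = _em(values)
        net = build_network(em, 6)
        part = detect_modules(net.tom, expression=em, min_module_size=5, merge_height=0.25)
        assert len(part.module_labels) == 1
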