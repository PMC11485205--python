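"""Pruning, annotation filters, randomization, density, propagation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordshift.datatypes import RegulatoryModel
from coordshift.network_ops import (
    PropagationConfig,
    PruneConfig,
    gene_set_edge_density,
    largest_connected_component,
    propagate_scores,
    prune_residual_edges,
    randomize_targets,
    remove_same_arm_predictors,
    symmetrize,
)


def model_from(*triples):
    return RegulatoryModel(
        pd.DataFrame(triples, columns=["predictor", "target", "weight"])
    )


def random_model(rng, n_nodes=12, n_edges=20):
    nodes = [f"g{i}" for i in range(n_nodes)]
    seen = set()
    rows = []
    while len(rows) < n_edges:
        p, t = rng.choice(nodes, 2, replace=False)
        if (p, t) in seen:
            continue
        seen.add((p, t))
        rows.append((p, t, float(rng.normal()) or 0.1))
    return model_from(*rows)


class TestPrune:
    def test_asymmetric_reciprocal_pair_loses_weak_edge(self):
        m = model_from(("a", "b", 1.0), ("b", "a", 0.05), ("c", "d", 0.2))
        out = prune_residual_edges(m)  # r = 0.05/1.05 ~ 0.0476 < 0.1
        kept = set(zip(out.edges["predictor"], out.edges["target"]))
        assert kept == {("a", "b"), ("c", "d")}

    def test_balanced_pair_and_unpaired_edges_survive(self):
        m = model_from(("a", "b", 0.5), ("b", "a", 0.5), ("c", "d", 1e-6))
        out = prune_residual_edges(m)
        assert out.n_edges == 3  # r = 0.5 for the pair; no reciprocal for c->d

    def test_threshold_controls_removal(self):
        # r = 0.2/1.2 ~ 0.1667: kept at the 0.1 default, removed at 0.2
        m = model_from(("a", "b", 1.0), ("b", "a", 0.2))
        assert prune_residual_edges(m).n_edges == 2
        assert prune_residual_edges(m, PruneConfig(0.2)).n_edges == 1

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PruneConfig(0.6)


class TestSameArm:
    ann = pd.DataFrame(
        {
            "chromosome": ["1", "1", "1", "2"],
            "arm": ["p", "p", "q", "p"],
        },
        index=["a", "b", "c", "d"],
    )

    def test_same_arm_edge_removed_other_arms_kept(self):
        m = model_from(("a", "b", 1.0), ("a", "c", 1.0), ("a", "d", 1.0))
        out = remove_same_arm_predictors(m, self.ann)
        kept = set(zip(out.edges["predictor"], out.edges["target"]))
        assert kept == {("a", "c"), ("a", "d")}  # 1p->1p removed; 1p->1q, 1p->2p kept

    def test_unannotated_gene_keeps_edges_with_warning(self):
        m = model_from(("a", "x", 1.0))
        with pytest.warns(UserWarning, match="unannotated"):
            out = remove_same_arm_predictors(m, self.ann)
        assert out.n_edges == 1

    def test_malformed_arm_label_rejected(self):
        bad = pd.DataFrame({"chromosome": ["1"], "arm": ["z"]}, index=["a"])
        with pytest.raises(ValueError, match="arm"):
            remove_same_arm_predictors(model_from(("a", "b", 1.0)), bad)


class TestLargestComponent:
    def test_larger_component_wins(self):
        m = model_from(
            ("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "e", 1),
            ("x", "y", 1), ("y", "z", 1),
        )
        out = largest_connected_component(m)
        assert set(out.genes) == {"a", "b", "c", "d", "e"}

    def test_fully_connected_model_is_identity(self):
        m = model_from(("a", "b", 1), ("b", "c", 1))
        out = largest_connected_component(m)
        pd.testing.assert_frame_equal(out.edges, m.edges)

    def test_size_tie_broken_by_smallest_gene_id(self):
        m = model_from(("x", "y", 1), ("y", "z", 1), ("a", "b", 1), ("b", "c", 1))
        out = largest_connected_component(m)
        assert set(out.genes) == {"a", "b", "c"}


class TestRandomizeTargets:
    def test_pair_swap_exchanges_targets_keeping_weights_with_predictors(self):
        m = model_from(("a", "b", 0.5), ("c", "d", -0.2))
        out = randomize_targets(m, seed=0)
        edges = {
            (p, t): w for p, t, w in out.edges.itertuples(index=False, name=None)
        }
        assert edges == {("a", "d"): 0.5, ("c", "b"): -0.2}

    def test_degree_sequences_and_weight_multiset_preserved(self, rng):
        for _ in range(50):
            m = random_model(rng)
            out = randomize_targets(m, seed=int(rng.integers(2**31)))
            assert out.n_edges == m.n_edges
            assert sorted(out.edges["weight"]) == sorted(m.edges["weight"])
            for col in ("predictor", "target"):
                assert (
                    m.edges[col].value_counts().sort_index().equals(
                        out.edges[col].value_counts().sort_index()
                    )
                )

    def test_no_self_edges_or_duplicates_created(self, rng):
        for _ in range(20):
            m = random_model(rng, n_nodes=6, n_edges=14)
            out = randomize_targets(m, seed=3)
            assert not (out.edges["predictor"] == out.edges["target"]).any()
            assert not out.edges.duplicated(["predictor", "target"]).any()

    def test_deterministic_given_seed(self, rng):
        m = random_model(rng)
        pd.testing.assert_frame_equal(
            randomize_targets(m, seed=11).edges, randomize_targets(m, seed=11).edges
        )


class TestEdgeDensity:
    def test_three_gene_set_with_two_edges_has_density_two_thirds(self):
        m = model_from(("a", "b", 1), ("b", "c", 1), ("d", "e", 1))
        dens, background, test = gene_set_edge_density(m, {"s": ["a", "b", "c"]})
        assert dens["s"] == pytest.approx(2 / 3)
        assert test is None  # a single set cannot support the t-test

    def test_set_without_internal_edges_scores_zero(self):
        m = model_from(("a", "b", 1), ("c", "d", 1))
        dens, *_ = gene_set_edge_density(m, {"s": ["a", "c", "d"]})
        # a-c and a-d unconnected; c-d connected -> 1/3... use disjoint genes
        m2 = model_from(("a", "b", 1), ("x", "y", 1))
        dens2, *_ = gene_set_edge_density(
            model_from(("a", "b", 1), ("x", "y", 1), ("p", "q", 1)),
            {"s": ["a", "x", "p"]},
        )
        assert dens2["s"] == 0.0

    def test_density_matches_brute_force_pair_enumeration(self, rng):
        m = random_model(rng, n_nodes=30, n_edges=80)
        nodes = sorted(m.genes)
        sets = {
            f"s{k}": list(rng.choice(nodes, size=6, replace=False)) for k in range(5)
        }
        dens, background, test = gene_set_edge_density(m, sets)
        linked = {(p, t) for p, t in zip(m.edges["predictor"], m.edges["target"])}

        def brute(members):
            hits = 0
            pairs = 0
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs += 1
                    hits += ((a, b) in linked) or ((b, a) in linked)
            return hits / pairs

        for name, members in sets.items():
            assert dens[name] == pytest.approx(brute(sorted(members)), abs=1e-15)
        assert background == pytest.approx(brute(nodes), abs=1e-15)
        assert test["n_sets"] == 5

    def test_small_sets_skipped_with_warning(self):
        m = model_from(("a", "b", 1), ("b", "c", 1))
        with pytest.warns(UserWarning, match="skipped"):
            dens, *_ = gene_set_edge_density(m, {"tiny": ["a", "b"]})
        assert dens.empty


class TestSymmetrize:
    def test_pair_weights_sum(self):
        g = symmetrize(model_from(("a", "b", 0.3), ("b", "a", 0.2)))
        assert g["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_single_direction_passes_through(self):
        g = symmetrize(model_from(("a", "b", 0.3)))
        assert g["a"]["b"]["weight"] == pytest.approx(0.3)

    def test_exact_cancellation_drops_edge(self):
        g = symmetrize(model_from(("a", "b", 0.3), ("b", "a", -0.3)))
        assert not g.has_edge("a", "b")
        assert set(g.nodes) == {"a", "b"}


class TestPropagation:
    def test_alpha_zero_returns_input(self):
        g = symmetrize(model_from(("a", "b", 1.0)))
        out = propagate_scores(g, {"a": 3.0, "b": -1.0}, PropagationConfig(alpha=0.0))
        assert out["a"] == 3.0 and out["b"] == -1.0

    def test_two_node_closed_form(self):
        # A = [[0,1],[1,0]], F0 = (1, 0), alpha = 0.2:
        # F = 0.8 * inv(I - 0.2 A) @ F0 = (0.8333..., 0.1666...)
        g = symmetrize(model_from(("a", "b", 1.0)))
        out = propagate_scores(g, {"a": 1.0, "b": 0.0})
        assert out["a"] == pytest.approx(5 / 6, abs=1e-7)
        assert out["b"] == pytest.approx(1 / 6, abs=1e-7)

    def test_matches_closed_form_on_random_graph(self, rng):
        m = random_model(rng, n_nodes=15, n_edges=40)
        g = symmetrize(m)
        nodes = sorted(g.nodes, key=str)
        scores = {n: float(rng.normal()) for n in nodes}
        cfg = PropagationConfig(alpha=0.2, tol=1e-12)
        out = propagate_scores(g, scores, cfg)
        A = np.zeros((len(nodes), len(nodes)))
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if g.has_edge(a, b):
                    A[i, j] = abs(g[a][b]["weight"])
        rs = A.sum(axis=1)
        A[rs > 0] /= rs[rs > 0, None]
        for i in np.flatnonzero(rs == 0):
            A[i, i] = 1.0
        f0 = np.array([scores[n] for n in nodes])
        expected = 0.8 * np.linalg.solve(np.eye(len(nodes)) - 0.2 * A, f0)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-8)

    def test_isolated_node_keeps_its_score(self):
        g = symmetrize(model_from(("a", "b", 1.0)))
        g.add_node("lonely")
        out = propagate_scores(g, {"a": 1.0, "b": 0.0, "lonely": 7.0})
        assert out["lonely"] == pytest.approx(7.0)

    @given(st.floats(0.0, 0.95), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_bounded_by_input_range(self, alpha, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_nodes=8, n_edges=14)
        g = symmetrize(m)
        scores = {n: float(rng.uniform(-2, 5)) for n in g.nodes}
        out = propagate_scores(g, scores, PropagationConfig(alpha=alpha))
        lo, hi = min(scores.values()), max(scores.values())
        assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()


def test_prune_arm_lcc_pipeline_idempotent(rng):
    ann = pd.DataFrame(
        {
            "chromosome": [str(1 + i % 3) for i in range(12)],
            "arm": ["p" if i % 2 else "q" for i in range(12)],
        },
        index=[f"g{i}" for i in range(12)],
    )

    def process(m):
        return largest_connected_component(
            remove_same_arm_predictors(prune_residual_edges(m), ann)
        )

    m = random_model(rng, n_nodes=12, n_edges=30)
    once = process(m)
    twice = process(once)
    pd.testing.assert_frame_equal(
        once.edges.reset_index(drop=True), twice.edges.reset_index(drop=True)
    )
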