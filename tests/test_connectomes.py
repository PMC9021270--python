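"""Connectome validation, group consensus and topological null models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gabadmf as g
from gabadmf.connectomes import CohortConnectomes, read_cohort


def make_connectome(w, coords=None):
    labels = [f"R{i:03d}" for i in range(len(w))]
    return g.validate_connectome(np.asarray(w, float), labels, coordinates=coords)


def symmetric_from_edges(n, edges):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


class TestValidation:
    def test_accepts_symmetric_zero_diagonal(self):
        w = symmetric_from_edges(3, [(0, 1, 1.0), (1, 2, 2.0)])
        c = make_connectome(w)
        assert np.array_equal(c.weights, w)

    def test_rejects_asymmetry_without_averaging(self):
        w = np.zeros((3, 3))
        w[1, 2], w[2, 1] = 2.0, 3.0
        with pytest.raises(g.ValidationError, match=r"\(1, 2\)"):
            make_connectome(w)

    @pytest.mark.parametrize(
        "bad",
        [
            np.full((3, 3), np.nan),
            symmetric_from_edges(3, [(0, 1, -1.0)]),
            np.eye(3),  # non-zero diagonal
            np.zeros((2, 3)),  # not square
        ],
    )
    def test_rejects_malformed(self, bad):
        with pytest.raises(g.ValidationError):
            make_connectome(bad)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(g.ValidationError, match="unique"):
            g.validate_connectome(np.zeros((2, 2)), ["a", "a"])


class TestConsensus:
    def build_cohort(self, edge_weight_sets, n=3):
        subs = []
        for ws in edge_weight_sets:
            subs.append(make_connectome(symmetric_from_edges(n, [(0, 1, ws)])))
        return CohortConnectomes(subjects=tuple(subs))

    def test_strict_majority_mean_of_nonzero(self):
        # 2 of 3 subjects connected -> mean of the non-zero weights
        cons = g.consensus_connectome(self.build_cohort([2.0, 4.0, 0.0]))
        assert cons.weights[0, 1] == pytest.approx(3.0)

    def test_exact_half_is_dropped(self):
        cons = g.consensus_connectome(self.build_cohort([5.0, 7.0, 0.0, 0.0]))
        assert cons.weights[0, 1] == 0.0

    def test_single_subject_identity(self, sphere_connectome):
        cohort = CohortConnectomes(subjects=(sphere_connectome,))
        cons = g.consensus_connectome(cohort)
        assert np.allclose(cons.weights, sphere_connectome.weights)

    def test_identical_cohort_reproduces_member(self, sphere_connectome):
        cohort = CohortConnectomes(subjects=(sphere_connectome,) * 5)
        cons = g.consensus_connectome(cohort)
        assert np.allclose(cons.weights, sphere_connectome.weights)

    def test_label_mismatch_raises(self, sphere_connectome):
        other = g.Connectome(
            weights=sphere_connectome.weights,
            labels=tuple(reversed(sphere_connectome.labels)),
        )
        with pytest.raises(g.AlignmentError):
            CohortConnectomes(subjects=(sphere_connectome, other))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.lists(st.floats(0, 10), min_size=3, max_size=3),
                    min_size=1, max_size=7))
    def test_matches_per_edge_brute_force(self, weight_rows):
        """Consensus equals a direct per-edge strict-majority computation."""
        n = 3
        subs = tuple(
            make_connectome(symmetric_from_edges(n, [(0, 1, row[0]), (0, 2, row[1]),
                                                     (1, 2, row[2])]))
            for row in weight_rows
        )
        cons = g.consensus_connectome(CohortConnectomes(subjects=subs))
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            vals = [s.weights[a, b] for s in subs]
            nz = [v for v in vals if v > 0]
            expected = float(np.mean(nz)) if len(nz) > len(vals) / 2 else 0.0
            assert cons.weights[a, b] == pytest.approx(expected)


class TestNullModels:
    @pytest.mark.parametrize("null", [g.randomise_weight_preserving, g.latticise])
    def test_conserves_weights_edges_degrees(self, sphere_connectome, null):
        out = null(sphere_connectome, seed=5)
        assert out.n_edges == sphere_connectome.n_edges
        assert np.allclose(
            np.sort(out.edge_list()[2]), np.sort(sphere_connectome.edge_list()[2])
        )
        assert np.array_equal(
            np.sort(out.degrees()), np.sort(sphere_connectome.degrees())
        )

    @pytest.mark.parametrize("null", [g.randomise_weight_preserving, g.latticise])
    def test_seeded_determinism(self, sphere_connectome, null):
        a = null(sphere_connectome, seed=9)
        b = null(sphere_connectome, seed=9)
        assert np.array_equal(a.weights, b.weights)

    def test_randomise_rewires_sparse_graphs(self, sphere_connectome):
        """On a 20-node geometric graph, at least one endpoint changes."""
        changed = 0
        for seed in range(5):
            out = g.randomise_weight_preserving(sphere_connectome, seed=seed)
            if not np.array_equal(out.weights > 0, sphere_connectome.weights > 0):
                changed += 1
        assert changed == 5

    def test_complete_graph_permutes_weights_only(self):
        # K4 admits no degree-preserving rewiring; weights still shuffle
        n = 4
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        w[iu, ju] = np.arange(1.0, 7.0)
        w = w + w.T
        c = make_connectome(w)
        out = g.randomise_weight_preserving(c, seed=3)
        assert np.array_equal(out.weights > 0, c.weights > 0)
        assert np.allclose(np.sort(out.edge_list()[2]), np.arange(1.0, 7.0))

    def test_latticise_reduces_ring_distance(self, sphere_connectome):
        lat = g.latticise(sphere_connectome, seed=2)
        assert g.total_ring_distance(lat) <= g.total_ring_distance(sphere_connectome)

    def test_perfect_ring_lattice_unchanged_topology(self):
        # nearest-neighbour ring: no swap can reduce ring distance
        n = 12
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0 + i * 0.01
        c = make_connectome(w)
        lat = g.latticise(c, seed=4)
        assert np.array_equal(lat.weights > 0, c.weights > 0)

    def test_too_few_edges_raises(self):
        w = symmetric_from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        with pytest.raises(g.ValidationError, match="4 edges"):
            g.randomise_weight_preserving(make_connectome(w), seed=0)

    @pytest.mark.parametrize("null", [g.randomise_weight_preserving, g.latticise])
    def test_outputs_pass_validation(self, sphere_connectome, null):
        out = null(sphere_connectome, seed=1)
        revalidated = g.validate_connectome(out.weights, out.labels)
        assert np.array_equal(revalidated.weights, out.weights)


class TestScalingAndIO:
    def test_scale_for_simulation(self, sphere_connectome):
        scaled = g.scale_for_simulation(sphere_connectome, max_weight=0.2)
        assert scaled.weights.max() == pytest.approx(0.2)
        ratio = scaled.weights[sphere_connectome.weights > 0] / \
            sphere_connectome.weights[sphere_connectome.weights > 0]
        assert np.allclose(ratio, ratio[0])

    def test_roundtrip(self, tmp_path, sphere_connectome):
        m, l, x = tmp_path / "c.tsv", tmp_path / "l.txt", tmp_path / "xyz.tsv"
        g.write_connectome(sphere_connectome, m, l, x)
        back = g.read_connectome(m, l, x)
        assert back.labels == sphere_connectome.labels
        assert np.allclose(back.weights, sphere_connectome.weights)
        assert np.allclose(back.coordinates, sphere_connectome.coordinates, atol=1e-6)

    def test_read_cohort(self, tmp_path, sphere_spec, sphere_connectome):
        cohort = g.synth_cohort(sphere_spec, sphere_connectome)
        d = tmp_path / "cohort"
        d.mkdir()
        g.write_connectome(sphere_connectome, tmp_path / "base.tsv", tmp_path / "l.txt")
        for k, s in enumerate(cohort.subjects):
            g.write_connectome(s, d / f"s{k}.tsv")
        back = read_cohort(d, tmp_path / "l.txt")
        assert len(back.subjects) == len(cohort.subjects)
        assert np.allclose(back.subjects[0].weights, cohort.subjects[0].weights)
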