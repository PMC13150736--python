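"""Functional-symmetry group, invariance of the network function, geometry."""

import itertools
import math

import numpy as np
import pytest

from nnmo import (
    NetworkConfig,
    StreamConfig,
    TaskSpec,
    WeightMatrix,
    evaluate,
    generate_stream,
    run_stream,
    swap_AB,
)
from nnmo.symmetry import (
    InvariantTransform,
    apply_transform,
    canonicalize,
    cluster_count,
    distance_modality,
    enumerate_group,
    pairwise_distances,
    predicted_cluster_count,
    project3d,
)


def random_weights(rng, n=6, scale=1.0, frozen_frac=0.0):
    x = rng.uniform(-scale, scale, (n, n))
    frozen = rng.random((n, n)) < frozen_frac
    x[frozen] = 0.0
    return WeightMatrix(x, frozen)


class TestGroup:
    @pytest.mark.parametrize(
        "k,swap,n", [(0, False, 1), (1, False, 2), (2, False, 8), (2, True, 16), (3, False, 48)]
    )
    def test_group_size_and_formula(self, k, swap, n):
        group = enumerate_group(k, swap)
        assert len(group) == n == predicted_cluster_count(k, swap)
        assert len(set(group)) == n  # no duplicates

    def test_formula_is_2k_kfact(self):
        for k in range(5):
            assert predicted_cluster_count(k) == 2**k * math.factorial(k)

    def test_closed_under_composition(self):
        group = set(enumerate_group(2, input_swap_allowed=True))
        for t1, t2 in itertools.product(group, repeat=2):
            assert t1.compose(t2) in group

    def test_composition_matches_sequential_application(self, config6, rng):
        w = random_weights(rng)
        group = enumerate_group(2, input_swap_allowed=True)
        for t1, t2 in itertools.product(group[:6], group[:6]):
            via_compose = apply_transform(w, t1.compose(t2), config6)
            sequential = apply_transform(apply_transform(w, t2, config6), t1, config6)
            np.testing.assert_allclose(via_compose.x, sequential.x, atol=1e-15)


class TestApplyTransform:
    def test_identity_is_noop(self, config6, rng):
        w = random_weights(rng)
        t = InvariantTransform((0, 1), (1, 1))
        assert apply_transform(w, t, config6) == w

    def test_sign_flip_is_involution(self, config6, rng):
        w = random_weights(rng, frozen_frac=0.2)
        t = InvariantTransform((0, 1), (-1, 1))
        back = apply_transform(apply_transform(w, t, config6), t, config6)
        np.testing.assert_array_equal(back.x, w.x)
        np.testing.assert_array_equal(back.frozen, w.frozen)

    def test_frozen_mask_transported(self, config6, rng):
        w = random_weights(rng, frozen_frac=0.3)
        for t in enumerate_group(2, True):
            tw = apply_transform(w, t, config6)
            assert tw.frozen.sum() == w.frozen.sum()
            assert np.all(tw.x[tw.frozen] == 0.0)

    def test_output_rows_never_sign_flipped(self, config6, rng):
        """Transforms only permute/flip hidden (and optionally input) neurons."""
        w = random_weights(rng)
        t = InvariantTransform((1, 0), (-1, -1))
        tw = apply_transform(w, t, config6)
        o = list(config6.output_ids)
        np.testing.assert_array_equal(tw.x[np.ix_(o, o)], w.x[np.ix_(o, o)])

    def test_wrong_hidden_count_raises(self, rng):
        config5 = NetworkConfig(5)
        w = random_weights(rng, n=5)
        with pytest.raises(ValueError):
            apply_transform(w, InvariantTransform((0, 1), (1, 1)), config5)


class TestFunctionalInvariance:
    def test_traces_exactly_invariant_for_hidden_transforms(self, config6, task_a3, rng):
        """All 8 K=2 transforms preserve the output trace on any stream to <=1e-9."""
        group = enumerate_group(2)
        for _ in range(25):
            w = random_weights(rng, scale=1.5)
            stream = generate_stream(task_a3, StreamConfig(length_symbols=10), rng=rng)
            base = run_stream(w, stream, config6).outputs
            for t in group:
                got = run_stream(apply_transform(w, t, config6), stream, config6).outputs
                np.testing.assert_allclose(got, base, atol=1e-9)

    def test_goal_equal_across_orbit(self, config6, task_c4, rng):
        w = random_weights(rng, scale=1.5)
        stream = generate_stream(task_c4, StreamConfig(length_symbols=15), rng=rng)
        goals = {
            round(evaluate(apply_transform(w, t, config6), stream, config6)[0], 9)
            for t in enumerate_group(2)
        }
        assert len(goals) == 1

    def test_global_negation_is_not_an_invariance(self, config6, task_a3, rng):
        """Negating the whole matrix (touching input/output rows) changes the trace."""
        w = random_weights(rng, scale=1.5)
        stream = generate_stream(task_a3, StreamConfig(length_symbols=10), rng=rng)
        base = run_stream(w, stream, config6).outputs
        negated = run_stream(WeightMatrix(-w.x), stream, config6).outputs
        assert np.max(np.abs(negated - base)) > 1e-3

    def test_input_swap_matches_swapped_stream(self, config6, task_c4, rng):
        """T_swap(w) on s behaves as w on swap_AB(s): same per-tick trace and errors."""
        w = random_weights(rng, scale=1.5)
        t_swap = InvariantTransform((0, 1), (1, 1), input_swap=True)
        stream = generate_stream(task_c4, StreamConfig(length_symbols=20), rng=rng)
        trace_transformed = run_stream(apply_transform(w, t_swap, config6), stream, config6)
        trace_swapped_env = run_stream(w, swap_AB(stream), config6)
        np.testing.assert_allclose(
            trace_transformed.outputs, trace_swapped_env.outputs, atol=1e-9
        )
        g1, e1 = evaluate(apply_transform(w, t_swap, config6), stream, config6)
        g2, e2 = evaluate(w, swap_AB(stream), config6)
        assert e1 == e2


class TestCanonicalize:
    def test_idempotent(self, config6, rng):
        w = random_weights(rng)
        c1, _ = canonicalize(w, config6)
        c2, _ = canonicalize(c1, config6)
        assert c1 == c2

    def test_constant_on_orbits_brute_force(self, config6, rng):
        """Every K=2 orbit member maps to the same representative."""
        w = random_weights(rng)
        rep, _ = canonicalize(w, config6)
        for t in enumerate_group(2):
            rep_t, _ = canonicalize(apply_transform(w, t, config6), config6)
            np.testing.assert_array_equal(rep_t.x, rep.x)

    def test_zero_matrix_fixed_point(self, config6):
        w = WeightMatrix(np.zeros((6, 6)))
        rep, t = canonicalize(w, config6)
        assert rep == w

    def test_returned_transform_achieves_representative(self, config6, rng):
        w = random_weights(rng)
        rep, t = canonicalize(w, config6)
        np.testing.assert_array_equal(apply_transform(w, t, config6).x, rep.x)


class TestGeometry:
    def test_duplicate_member_distance_zero(self, config6, rng):
        w = random_weights(rng)
        geo = pairwise_distances([w, w.copy()])
        assert geo.distances[0] == 0.0

    def test_single_synapse_difference(self, config6, rng):
        w = random_weights(rng)
        w2 = w.copy()
        w2.x[3, 4] += 0.7
        geo = pairwise_distances([w, w2])
        assert geo.distances[0] == pytest.approx(0.7)

    def test_matches_double_loop_oracle(self, rng):
        members = [random_weights(rng) for _ in range(6)]
        geo = pairwise_distances(members)
        mat = geo.distance_matrix()
        for i, j in itertools.combinations(range(6), 2):
            expected = math.sqrt(
                sum(
                    (members[i].x[r, c] - members[j].x[r, c]) ** 2
                    for r in range(6)
                    for c in range(6)
                )
            )
            assert mat[i, j] == pytest.approx(expected, rel=1e-12)

    def test_canonical_distances_collapse_orbits(self, config6, rng):
        w = random_weights(rng)
        orbit = [apply_transform(w, t, config6) for t in enumerate_group(2)]
        geo = pairwise_distances(orbit, config6)
        assert np.max(geo.canonical_distances) < 1e-12
        assert np.min(geo.distances) > 0.1  # generic point: orbit images differ


def orbit_ensemble(rng, config, members_per_cluster=5, jitter=1e-3):
    """Ground-truth clustered ensemble: jittered copies of each orbit image."""
    w = WeightMatrix(rng.uniform(-2, 2, (6, 6)))
    out = []
    for t in enumerate_group(2):
        tw = apply_transform(w, t, config)
        for _ in range(members_per_cluster):
            out.append(WeightMatrix(tw.x + rng.uniform(-jitter, jitter, (6, 6))))
    return out


class TestClusterCount:
    def test_orbit_ensemble_recovers_eight_clusters(self, config6, rng):
        ensemble = orbit_ensemble(rng, config6)
        geo = pairwise_distances(ensemble)
        n, labels = cluster_count(geo)
        assert n == 8
        assert sorted(np.bincount(labels)[1:]) == [5] * 8

    def test_single_blob_is_one_cluster(self, rng):
        pts = rng.normal(size=(40, 36))
        geo = pairwise_distances(pts)
        n, labels = cluster_count(geo)
        assert n == 1
        assert np.all(labels == 1)

    def test_identical_ensemble_is_one_cluster(self, config6, rng):
        w = random_weights(rng)
        geo = pairwise_distances([w, w.copy(), w.copy()])
        n, _ = cluster_count(geo)
        assert n == 1

    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(20, 36)) * 0.05
        b = rng.normal(size=(20, 36)) * 0.05 + 3.0
        geo = pairwise_distances(np.vstack([a, b]))
        n, labels = cluster_count(geo)
        assert n == 2


class TestProjectionAndModality:
    def test_projection_selects_flat_coordinates(self, rng):
        pts = rng.normal(size=(4, 36))
        table = project3d(pts, (25, 26, 31))
        np.testing.assert_array_equal(table.to_numpy(), pts[:, [24, 25, 30]])
        assert list(table.columns) == ["synapse_25", "synapse_26", "synapse_31"]

    def test_projection_rejects_out_of_range(self, rng):
        with pytest.raises(IndexError):
            project3d(rng.normal(size=(3, 36)), (0, 1, 2))

    def test_projection_of_sign_flip_orbit_shows_distinct_centroids(self, config6, rng):
        """A sign-flipped coordinate separates orbit images in the projection."""
        ensemble = orbit_ensemble(rng, config6, members_per_cluster=3)
        hid = config6.hidden_ids[0]
        synapse = hid * 6 + config6.input_ids[0] + 1  # hidden row, input column
        table = project3d(ensemble, (synapse, synapse, synapse))
        values = table.iloc[:, 0].to_numpy()
        assert values.max() > 0.0 > values.min() or np.unique(np.sign(values)).size > 1

    def test_single_blob_unimodal(self, rng):
        geo = pairwise_distances(rng.normal(size=(60, 10)) * 0.01)
        assert not distance_modality(geo, bins=20).multimodal

    def test_two_blobs_bimodal(self, rng):
        a = rng.normal(size=(30, 10)) * 0.05
        b = rng.normal(size=(30, 10)) * 0.05 + 2.0
        geo = pairwise_distances(np.vstack([a, b]))
        assert distance_modality(geo, bins=30).multimodal

    def test_orbit_ensemble_multimodal(self, config6, rng):
        geo = pairwise_distances(orbit_ensemble(rng, config6))
        report = distance_modality(geo, bins=40)
        assert report.multimodal
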