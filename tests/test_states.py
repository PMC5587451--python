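"""State space, transition-matrix validation and profile aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    ProfilePartition,
    RewardSet,
    StateSpace,
    TransitionMatrix,
    ValidationError,
    aggregate_profiles,
    as_distribution,
    validate_matrix,
)


class TestStateSpace:
    def test_default_order_and_absorbing(self, states):
        assert states.labels == ("mild", "moderate", "severe", "total", "death")
        assert states.absorbing == frozenset({"death"})
        assert states.absorbing_indices == (4,)

    @pytest.mark.parametrize(
        "labels,absorbing",
        [((), set()), (("a", "a"), set()), (("a", "b"), {"c"})],
    )
    def test_rejects_bad_spaces(self, labels, absorbing):
        with pytest.raises(ValidationError):
            StateSpace(labels, frozenset(absorbing))


class TestMatrixValidation:
    def test_published_matrix_passes(self, matrix):
        assert validate_matrix(matrix) is matrix
        assert matrix.prob("severe", "moderate") == 0.12

    def test_identity_matrix_passes(self, states):
        m = TransitionMatrix(states, np.eye(5))
        assert validate_matrix(m) is m

    def test_non_stochastic_row_names_offender(self, states, matrix):
        p = matrix.p.copy()
        p[2, 2] = 0.60  # severe row now sums to 0.99
        with pytest.raises(ValidationError, match="severe"):
            TransitionMatrix(states, p)

    def test_out_of_range_entry_named(self, states):
        p = np.eye(5)
        p[0, 0], p[0, 1] = 1.2, -0.2
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            TransitionMatrix(states, p)

    def test_non_absorbing_death_row_rejected(self, states, matrix):
        p = matrix.p.copy()
        p[4] = [0.01, 0, 0, 0, 0.99]
        with pytest.raises(ValidationError, match="death"):
            TransitionMatrix(states, p)

    def test_repair_renormalises_small_rounding_error(self, states, matrix):
        p = matrix.p.copy()
        p[0, 0] = 0.79 + 0.004  # within the two-decimal rounding band
        m = TransitionMatrix(states, p, repair=True)
        assert np.allclose(m.p.sum(axis=1), 1.0, atol=1e-12)
        with pytest.raises(ValidationError):
            TransitionMatrix(states, p, repair=False)

    def test_repair_does_not_mask_large_errors(self, states, matrix):
        p = matrix.p.copy()
        p[0, 0] = 0.79 + 0.02
        with pytest.raises(ValidationError):
            TransitionMatrix(states, p, repair=True)

    def test_csv_roundtrip_with_permuted_labels(self, matrix, states, tmp_path):
        # write in a permuted row/column order; labels must win over position
        df = matrix.to_frame()
        perm = ["death", "total", "severe", "moderate", "mild"]
        path = tmp_path / "m.csv"
        df.loc[perm, perm].to_csv(path, index_label="from_state")
        m2 = TransitionMatrix.from_csv(path, states=states)
        assert np.allclose(m2.p, matrix.p)


class TestAggregation:
    def test_destination_sum_and_equal_weight_rows(self):
        fine = TransitionMatrix(
            StateSpace(("a", "b", "c"), frozenset()),
            np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]]),
        )
        part = ProfilePartition(("a", "b", "c"), {"a": "X", "b": "Y", "c": "Y"})
        coarse = aggregate_profiles(fine, part)
        assert coarse.states.labels == ("X", "Y")
        assert np.allclose(coarse.row("X"), [0.5, 0.5])
        assert np.allclose(coarse.row("Y"), [0.2, 0.8])

    def test_identity_partition_is_identity(self, matrix):
        part = ProfilePartition(matrix.states.labels, {lab: lab for lab in matrix.states.labels})
        out = aggregate_profiles(matrix, part, coarse_states=matrix.states)
        assert np.allclose(out.p, matrix.p)

    def test_source_weights_change_row_mix(self):
        fine = TransitionMatrix(
            StateSpace(("a", "b", "c"), frozenset()),
            np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]]),
        )
        part = ProfilePartition(
            ("a", "b", "c"), {"a": "X", "b": "Y", "c": "Y"}, source_weights={"b": 3.0, "c": 1.0}
        )
        coarse = aggregate_profiles(fine, part)
        # 0.75 * [0.1, 0.9] + 0.25 * [0.3, 0.7]
        assert np.allclose(coarse.row("Y"), [0.15, 0.85])

    def test_all_zero_weights_rejected(self):
        fine = TransitionMatrix(StateSpace(("a", "b"), frozenset()), np.array([[0.5, 0.5], [0.2, 0.8]]))
        part = ProfilePartition(("a", "b"), {"a": "X", "b": "X"}, source_weights={"a": 0.0, "b": 0.0})
        with pytest.raises(ValidationError, match="zero"):
            aggregate_profiles(fine, part)

    def test_unmapped_fine_label_rejected(self):
        with pytest.raises(ValidationError, match="without a coarse"):
            ProfilePartition(("a", "b"), {"a": "X"})

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_aggregation_conserves_probability(self, seed):
        """Coarse rows sum to 1 for any fine stochastic matrix and
        any random partition/weights."""
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 9)
        p = rng.dirichlet(np.ones(k), size=k)
        fine_labels = tuple(f"f{i}" for i in range(k))
        n_coarse = rng.integers(1, k + 1)
        assign = rng.integers(0, n_coarse, size=k)
        assign[:n_coarse] = np.arange(n_coarse)  # every coarse state non-empty
        mapping = {fine_labels[i]: f"C{assign[i]}" for i in range(k)}
        weights = {fine_labels[i]: float(rng.uniform(0.1, 2.0)) for i in range(k)}
        fine = TransitionMatrix(StateSpace(fine_labels, frozenset()), p)
        coarse = aggregate_profiles(fine, ProfilePartition(fine_labels, mapping, weights))
        assert np.allclose(coarse.p.sum(axis=1), 1.0, atol=1e-9)

    def test_aggregation_commutes_with_propagation_when_rows_identical(self):
        """When fine profiles within a coarse group share identical rows,
        collapsing then stepping equals stepping then collapsing."""
        row_x = np.array([0.6, 0.25, 0.15])
        row_y = np.array([0.1, 0.5, 0.4])
        p = np.stack([row_x, row_y, row_y])
        fine = TransitionMatrix(StateSpace(("a", "b", "c"), frozenset()), p)
        part = ProfilePartition(("a", "b", "c"), {"a": "X", "b": "Y", "c": "Y"})
        coarse = aggregate_profiles(fine, part)
        col = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])  # fine -> coarse membership
        start_fine = np.array([0.5, 0.3, 0.2])
        stepped_then_collapsed = (start_fine @ p) @ col
        collapsed_then_stepped = (start_fine @ col) @ coarse.p
        assert np.allclose(stepped_then_collapsed, collapsed_then_stepped)


class TestRewards:
    def test_published_rewards_load(self, rewards):
        assert np.allclose(rewards.utility, [0.77, 0.60, 0.47, 0.41, 0.0])
        assert np.allclose(rewards.annual_cost, [2864, 8593, 22915, 68746, 0])

    @pytest.mark.parametrize(
        "util,cost",
        [
            ({"mild": 1.2}, {}),  # utility above 1
            ({}, {"mild": -5.0}),  # negative cost
            ({"death": 0.1}, {}),  # non-zero death utility
        ],
    )
    def test_invalid_rewards_rejected(self, states, util, cost):
        u = {"mild": 0.77, "moderate": 0.6, "severe": 0.47, "total": 0.41, "death": 0.0} | util
        c = {"mild": 2864.0, "moderate": 8593.0, "severe": 22915.0, "total": 68746.0, "death": 0.0} | cost
        with pytest.raises(ValidationError):
            RewardSet.from_mappings(states, u, c)


class TestDistributions:
    def test_mapping_coercion_fills_zeros(self, states):
        v = as_distribution({"severe": 1.0}, states)
        assert np.allclose(v, [0, 0, 1, 0, 0])

    @pytest.mark.parametrize("bad", [{"ghost": 1.0}, {"severe": 0.9}, {"severe": 1.5, "mild": -0.5}])
    def test_invalid_distributions_rejected(self, states, bad):
        with pytest.raises(ValidationError):
            as_distribution(bad, states)
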