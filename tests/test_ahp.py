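"""Priority derivation, consistency filtering, and group aggregation."""

import numpy as np
import pytest
from scipy import linalg

from consensuskit import (
    DegenerateDataError,
    GroupWeightTable,
    PairwiseComparisonMatrix,
    PriorityVector,
    ValidationError,
    aggregate_group,
    consistency,
    derive_priorities,
    pcm_from_upper_triangle,
    rank_items,
    validate_pcm,
)
from consensuskit.ahp import RANDOM_INDEX

from conftest import random_reciprocal_matrix


def dense_eigen_oracle(matrix):
    """Principal eigenpair via a full dense eigensolver (scipy.linalg.eig)."""
    vals, vecs = linalg.eig(np.asarray(matrix, dtype=float))
    k = int(np.argmax(vals.real))
    w = np.abs(vecs[:, k].real)
    return w / w.sum(), float(vals[k].real)


class TestValidatePcm:
    def test_trivial_two_item_matrix(self):
        m = validate_pcm([[1, 1], [1, 1]])
        assert m.shape == (2, 2)

    def test_upper_triangle_completion(self):
        m = pcm_from_upper_triangle([3, 5, 3])
        expected = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1]])
        assert np.allclose(m, expected)

    def test_reciprocity_violation_names_the_cell(self):
        bad = [[1, 3], [0.5, 1]]
        with pytest.raises(ValidationError, match=r"\(2,1\)"):
            validate_pcm(bad)

    @pytest.mark.parametrize(
        "matrix",
        [
            [[1, 2, 3], [0.5, 1, 1]],            # not square
            [[1, -2], [-0.5, 1]],                 # non-positive
            [[1, 12], [1 / 12, 1]],               # outside Saaty domain
            [[2, 1], [1, 2]],                     # diagonal not 1
        ],
    )
    def test_malformed_matrices_rejected(self, matrix):
        with pytest.raises(ValidationError):
            validate_pcm(matrix)


class TestDerivePriorities:
    def test_consistent_matrix_reproduces_generating_vector(self):
        m = [[1, 2, 2], [0.5, 1, 1], [0.5, 1, 1]]
        vec, lam = derive_priorities(np.array(m))
        assert np.allclose(vec.weights, [0.5, 0.25, 0.25], atol=1e-10)
        assert lam == pytest.approx(3.0, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_all_ones_matrix_gives_uniform_weights(self, n):
        vec, lam = derive_priorities(np.ones((n, n)))
        assert np.allclose(vec.weights, np.full(n, 1 / n))
        assert lam == pytest.approx(n)

    def test_mildly_inconsistent_matrix_matches_dense_oracle(self):
        m = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1]])
        vec, lam = derive_priorities(m)
        w_ref, lam_ref = dense_eigen_oracle(m)
        assert np.allclose(vec.weights, w_ref, atol=1e-8)
        assert lam == pytest.approx(lam_ref, abs=1e-8)
        assert consistency(lam, 3).accepted

    def test_matches_dense_oracle_on_random_matrices(self, rng):
        # >= 100 random reciprocal matrices across the tabulated sizes
        for trial in range(105):
            n = int(rng.integers(3, 10))
            m = random_reciprocal_matrix(rng, n)
            vec, lam = derive_priorities(m)
            w_ref, lam_ref = dense_eigen_oracle(m)
            assert np.allclose(vec.weights, w_ref, atol=1e-8), (trial, n)
            assert lam == pytest.approx(lam_ref, abs=1e-8)

    def test_geometric_mean_agrees_on_consistent_matrices(self):
        w = np.array([0.4, 0.3, 0.2, 0.1])
        m = w[:, None] / w[None, :]
        for method in ("eigenvector", "geometric_mean"):
            vec, _ = derive_priorities(m, method=method)
            assert np.allclose(vec.weights, w, atol=1e-10)

    def test_row_column_scaling_rescales_one_priority_only(self, rng):
        # multiplying row i by c and column i by 1/c is a similarity
        # transform: it preserves reciprocity, multiplies w_i by c, and
        # leaves the relative priorities of all other items unchanged
        for _ in range(20):
            n = int(rng.integers(3, 7))
            # entries near 1 so the scaled matrix stays inside [1/9, 9]
            m = np.eye(n)
            for a in range(n):
                for b in range(a + 1, n):
                    v = float(rng.choice([1 / 2, 1, 2]))
                    m[a, b], m[b, a] = v, 1 / v
            c = float(rng.uniform(0.8, 1.25))
            i = int(rng.integers(n))
            scaled = m.copy()
            scaled[i, :] *= c
            scaled[:, i] /= c
            scaled[i, i] = 1.0
            w_base, lam_base = derive_priorities(m)
            w_scaled, lam_scaled = derive_priorities(scaled)
            ratio = np.delete(w_scaled.weights / w_base.weights, i)
            assert np.allclose(ratio / ratio[0], 1.0, atol=1e-8)
            assert w_scaled.weights[i] / w_base.weights[i] == pytest.approx(
                c * ratio[0], rel=1e-8
            )
            assert lam_scaled == pytest.approx(lam_base, abs=1e-8)


class TestConsistency:
    @pytest.mark.parametrize("n", [3, 7, 15])
    def test_perfectly_consistent_matrix_has_zero_cr(self, n):
        rep = consistency(float(n), n)
        assert rep.ci == 0 and rep.cr == 0 and rep.accepted

    def test_closed_form_arithmetic_n4(self):
        rep = consistency(4.18, 4)
        assert rep.ci == pytest.approx(0.06)
        assert rep.ri == 0.90
        assert rep.cr == pytest.approx(0.06 / 0.90)
        assert rep.accepted

    def test_threshold_is_strict(self):
        # acceptance must be cr < 0.1 strictly: 0.12 is rejected, just-below
        # is accepted, and the report's own cr always agrees with the flag
        n, ri = 4, RANDOM_INDEX[4]
        lam_for = lambda cr: n + cr * ri * (n - 1)
        assert not consistency(lam_for(0.12), n).accepted
        assert consistency(lam_for(0.0999), n).accepted
        for target in (0.05, 0.0999, 0.1, 0.1001, 0.12):
            rep = consistency(lam_for(target), n)
            assert rep.accepted == (rep.cr < 0.1)

    def test_small_matrices_are_always_consistent(self):
        assert consistency(2.0, 2).cr == 0.0
        assert consistency(2.0, 2).accepted

    def test_untabulated_size_requires_extrapolation_flag(self):
        with pytest.raises(ValidationError):
            consistency(16.5, 16)
        rep = consistency(16.5, 16, extrapolate_ri=True)
        assert rep.ri == 1.60


def _vector(weights, items=None):
    w = np.asarray(weights, dtype=float)
    items = items or tuple(f"i{k}" for k in range(w.size))
    return PriorityVector(item_ids=tuple(items), weights=w / w.sum())


def _report(cr, n=3):
    from consensuskit.ahp import ConsistencyReport
    return ConsistencyReport(lambda_max=n + cr * RANDOM_INDEX[n] * (n - 1),
                             n=n, ci=cr * RANDOM_INDEX[n], ri=RANDOM_INDEX[n],
                             cr=cr, accepted=cr < 0.1)


class TestAggregateGroup:
    def test_single_accepted_vector(self):
        table = aggregate_group([_vector([40, 35, 25])], [_report(0.0)])
        assert np.allclose(table.mean_weight_pct, [40, 35, 25])
        assert np.allclose(table.sd_weight_pct, 0.0)
        assert table.n_accepted == 1

    def test_two_vector_sample_sd(self):
        table = aggregate_group(
            [_vector([60, 40], items=("a", "b")), _vector([40, 60], items=("a", "b"))],
            [_report(0.0), _report(0.0)],
        )
        assert np.allclose(table.mean_weight_pct, [50, 50])
        assert np.allclose(table.sd_weight_pct, np.sqrt(200), atol=1e-9)  # 14.142...

    def test_rejected_participants_are_excluded(self):
        table = aggregate_group(
            [_vector([60, 30, 10]), _vector([10, 30, 60])],
            [_report(0.05), _report(0.2)],
        )
        assert table.n_accepted == 1
        assert table.rejected_participants == ("participant-2",)
        assert np.allclose(table.mean_weight_pct, [60, 30, 10])

    def test_all_rejected_is_an_error(self):
        with pytest.raises(DegenerateDataError, match="re-elicit"):
            aggregate_group([_vector([50, 50])], [_report(0.3)])

    def test_means_always_sum_to_100(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 12))
            n_part = int(rng.integers(1, 12))
            vectors = [_vector(rng.uniform(0.05, 1, size=k),
                               items=tuple(f"i{j}" for j in range(k)))
                       for _ in range(n_part)]
            reports = [_report(float(rng.uniform(0, 0.2))) for _ in range(n_part)]
            if not any(r.accepted for r in reports):
                reports[0] = _report(0.0)
            table = aggregate_group(vectors, reports)
            assert table.mean_weight_pct.sum() == pytest.approx(100.0, abs=1e-6)


class TestRankItems:
    def test_descending_by_mean_weight(self):
        table = GroupWeightTable(
            category="diagnosis",
            item_ids=("enter-diagnosis", "database-access", "diagnosis-hints"),
            mean_weight_pct=np.array([39.7, 32.1, 28.2]),
            sd_weight_pct=np.array([10.3, 6.2, 4.6]),
            n_accepted=10,
            participant_weights_pct=np.empty((0, 3)),
        )
        assert rank_items(table) == [
            "enter-diagnosis", "database-access", "diagnosis-hints"
        ]

    def test_ties_keep_catalog_order(self):
        table = GroupWeightTable(
            category="c", item_ids=("a", "b", "c"),
            mean_weight_pct=np.array([30.0, 40.0, 30.0]),
            sd_weight_pct=np.zeros(3), n_accepted=1,
            participant_weights_pct=np.empty((0, 3)),
        )
        assert rank_items(table) == ["b", "a", "c"]

    def test_agrees_with_sort_oracle(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 10))
            means = rng.uniform(0, 100, size=k)
            items = tuple(f"i{j}" for j in range(k))
            table = GroupWeightTable(
                category="c", item_ids=items, mean_weight_pct=means,
                sd_weight_pct=np.zeros(k), n_accepted=1,
                participant_weights_pct=np.empty((0, k)),
            )
            oracle = [i for _, i in sorted(zip(-means, range(k)))]
            assert rank_items(table) == [items[i] for i in oracle]


def test_pcm_item_id_mismatch_rejected():
    with pytest.raises(ValidationError):
        PairwiseComparisonMatrix(
            participant_id="p", category="c", item_ids=("a", "b", "c"),
            matrix=np.ones((2, 2)),
        )
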