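import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bombnet import (
    QuantNetwork,
    entropy_bounds,
    focal_species_filter,
    h2prime,
    interspecific_index,
    intraspecific_index,
    muller_pac,
    shannon_H2,
)


def _net(arr, prefix=("b", "p")):
    arr = np.asarray(arr, dtype=float)
    return QuantNetwork.from_arrays(
        arr,
        [f"{prefix[0]}{i}" for i in range(arr.shape[0])],
        [f"{prefix[1]}{j}" for j in range(arr.shape[1])],
    )


# integer matrices with at least 2x2 nonzero structure
matrices = st.integers(2, 4).flatmap(
    lambda r: st.integers(2, 4).flatmap(
        lambda c: st.lists(
            st.lists(st.integers(0, 9), min_size=c, max_size=c),
            min_size=r, max_size=r,
        )
    )
).map(np.array).filter(
    lambda m: (m.sum(axis=1) > 0).sum() >= 2 and (m.sum(axis=0) > 0).sum() >= 2
)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[5, 0], [0, 5]], math.log(2)),
            ([[4, 4], [4, 4]], math.log(4)),
            ([[7, 0], [0, 0]], 0.0),
        ],
    )
    def test_known_values(self, matrix, expected):
        assert shannon_H2(_net(matrix)) == pytest.approx(expected)

    def test_empty_network_is_nan(self):
        assert math.isnan(shannon_H2(QuantNetwork.empty()))


class TestEntropyBounds:
    def test_diagonal_continuous(self):
        b = entropy_bounds(_net([[5, 0], [0, 5]]), mode="continuous")
        assert b.H2max == pytest.approx(2 * math.log(2))
        assert b.H2min == pytest.approx(math.log(2))

    def test_outer_product_reaches_max(self):
        b = entropy_bounds(_net([[4, 4], [4, 4]]), mode="continuous")
        assert b.H2max == pytest.approx(math.log(4))
        assert b.H2 == pytest.approx(b.H2max)

    def test_integer_mode_rejects_fractional_weights(self):
        with pytest.raises(ValueError, match="integer"):
            entropy_bounds(_net([[0.5, 1.0], [1.0, 0.5]]), mode="integer")

    @given(matrices)
    @settings(max_examples=200, deadline=None)
    def test_bounds_bracket_observed_entropy(self, m):
        b = entropy_bounds(_net(m).drop_empty_margins(), mode="integer")
        assert b.H2min - 1e-9 <= b.H2 <= b.H2max + 1e-9


class TestH2Prime:
    def test_perfect_specialization_is_one(self):
        diag = np.diag([10.0] * 5)
        assert h2prime(_net(diag)) == pytest.approx(1.0, abs=1e-12)

    def test_no_specialization_is_zero(self):
        outer = np.outer([1, 2, 3, 4], [1, 2, 3])
        assert h2prime(_net(outer), mode="continuous") == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance_continuous(self):
        m = np.array([[3, 1, 0], [0, 2, 5], [1, 1, 1]], dtype=float)
        assert h2prime(_net(m), mode="continuous") == pytest.approx(
            h2prime(_net(7 * m), mode="continuous"), abs=1e-12
        )

    def test_degenerate_single_row_gives_nan(self):
        assert math.isnan(h2prime(_net([[3, 4, 5]])))

    @given(matrices)
    @settings(max_examples=300, deadline=None)
    def test_range_and_permutation_invariance(self, m):
        net = _net(m)
        h = h2prime(net)
        assert math.isnan(h) or -1e-12 <= h <= 1 + 1e-12
        perm = m[np.random.RandomState(0).permutation(m.shape[0]), :]
        assert h2prime(_net(perm)) == pytest.approx(h, abs=1e-9, nan_ok=True)

    def test_monotone_from_diagonal_to_outer_product(self):
        """Interpolating a diagonal web toward its outer-product table keeps
        the margins fixed and must decrease specialization monotonically."""
        diag = np.diag([10.0, 10.0, 10.0, 10.0])
        r = diag.sum(axis=1)
        outer = np.outer(r, r) / r.sum()
        values = [
            h2prime(_net((1 - t) * diag + t * outer), mode="continuous")
            for t in np.linspace(0, 1, 11)
        ]
        assert values[0] == pytest.approx(1.0)
        assert values[-1] == pytest.approx(0.0, abs=1e-9)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestMullerPAC:
    def test_disjoint_plants_give_identity(self):
        net = _net([[3, 0, 0], [0, 2, 0], [0, 0, 9]])
        np.testing.assert_allclose(muller_pac(net).d.to_numpy(), np.eye(3), atol=1e-12)

    def test_single_pollinator(self):
        assert muller_pac(_net([[2, 3]])).d.to_numpy().tolist() == [[1.0]]

    def test_worked_example(self, worked_pac_network):
        d = muller_pac(worked_pac_network).d
        assert d.loc["A", "A"] == pytest.approx(0.5)
        assert d.loc["A", "B"] == pytest.approx(0.5)
        assert d.loc["B", "A"] == pytest.approx(0.25)
        assert d.loc["B", "B"] == pytest.approx(0.75)

    @given(matrices)
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one_and_permutation_equivariance(self, m):
        net = _net(m).drop_empty_margins()
        d = muller_pac(net).d
        np.testing.assert_allclose(d.sum(axis=1).to_numpy(), 1.0, atol=1e-9)
        assert ((d.to_numpy() >= -1e-12) & (d.to_numpy() <= 1 + 1e-12)).all()
        perm = np.random.RandomState(1).permutation(len(net.pollinators))
        permuted = QuantNetwork(net.matrix.iloc[perm])
        dp = muller_pac(permuted).d
        np.testing.assert_allclose(
            dp.loc[d.index, d.columns].to_numpy(), d.to_numpy(), atol=1e-12
        )


class TestCompetitionIndices:
    def test_disjoint_diets_intra_one_inter_zero(self):
        pac = muller_pac(_net([[3, 0], [0, 5]]))
        for focal in pac.taxa:
            assert intraspecific_index(pac, focal) == pytest.approx(1.0)
            assert interspecific_index(pac, focal) == pytest.approx(0.0)

    def test_worked_example_indices(self, worked_pac_network):
        pac = muller_pac(worked_pac_network)
        assert intraspecific_index(pac, "B") == pytest.approx(0.75)
        assert interspecific_index(pac, "B") == pytest.approx(0.5)   # d_AB
        assert interspecific_index(pac, "A") == pytest.approx(0.25)  # d_BA

    def test_missing_focal_gives_nan(self, worked_pac_network):
        pac = muller_pac(worked_pac_network)
        assert math.isnan(intraspecific_index(pac, "Z"))
        assert math.isnan(interspecific_index(pac, "Z"))

    def test_single_taxon_interspecific_is_nan(self):
        pac = muller_pac(_net([[2, 3]]))
        assert math.isnan(interspecific_index(pac, "b0"))

    def test_aggregation_and_direction_options(self):
        net = _net([[2, 0, 1], [1, 2, 0], [0, 1, 2]])
        pac = muller_pac(net)
        d = pac.d
        focal = "b0"
        others = d.loc[d.index != focal, focal]
        assert interspecific_index(pac, focal, "sum") == pytest.approx(others.sum())
        assert interspecific_index(pac, focal, "max") == pytest.approx(others.max())
        from_others = d.loc[focal, d.columns != focal]
        assert interspecific_index(pac, focal, "mean", "from_others") == pytest.approx(
            from_others.mean()
        )


class TestFocalSpeciesFilter:
    def _networks(self, presence_counts, n_patches=24):
        nets = {}
        for i in range(n_patches):
            rows = [sp for sp, c in presence_counts.items() if i < c]
            if not rows:
                rows = ["filler"]
            nets[f"P{i}"] = QuantNetwork.from_arrays(
                np.ones((len(rows), 2)), rows, ["x", "y"]
            )
        return nets

    def test_half_presence_retained(self):
        nets = self._networks({"A": 12, "B": 24})
        assert "A" in focal_species_filter(nets, 0.5)

    def test_below_half_dropped(self):
        nets = self._networks({"A": 11, "B": 24})
        assert "A" not in focal_species_filter(nets, 0.5)

    def test_zero_threshold_keeps_all(self):
        nets = self._networks({"A": 1, "B": 24})
        assert set(focal_species_filter(nets, 0.0)) >= {"A", "B"}
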