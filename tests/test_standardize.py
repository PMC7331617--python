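import datetime as dt
import itertools

import numpy as np
import pytest

from bombnet import (
    QuantNetwork,
    SamplingCalendar,
    VisitRecord,
    min_sampling_days,
    rarefy_network,
    rarefy_scalars,
    standardize_study,
)


def _days(n, month=6):
    return tuple(dt.date(2007, month, i + 1) for i in range(n))


def _visits_for_totals(patch, totals, month=6, plant="x"):
    """One species, one plant; day i carries totals[i] visits (0 allowed)."""
    out = []
    for i, t in enumerate(totals):
        if t > 0:
            out.append(VisitRecord(patch, dt.date(2007, month, i + 1), "SpA", plant, t))
    return out


class TestMinSamplingDays:
    def test_minimum_over_patches(self):
        cal = SamplingCalendar({"P1": _days(12), "P2": _days(9), "P3": _days(15)})
        assert min_sampling_days(cal) == 9

    def test_all_equal(self):
        cal = SamplingCalendar({"P1": _days(7), "P2": _days(7)})
        assert min_sampling_days(cal) == 7

    def test_single_patch(self):
        assert min_sampling_days(SamplingCalendar({"P1": _days(4)})) == 4


class TestRarefyScalars:
    def test_minimum_effort_patch_is_identity(self):
        visits = _visits_for_totals("P1", [2, 4, 6]) + _visits_for_totals("P2", [1, 1])
        cal = SamplingCalendar({"P1": _days(3), "P2": _days(2)})
        for B, seed in [(1, 0), (50, 1), (500, 99)]:
            (s,) = [
                s for s in rarefy_scalars(visits, cal, B=B, seed=seed, per_month=False)
                if s.patch_id == "P2"
            ]
            assert s.abundance == 2.0 and s.richness == 1.0

    def test_two_identical_days_rarefied_to_one(self):
        visits = _visits_for_totals("P1", [5, 5]) + _visits_for_totals("P2", [3])
        cal = SamplingCalendar({"P1": _days(2), "P2": _days(1)})
        (s,) = [
            s for s in rarefy_scalars(visits, cal, B=200, seed=0, per_month=False)
            if s.patch_id == "P1"
        ]
        assert s.abundance == 5.0

    def test_four_day_fixture_matches_enumeration_oracle(self):
        """Day totals [2,4,6,8] rarefied to 2 days: exact expectation is the
        mean over all 6 day pairs = 10 (= n_min/n x grand total)."""
        totals = [2, 4, 6, 8]
        expected = np.mean(
            [sum(pair) for pair in itertools.combinations(totals, 2)]
        )
        assert expected == 10.0
        visits = _visits_for_totals("P1", totals) + _visits_for_totals("P2", [1, 1])
        cal = SamplingCalendar({"P1": _days(4), "P2": _days(2)})
        B = 2000
        (s,) = [
            s for s in rarefy_scalars(visits, cal, B=B, seed=5, per_month=False)
            if s.patch_id == "P1"
        ]
        # MC standard error of the replicate mean of pair sums
        pair_sums = [sum(p) for p in itertools.combinations(totals, 2)]
        se = np.std(pair_sums, ddof=0) / np.sqrt(B)
        assert abs(s.abundance - expected) < 3 * se

    def test_seed_reproducibility_and_seed_sensitivity(self):
        visits = _visits_for_totals("P1", [2, 0, 7, 3, 5]) + _visits_for_totals("P2", [1, 1])
        cal = SamplingCalendar({"P1": _days(5), "P2": _days(2)})
        a = rarefy_scalars(visits, cal, B=300, seed=11, per_month=False)
        b = rarefy_scalars(visits, cal, B=300, seed=11, per_month=False)
        c = rarefy_scalars(visits, cal, B=300, seed=12, per_month=False)
        assert a == b
        assert a[0].abundance != c[0].abundance  # different draws
        assert abs(a[0].abundance - c[0].abundance) < 1.5  # within MC tolerance

    def test_adding_a_patch_does_not_perturb_others(self):
        visits = _visits_for_totals("P1", [2, 4, 6, 8]) + _visits_for_totals("P2", [1, 1])
        cal = SamplingCalendar({"P1": _days(4), "P2": _days(2)})
        base = {
            s.patch_id: s.abundance
            for s in rarefy_scalars(visits, cal, B=100, seed=3, per_month=False)
        }
        visits3 = visits + _visits_for_totals("P3", [9, 9, 9])
        cal3 = SamplingCalendar({"P1": _days(4), "P2": _days(2), "P3": _days(3)})
        extended = {
            s.patch_id: s.abundance
            for s in rarefy_scalars(visits3, cal3, B=100, seed=3, per_month=False)
        }
        assert extended["P1"] == base["P1"] and extended["P2"] == base["P2"]

    def test_parameter_validation(self):
        visits = _visits_for_totals("P1", [1, 2])
        cal = SamplingCalendar({"P1": _days(2)})
        with pytest.raises(ValueError):
            rarefy_scalars(visits, cal, B=0, per_month=False)
        with pytest.raises(ValueError):
            rarefy_scalars(visits, cal, n_min=0, per_month=False)


class TestRarefyNetwork:
    def _three_day_visits(self):
        d = _days(3)
        v = [
            VisitRecord("P1", d[0], "A", "x", 2),
            VisitRecord("P1", d[1], "A", "y", 1),
            VisitRecord("P1", d[1], "B", "x", 3),
            VisitRecord("P1", d[2], "B", "y", 4),
            VisitRecord("P2", d[0], "A", "x", 1),
            VisitRecord("P2", d[1], "A", "x", 1),
        ]
        return v, SamplingCalendar({"P1": d, "P2": d[:2]})

    def test_min_effort_patch_is_exact_sum(self):
        visits, cal = self._three_day_visits()
        net = rarefy_network(visits, cal, "P2", B=10, seed=0)
        assert net.total == 2.0

    def test_identical_days_scale_by_n_min(self):
        d = _days(4)
        visits = [VisitRecord("P1", day, "A", "x", 3) for day in d]
        visits += [VisitRecord("P2", day, "A", "x", 1) for day in d[:2]]
        cal = SamplingCalendar({"P1": d, "P2": d[:2]})
        net = rarefy_network(visits, cal, "P1", B=50, seed=1)
        assert net.values().tolist() == [[6.0]]  # n_min=2 x daily cell 3

    def test_cellwise_expectation_matches_pair_enumeration(self):
        """3 days rarefied to 2: replicate mean per cell converges to the
        mean over the 3 possible day pairs (exhaustive oracle)."""
        visits, cal = self._three_day_visits()
        daily = {
            0: np.array([[2.0, 0.0], [0.0, 0.0]]),
            1: np.array([[0.0, 1.0], [3.0, 0.0]]),
            2: np.array([[0.0, 0.0], [0.0, 4.0]]),
        }
        pairs = list(itertools.combinations(range(3), 2))
        oracle = np.mean([daily[i] + daily[j] for i, j in pairs], axis=0)
        B = 30000
        net = rarefy_network(visits, cal, "P1", B=B, seed=2)
        got = net.matrix.loc[["A", "B"], ["x", "y"]].to_numpy()
        np.testing.assert_allclose(got, oracle, atol=0.06)

    def test_conservation_network_total_equals_scalar_abundance(self):
        visits, cal = self._three_day_visits()
        (s,) = [
            s for s in rarefy_scalars(visits, cal, B=400, seed=9, per_month=False)
            if s.patch_id == "P1"
        ]
        net = rarefy_network(visits, cal, "P1", B=400, seed=9, scope="season")
        assert net.total == pytest.approx(s.abundance, abs=1e-12)


class TestMonthScopes:
    def test_month_pools_and_dropped_cells(self):
        visits = (
            _visits_for_totals("P1", [2, 4, 6], month=6)
            + _visits_for_totals("P1", [1, 1], month=7)
            + _visits_for_totals("P2", [3, 5], month=6)
        )
        cal = SamplingCalendar.from_records(visits)
        out = rarefy_scalars(visits, cal, B=100, seed=0, per_month=True)
        by = {(s.patch_id, s.scope): s for s in out}
        # June n_min = 2 (P2); P2 is at minimum effort -> identity
        assert by[("P2", "June")].abundance == 8.0
        # P2 has no July day: that cell is absent
        assert ("P2", "July") not in by
        assert by[("P1", "July")].abundance == 2.0

    def test_full_standardization_runs(self, small_study):
        table, networks = standardize_study(
            small_study.visits,
            SamplingCalendar.from_records(small_study.visits, small_study.flowers),
            B=50,
            seed=4,
        )
        assert set(table.columns) >= {"patch", "month", "abundance", "richness"}
        assert len(networks) == 8
        assert all(isinstance(n, QuantNetwork) for n in networks.values())
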