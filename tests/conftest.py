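import datetime as dt

import pytest

from bombnet import (
    FlowerSurveyRecord,
    QuantNetwork,
    SimConfig,
    VisitRecord,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by pipeline-level tests."""
    return simulate_study(SimConfig(n_patches=8), seed=17)


@pytest.fixture
def toy_visits():
    d1 = dt.date(2007, 6, 10)
    d2 = dt.date(2007, 7, 2)
    return [
        VisitRecord("P1", d1, "Bombus A", "x", 2),
        VisitRecord("P1", d1, "Bombus A", "y", 1),
        VisitRecord("P1", d1, "Bombus B", "x", 3),
        VisitRecord("P1", d2, "Bombus B", "y", 4),
        VisitRecord("P2", d1, "Bombus A", "x", 5),
    ]


@pytest.fixture
def worked_pac_network():
    """2x2 example: A visits only x (2), B visits x (2) and y (2)."""
    return QuantNetwork.from_arrays([[2, 0], [2, 2]], ["A", "B"], ["x", "y"])


def quadrat_record(counts, patch="P1", date=dt.date(2007, 6, 5), plant="p"):
    return FlowerSurveyRecord(patch_id=patch, date=date, plant=plant,
                              quadrat_counts=tuple(counts))


def transect_record(total, patch="P1", date=dt.date(2007, 6, 5), plant="p"):
    return FlowerSurveyRecord(patch_id=patch, date=date, plant=plant,
                              transect_total=total)
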