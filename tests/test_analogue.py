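import numpy as np
import pandas as pd
import pytest

from fossilclim.analogue import analogue_distances, analogue_geography, analogue_threshold
from fossilclim.io import AssemblageTable, ClimateTable, percentages
from oracles import min_scd_bruteforce


def table_from(matrix, prefix):
    m = np.asarray(matrix, float)
    return AssemblageTable(
        pd.DataFrame(m, index=[f"{prefix}{i}" for i in range(len(m))],
                     columns=[f"t{j}" for j in range(m.shape[1])])
    )


class TestAnalogueDistances:
    def test_verbatim_sample_has_zero_distance(self, small_scenario):
        s = small_scenario
        report = analogue_distances(s.calibration, s.calibration, n_neighbors=1)
        np.testing.assert_allclose(report.d_min, 0.0, atol=1e-12)

    def test_matches_bruteforce_scan(self, rng):
        cal = table_from(rng.uniform(1, 50, size=(10, 5)), "c")
        fossil = table_from(rng.uniform(1, 50, size=(6, 5)), "f")
        report = analogue_distances(fossil, cal, n_neighbors=3)
        expected = min_scd_bruteforce(
            percentages(fossil).proportions().to_numpy(),
            percentages(cal).proportions().to_numpy(),
        )
        np.testing.assert_allclose(report.d_min, expected, rtol=1e-10)

    def test_adding_calibration_sample_never_increases_dmin(self, rng):
        cal = rng.uniform(1, 50, size=(8, 4))
        fossil = table_from(rng.uniform(1, 50, size=(5, 4)), "f")
        base = analogue_distances(fossil, table_from(cal, "c"), n_neighbors=1)
        extended = analogue_distances(
            fossil, table_from(np.vstack([cal, rng.uniform(1, 50, 4)]), "c"),
            n_neighbors=1,
        )
        assert (extended.d_min <= base.d_min + 1e-12).all()

    def test_empty_calibration_rejected(self, rng):
        fossil = table_from(rng.uniform(1, 50, size=(2, 3)), "f")
        with pytest.raises(ValueError):
            analogue_distances(fossil, table_from(rng.uniform(1, 50, (1, 3)), "c"),
                               n_neighbors=5)


class TestAnalogueThreshold:
    def _report(self, d_min):
        d = np.asarray(d_min, float)
        return analogue_distances.__self__ if False else type(
            "R", (), {"d_min": d, "good": None}
        )()

    def test_rule_application(self):
        r = self._report([0.39, 0.41])
        flags = analogue_threshold(r, reference_distances=[0.2, 0.2])
        assert flags.tolist() == [True, False]

    def test_degenerate_all_zero_reference(self):
        r = self._report([0.0, 0.05])
        flags = analogue_threshold(r, reference_distances=[0.0, 0.0])
        assert flags.tolist() == [True, False]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            analogue_threshold(self._report([0.1]), reference_distances=[])


class TestAnalogueGeography:
    def make_setup(self, coords, comps_cal, comps_fossil):
        cal = table_from(comps_cal, "c")
        fossil = table_from(comps_fossil, "f")
        climate = ClimateTable(
            pd.DataFrame(
                {
                    "t_jul": np.full(len(coords), 12.0),
                    "t_jan": np.full(len(coords), -5.0),
                    "lat": [c[0] for c in coords],
                    "lon": [c[1] for c in coords],
                },
                index=cal.sample_ids,
            )
        )
        return fossil, cal, climate

    def test_identical_analogue_locations_returned_exactly(self, rng):
        comps = rng.uniform(1, 50, size=(5, 4))
        fossil, cal, climate = self.make_setup([(61.0, 25.0)] * 5, comps,
                                               rng.uniform(1, 50, (2, 4)))
        geo = analogue_geography(fossil, cal, climate, n=5)
        np.testing.assert_allclose(geo["lat"], 61.0)
        np.testing.assert_allclose(geo["lon"], 25.0)

    def test_exact_match_takes_all_weight(self, rng):
        comps = rng.uniform(1, 50, size=(4, 3))
        coords = [(60.0, 20.0), (62.0, 22.0), (64.0, 24.0), (66.0, 26.0)]
        fossil, cal, climate = self.make_setup(coords, comps, comps[1:2])
        geo = analogue_geography(fossil, cal, climate, n=3)
        assert geo["lat"].iloc[0] == pytest.approx(62.0)
        assert geo["lon"].iloc[0] == pytest.approx(22.0)

    def test_two_equidistant_analogues_average(self):
        cal = np.array([[80.0, 20.0], [20.0, 80.0]])
        coords = [(60.0, 20.0), (62.0, 30.0)]
        fossil, cal_t, climate = self.make_setup(coords, cal, np.array([[50.0, 50.0]]))
        geo = analogue_geography(fossil, cal_t, climate, n=2)
        assert geo["lat"].iloc[0] == pytest.approx(61.0)
        assert geo["lon"].iloc[0] == pytest.approx(25.0)

    def test_positions_inside_analogue_bounding_box(self, small_scenario):
        s = small_scenario
        geo = analogue_geography(s.fossil, s.calibration, s.climate, n=5)
        lat = s.climate.data["lat"]
        lon = s.climate.data["lon"]
        assert geo["lat"].between(lat.min(), lat.max()).all()
        assert geo["lon"].between(lon.min(), lon.max()).all()

    def test_n_exceeding_calibration_rejected(self, rng):
        comps = rng.uniform(1, 50, size=(3, 3))
        fossil, cal, climate = self.make_setup([(60.0, 20.0)] * 3, comps, comps[:1])
        with pytest.raises(ValueError, match="exceeds"):
            analogue_geography(fossil, cal, climate, n=5)
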