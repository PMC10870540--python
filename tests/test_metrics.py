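import numpy as np
import pandas as pd
import pytest

from nataldisp.metrics import (assemble, density_difference, dispersal_distance,
                               expected_density_difference)
from nataldisp.recovery import simulate_distance_cohort
from nataldisp.spatial import buffer_density, geodesic_km

KM_PER_DEG = 111.195


def _event(natal=(60.0, 25.0), breeding=(60.5, 25.0), hatch=2000,
           natal_t="TN", breeding_t="TB"):
    return pd.Series({
        "individual_id": "W1", "sex": "F",
        "natal_territory": natal_t, "natal_lat": natal[0], "natal_lon": natal[1],
        "hatch_year": hatch,
        "breeding_territory": breeding_t,
        "breeding_lat": breeding[0], "breeding_lon": breeding[1],
        "first_detection_year": hatch + 6, "source": "GENOTYPE",
        "age_at_first_detection": 7,
    })


def _statuses(points, year=2005):
    """points: list of (territory_id, lat, lon, active)."""
    return pd.DataFrame([(t, year, a, f"{t}N0", la, lo) for t, la, lo, a in points],
                        columns=["territory_id", "year", "active", "nest_id", "lat", "lon"])


class TestDistances:
    def test_same_nest_distance_zero(self):
        ev = _event(breeding=(60.0, 25.0))
        assert dispersal_distance(ev) == 0.0

    def test_one_degree_latitude(self):
        ev = _event(natal=(60.0, 25.0), breeding=(61.0, 25.0))
        assert dispersal_distance(ev) == pytest.approx(KM_PER_DEG, abs=1e-3)

    def test_missing_coordinates_rejected(self):
        ev = _event()
        ev["breeding_lat"] = np.nan
        with pytest.raises(ValueError):
            dispersal_distance(ev)


class TestDensityDifference:
    def test_sign_semantics(self):
        # 5 active territories within 10 km of natal, 2 near breeding -> -3
        pts = [("TN", 60.0, 25.0, True)]
        pts += [(f"N{i}", 60.0 + 0.02 * (i + 1), 25.0, True) for i in range(4)]
        pts += [("TB", 62.0, 25.0, True), ("B1", 62.0 + 0.02, 25.0, True)]
        st = _statuses(pts)
        ev = _event(natal=(60.0, 25.0), breeding=(62.0, 25.0))
        assert density_difference(ev, st) == 2 - 5

    def test_identical_nests_give_zero(self):
        st = _statuses([("TN", 60.0, 25.0, True), ("X", 60.02, 25.0, True)])
        ev = _event(breeding=(60.0, 25.0))
        assert density_difference(ev, st) == 0


class TestExpectedDensityDifference:
    def test_single_territory_case(self):
        # one active territory (besides natal cluster) within dispersal range
        pts = [("TN", 60.0, 25.0, True), ("N1", 60.01, 25.0, True),
               ("N2", 60.02, 25.0, True),                  # natal density 3
               ("TB", 60.4, 25.0, True), ("B1", 60.41, 25.0, True)]
        st = _statuses(pts)
        ev = _event(natal=(60.0, 25.0), breeding=(60.4, 25.0))
        val = expected_density_difference(ev, st)
        # brute-force S: active territories within the observed dispersal distance
        dist = dispersal_distance(ev)
        in_s = [(la, lo) for _, la, lo, _ in pts
                if geodesic_km((60.0, 25.0), (la, lo)) <= dist]
        dens = [buffer_density((la, lo), 10, 2005, st) for la, lo in in_s]
        assert len(in_s) == 4  # B1 lies just beyond the dispersal radius
        assert val == pytest.approx(np.mean(dens) - 3.0)

    def test_no_active_territory_in_range_is_undefined(self):
        st = _statuses([("TB", 63.0, 25.0, True)])
        ev = _event(natal=(60.0, 25.0), breeding=(60.1, 25.0))
        assert np.isnan(expected_density_difference(ev, st))

    def test_reduces_to_density_difference_for_singleton_set(self):
        # only the breeding territory is active within the dispersal radius
        st = _statuses([("TB", 60.3, 25.0, True), ("FAR", 64.0, 25.0, True)])
        ev = _event(natal=(60.0, 25.0), breeding=(60.3, 25.0))
        assert expected_density_difference(ev, st) == density_difference(ev, st)


class TestAssemble:
    @staticmethod
    def _events_and_statuses(rng, n=40):
        rows, ctx = simulate_distance_cohort(n, int(rng.integers(2 ** 31)))
        return rows, ctx

    def test_zscored_columns_are_standardised(self, rng):
        rows, _ = self._events_and_statuses(rng)
        for col in ("density30_z", "density10_natal_z", "year_z"):
            assert rows[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert rows[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_three_point_zscore(self):
        x = np.array([1.0, 2.0, 3.0])
        z = (x - x.mean()) / x.std(ddof=1)
        assert z == pytest.approx([-1.0, 0.0, 1.0])

    def test_log_distance_in_metres(self, rng):
        rows, _ = self._events_and_statuses(rng)
        i = 0
        assert rows["log_distance"].iloc[i] == pytest.approx(
            np.log(rows["distance_km"].iloc[i] * 1000.0))
        near50 = (rows["distance_km"] - 50.0).abs().idxmin()
        # a 50 km dispersal sits near the distance-model intercept scale
        assert np.log(50_000.0) == pytest.approx(10.820, abs=1e-3)

    def test_vectorised_densities_match_scalar_oracles(self, rng):
        rows, ctx = self._events_and_statuses(rng, n=30)
        statuses = ctx["statuses"]
        truth = ctx["truth"]["events"].set_index("individual_id")
        for _, row in rows.sample(10, random_state=0).iterrows():
            ev = truth.loc[row["individual_id"]]
            year = int(row["recruit_year"])
            d30 = buffer_density((ev["natal_lat"], ev["natal_lon"]), 30, year, statuses)
            d10n = buffer_density((ev["natal_lat"], ev["natal_lon"]), 10, year, statuses)
            d10b = buffer_density((ev["breeding_lat"], ev["breeding_lon"]), 10, year, statuses)
            assert row["density30_natal"] == d30
            assert row["density_diff"] == d10b - d10n
            scalar = expected_density_difference(
                pd.Series({**ev, "individual_id": row["individual_id"]}), statuses)
            if np.isnan(scalar):
                assert not row["expected_diff_defined"]
            else:
                assert row["expected_diff"] == pytest.approx(scalar)

    def test_assemble_is_pure(self, rng):
        rows1, ctx = self._events_and_statuses(rng, n=20)
        seed = ctx["config"].seed
        rows2, _ = simulate_distance_cohort(20, seed)
        pd.testing.assert_frame_equal(rows1, rows2)

    def test_non_positive_distance_rejected(self):
        st = _statuses([("TN", 60.0, 25.0, True), ("X", 60.3, 25.0, True)])
        ev = pd.DataFrame([_event(breeding=(60.0, 25.0))])
        with pytest.raises(ValueError, match="non-positive"):
            assemble(ev, st)
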