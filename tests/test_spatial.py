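import numpy as np
import pandas as pd
import pytest

from nataldisp.spatial import (buffer_density, distance_to_border_km,
                               geodesic_km, pairwise_km, resolve_status)

KM_PER_DEG = 111.195  # R * pi / 180 for R = 6371.0088


class TestGeodesic:
    def test_coincident_points(self):
        assert geodesic_km((60.0, 25.0), (60.0, 25.0)) == 0.0

    @pytest.mark.parametrize("p,q", [((60.0, 25.0), (61.0, 25.0)),
                                     ((0.0, 0.0), (0.0, 1.0))])
    def test_one_degree_closed_form(self, p, q):
        assert geodesic_km(p, q) == pytest.approx(KM_PER_DEG, abs=1e-3)

    @pytest.mark.parametrize("p", [(91.0, 0.0), (-91.0, 0.0), (0.0, 181.0)])
    def test_out_of_range_coordinates_rejected(self, p):
        with pytest.raises(ValueError):
            geodesic_km(p, (0.0, 0.0))

    def test_symmetry_and_triangle_inequality(self, rng):
        pts = np.column_stack([rng.uniform(-80, 80, 3000),
                               rng.uniform(-179, 179, 3000)]).reshape(1000, 3, 2)
        for p, q, r in pts:
            dpq = geodesic_km(p, q)
            assert dpq == pytest.approx(geodesic_km(q, p), abs=1e-9)
            assert dpq <= geodesic_km(p, r) + geodesic_km(r, q) + 1e-9


class TestResolveStatus:
    @staticmethod
    def _nests(stages):
        return pd.DataFrame({
            "territory_id": "T1",
            "nest_id": [f"N{i}" for i in range(len(stages))],
            "lat": 60.0, "lon": 25.0, "year": 2000, "stage": stages,
        })

    def test_all_zero_stages_inactive(self):
        st = resolve_status(self._nests([0, 0]))
        assert not st["active"].iloc[0]

    def test_furthest_advanced_nest_is_representative(self):
        st = resolve_status(self._nests([1, 3]))
        assert st["active"].iloc[0]
        assert st["nest_id"].iloc[0] == "N1"

    def test_stage_tie_broken_by_smallest_nest_id(self):
        st = resolve_status(self._nests([2, 2]))
        assert st["active"].iloc[0]
        assert st["nest_id"].iloc[0] == "N0"

    def test_activity_monotone_in_stage(self):
        base = resolve_status(self._nests([0, 0]))["active"].sum()
        raised = resolve_status(self._nests([0, 1]))["active"].sum()
        assert raised >= base

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            resolve_status(pd.DataFrame({"territory_id": ["T1"]}))


def _random_statuses(rng, n=60, year=2000):
    return pd.DataFrame({
        "territory_id": [f"T{i}" for i in range(n)],
        "year": year,
        "active": rng.random(n) < 0.7,
        "nest_id": [f"T{i}N0" for i in range(n)],
        "lat": rng.uniform(59, 66, n),
        "lon": rng.uniform(20, 30, n),
    })


class TestBufferDensity:
    def test_no_active_territories(self):
        st = pd.DataFrame(columns=["territory_id", "year", "active", "nest_id", "lat", "lon"])
        assert buffer_density((60, 25), 30, 2000, st) == 0

    def test_boundary_inclusive(self):
        # territories almost exactly 29.9 and 30.1 km due north
        st = pd.DataFrame({
            "territory_id": ["A", "B"], "year": 2000, "active": True,
            "nest_id": ["a", "b"],
            "lat": [60.0 + 29.9 / KM_PER_DEG, 60.0 + 30.1 / KM_PER_DEG],
            "lon": 25.0,
        })
        assert buffer_density((60.0, 25.0), 30.0, 2000, st) == 1

    def test_matches_brute_force_scan(self, rng):
        for _ in range(100):
            st = _random_statuses(rng)
            center = (rng.uniform(59, 66), rng.uniform(20, 30))
            r = rng.uniform(5, 200)
            expected = sum(
                1 for _, row in st.iterrows()
                if row["active"] and geodesic_km(center, (row["lat"], row["lon"])) <= r)
            assert buffer_density(center, r, 2000, st) == expected

    def test_monotone_in_radius(self, rng):
        st = _random_statuses(rng)
        center = (62.0, 25.0)
        counts = [buffer_density(center, r, 2000, st) for r in (5, 20, 50, 100, 400)]
        assert counts == sorted(counts)

    def test_exclude_focal_territory(self, rng):
        st = _random_statuses(rng)
        st.loc[0, ["active", "lat", "lon"]] = [True, 62.0, 25.0]
        full = buffer_density((62.0, 25.0), 30, 2000, st)
        without = buffer_density((62.0, 25.0), 30, 2000, st, exclude="T0")
        assert full - without == 1


class TestBorderDistance:
    BORDER = np.array([[70.0, 20.0], [50.0, 20.0]])

    def test_point_on_vertex(self):
        assert distance_to_border_km((70.0, 20.0), self.BORDER) == pytest.approx(0, abs=1e-9)

    def test_meridian_segment_offset(self):
        # 1 degree of longitude at 60 N
        assert distance_to_border_km((60.0, 21.0), self.BORDER) == pytest.approx(55.6, abs=0.2)

    def test_never_exceeds_vertex_distances(self, rng):
        border = np.column_stack([rng.uniform(55, 65, 8), rng.uniform(18, 30, 8)])
        for _ in range(50):
            p = (rng.uniform(55, 65), rng.uniform(18, 30))
            d = distance_to_border_km(p, border)
            assert d <= min(geodesic_km(p, v) for v in border) + 1e-9

    def test_matches_dense_sampling_oracle(self, rng):
        border = np.array([[66.0, 20.0], [63.0, 22.0], [60.0, 21.0]])
        # dense points along each great-circle segment (spherical interpolation)
        def to_xyz(lat, lon):
            la, lo = np.radians(lat), np.radians(lon)
            return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])

        segs = []
        for a, b in zip(border[:-1], border[1:]):
            va, vb = to_xyz(*a), to_xyz(*b)
            omega = np.arccos(np.clip(va @ vb, -1, 1))
            t = np.linspace(0, 1, 4000)[:, None]
            v = (np.sin((1 - t) * omega) * va + np.sin(t * omega) * vb) / np.sin(omega)
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            segs.append(np.column_stack([np.degrees(np.arcsin(v[:, 2])),
                                         np.degrees(np.arctan2(v[:, 1], v[:, 0]))]))
        dense = np.concatenate(segs)
        for _ in range(20):
            p = (rng.uniform(59, 67), rng.uniform(18, 26))
            oracle = pairwise_km(np.array([p]), dense)[0].min()
            assert distance_to_border_km(p, border) == pytest.approx(oracle, abs=0.05)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            distance_to_border_km((60, 20), np.array([[60.0, 20.0]]))
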