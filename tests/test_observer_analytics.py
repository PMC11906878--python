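import datetime as dt
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anthropause.ingest import PeriodWindow
from anthropause.observer_analytics import (classify_migration,
                                            compare_area_distributions,
                                            compute_activity_range,
                                            count_active_observers,
                                            select_top_observers,
                                            spherical_polygon_area_km2,
                                            unwrap_longitudes)
from anthropause.synthetic_data import (default_world, generate_world,
                                        make_fixture,
                                        simulate_migration_cohort)

from conftest import record

KM_PER_DEG = 111.195
WINDOW = PeriodWindow(year=2019)


class TestParticipation:
    def test_unique_observer_count(self):
        recs = [record(obs=o, date=dt.date(2019, 4, 1), rid=f"r{i}")
                for i, o in enumerate("aabbbcaaac")]
        assert count_active_observers(recs, "US", WINDOW) == 3

    def test_empty_window_counts_zero(self):
        recs = [record(date=dt.date(2018, 4, 1))]
        assert count_active_observers(recs, "US", WINDOW) == 0

    def test_non_ebird_records_ignored(self):
        recs = [record(tag="other", obs=None, date=dt.date(2019, 4, 1))]
        assert count_active_observers(recs, "US", WINDOW) == 0


class TestTopObservers:
    def test_days_then_records_then_id_tie_break(self):
        fx = make_fixture("tie-break")
        ranked = select_top_observers(fx["records"], "US", fx["window"])
        assert ranked == fx["expected_ranking"]
        assert select_top_observers(fx["records"], "US", fx["window"],
                                    k=2) == ["A", "C"]

    def test_all_returned_when_fewer_than_k(self):
        fx = make_fixture("tie-break")
        assert len(select_top_observers(fx["records"], "US", fx["window"],
                                        k=30)) == 3

    def test_planted_schedule_recovered(self, rng):
        recs = []
        rid = 0
        for i, n_days in enumerate([10, 8, 6, 4, 2]):
            for d in range(n_days):
                recs.append(record(obs=f"o{i}", rid=f"r{rid}",
                                   date=dt.date(2019, 4, 1)
                                   + dt.timedelta(d)))
                rid += 1
        assert select_top_observers(recs, "US", WINDOW, k=3) == \
            ["o0", "o1", "o2"]


class TestActivityRange:
    def test_collinear_points_have_zero_area(self):
        ar = compute_activity_range([(0, 0), (0.5, 0.5), (1, 1)])
        assert ar.area_km2 == 0.0

    def test_unit_square_matches_planar_oracle(self):
        ar = compute_activity_range([(0, 0), (1, 0), (1, 1), (0, 1)])
        oracle = KM_PER_DEG ** 2
        assert ar.area_km2 == pytest.approx(oracle, rel=0.005)

    def test_area_invariant_under_duplication_and_order(self, rng):
        pts = [(float(x), float(y)) for x, y in
               rng.uniform(0, 1, (12, 2))]
        base = compute_activity_range(pts).area_km2
        shuffled = list(pts)[::-1] + pts[:5]
        assert compute_activity_range(shuffled).area_km2 == \
            pytest.approx(base, rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(min_value=0, max_value=2, allow_nan=False),
        st.floats(min_value=0, max_value=2, allow_nan=False)),
        min_size=3, max_size=12),
        st.tuples(st.floats(min_value=0, max_value=2),
                  st.floats(min_value=0, max_value=2)))
    def test_adding_a_point_never_shrinks_the_hull(self, pts, extra):
        before = compute_activity_range(pts).area_km2
        after = compute_activity_range(pts + [extra]).area_km2
        assert after >= before - 1e-9

    def test_antimeridian_unwrap_and_area(self):
        fx = make_fixture("antimeridian")
        ar = compute_activity_range(fx["points"])
        assert ar.area_km2 == pytest.approx(fx["oracle_area_km2"],
                                            rel=0.005)

    def test_ambiguous_longitude_spread_rejected(self):
        with pytest.raises(ValueError, match="unwrapping"):
            unwrap_longitudes(np.array([0.0, 120.0, -120.0]))

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="WGS84"):
            compute_activity_range([(0, 95.0), (1, 1), (2, 2)])

    def test_single_point_retained_with_zero_area(self):
        ar = compute_activity_range([(10.0, 10.0)])
        assert ar.area_km2 == 0.0 and ar.n_distinct_points == 1


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        D, p = compare_area_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        D, _ = compare_area_distributions([0, 0, 0], [1, 1, 1])
        assert D == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_area_distributions([], [1.0])

    def test_exact_p_equals_permutation_enumeration(self, rng):
        """For small equal samples the exact p must coincide with the
        brute-force distribution of D over all C(2n, n) splits."""
        n = 5
        pooled = rng.normal(size=2 * n)  # continuous: no ties
        a, b = pooled[:n], pooled[n:]
        D_obs, p_exact = compare_area_distributions(a, b)
        count = 0
        idx = set(range(2 * n))
        total = 0
        for left in combinations(range(2 * n), n):
            right = tuple(sorted(idx - set(left)))
            xs, ys = pooled[list(left)], pooled[list(right)]
            grid = np.sort(pooled)
            cdfx = np.searchsorted(np.sort(xs), grid, side="right") / n
            cdfy = np.searchsorted(np.sort(ys), grid, side="right") / n
            D = np.max(np.abs(cdfx - cdfy))
            count += D >= D_obs - 1e-12
            total += 1
        assert p_exact == pytest.approx(count / total, abs=1e-12)


class TestMigration:
    def _recs(self, codes):
        return [record(code=c, rid=f"r{i}", date=dt.date(2020, 4, 1))
                for i, c in enumerate(codes)]

    def test_origin_only_is_returned(self):
        p = classify_migration("o", "US", self._recs(["US", "US"]))
        assert p.status == "returned" and p.returned

    def test_no_records_is_inactive(self):
        p = classify_migration("o", "US", [])
        assert p.status == "inactive" and p.lockdown_countries == set()

    def test_returned_takes_precedence_over_elsewhere(self):
        p = classify_migration("o", "US", self._recs(["MX", "US", "CA"]))
        assert p.status == "returned"
        assert p.lockdown_countries == {"MX", "US", "CA"}

    def test_only_elsewhere_is_migrated(self):
        p = classify_migration("o", "KE", self._recs(["GB"]))
        assert p.status == "migrated"

    def test_unknown_country_code_is_an_error(self):
        bad = [record(code="US", rid="r0", date=dt.date(2020, 4, 1))]
        object.__setattr__(bad[0], "country_code", "Q7")
        with pytest.raises(ValueError, match="Q7"):
            classify_migration("o", "US", bad)

    def test_destination_classes_resolved(self):
        econ = {"US": "developed", "KE": "developing"}
        p = classify_migration("o", "US", self._recs(["KE", "US"]), econ)
        assert p.destination_classes == ["developing", "developed"]

    @pytest.mark.parametrize("borders", ["open", "closed"])
    def test_cohort_classification_matches_ledger(self, borders):
        recs, truth = simulate_migration_cohort(
            np.random.default_rng(4), n_observers=800, borders=borders)
        for row in truth.itertuples():
            p = classify_migration(row.observer_id, row.origin,
                                   recs[row.observer_id])
            assert p.status == row.status
            assert sorted(p.lockdown_countries) == row.countries


def test_lockdown_movement_contraction_shrinks_median_range():
    """With the walk scale halved in 2020, the median activity range of a
    country's top observers contracts between the two windows."""
    cfg = default_world(n_countries=8, seed=5, observers_per_country=25)
    world = generate_world(cfg)
    led = world.ledger["observers"]
    occ = world.occurrences
    ebird = occ[occ.datasetTag == "ebird"]
    shrunk = 0
    n_countries = 0
    for code in world.covariates["country_code"]:
        areas = {2019: [], 2020: []}
        for year in (2019, 2020):
            sub = ebird[(ebird.countryCode == code) &
                        (ebird.eventDate.str[:4] == str(year))]
            for oid, grp in sub.groupby("observerId"):
                pts = list(zip(grp.decimalLongitude.astype(float),
                               grp.decimalLatitude.astype(float)))
                if len(pts) >= 3:
                    areas[year].append(
                        compute_activity_range(pts).area_km2)
        if len(areas[2019]) >= 10 and len(areas[2020]) >= 10:
            n_countries += 1
            shrunk += (np.median(areas[2020]) < np.median(areas[2019]))
    assert n_countries >= 4
    assert shrunk / n_countries >= 0.75
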