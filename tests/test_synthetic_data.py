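import numpy as np
import pytest

from anthropause.change_metrics import change_table
from anthropause.ingest import exclude_high_seas, parse_occurrences
from anthropause.synthetic_data import (CountryConfig, SyntheticWorldConfig,
                                        default_world, generate_world,
                                        make_fixture, simulate_change_frame,
                                        simulate_trend_series)


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_outputs(self):
        cfg = default_world(n_countries=6, seed=9, observers_per_country=8)
        a, b = generate_world(cfg), generate_world(cfg)
        assert a.occurrences.equals(b.occurrences)
        assert a.covariates.equals(b.covariates)
        assert a.ledger == b.ledger

    def test_written_files_are_byte_identical(self, tmp_path):
        cfg = default_world(n_countries=4, seed=2, observers_per_country=5)
        generate_world(cfg).write(tmp_path / "a")
        generate_world(cfg).write(tmp_path / "b")
        for name in ("occurrences.tsv", "covariates.csv", "ledger.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seed_changes_the_world(self):
        cfg = default_world(n_countries=4, seed=2, observers_per_country=5)
        a = generate_world(cfg, seed=2)
        b = generate_world(cfg, seed=3)
        assert not a.occurrences.equals(b.occurrences)


class TestNullWorld:
    def test_mean_change_is_zero_without_lockdown_effect(self):
        """m = 1 for every class and g = 0: the mean percent change across
        200 replicate frames sits within 2% of zero."""
        rng = np.random.default_rng(31)
        unit = {c: 1.0 for c in ("developed", "emerging", "developing",
                                 "least_developed")}
        means = []
        for _ in range(200):
            frame, _ = simulate_change_frame(
                rng, multipliers=unit, growth=0.0)
            means.append(frame["change_pct"].mean())
        assert abs(np.mean(means)) < 2.0

    def test_half_rate_class_halves_its_counts(self):
        rng = np.random.default_rng(32)
        mult = {"developed": 1.0, "emerging": 1.0, "developing": 0.5,
                "least_developed": 1.0}
        vals = []
        for _ in range(100):
            frame, _ = simulate_change_frame(
                rng, multipliers=mult, growth=0.0, multiplier_log_sd=0.0)
            sub = frame[frame["economic_class"] == "developing"]
            vals.append(sub["change_pct"].mean())
        assert np.mean(vals) == pytest.approx(-50.0, abs=2.0)


class TestLedger:
    def test_high_seas_bookkeeping_is_exact(self, tmp_path):
        cfg = default_world(n_countries=5, seed=6, observers_per_country=6)
        cfg.high_seas_frac = 0.05
        world = generate_world(cfg)
        world.write(tmp_path)
        parsed = parse_occurrences(tmp_path / "occurrences.tsv")
        assert parsed.rejections.total == 0
        kept = exclude_high_seas(parsed.records)
        assert len(parsed.records) - len(kept) == \
            world.ledger["n_records_high_seas"]
        assert len(kept) == world.ledger["n_records_land"]

    def test_closed_borders_ground_international_visitors(self):
        cfg = default_world(n_countries=12, seed=13,
                            observers_per_country=15, borders="closed")
        cfg.observer.travel_prob = 0.5
        world = generate_world(cfg)
        led = world.ledger["observers"]
        visitors = [o for o in led.values()
                    if o["present_2019"] != o["home"]]
        assert visitors, "the 2019 world should contain travellers"
        for o in led.values():
            assert o["present_2020"] == o["home"]
        # every 2019 visitor is inactive-or-elsewhere w.r.t. the country
        # they visited: none recorded there again in 2020
        for o in visitors:
            assert o["present_2019"] not in o["countries_2020"]

    def test_expected_counts_derivable_from_ledger(self):
        cfg = default_world(n_countries=4, seed=1, observers_per_country=5)
        world = generate_world(cfg)
        occ = world.occurrences
        for code, entry in world.ledger["countries"].items():
            lam = entry["lambda_by_year"]
            assert lam["2020"] == pytest.approx(
                entry["baseline_rate"] * (1 + entry["growth"]) ** 10
                * entry["lockdown_multiplier"], rel=1e-12)
            n2015 = ((occ.countryCode == code) &
                     (occ.eventDate.str[:4] == "2015")).sum()
            assert abs(n2015 - lam["2015"]) < 6 * np.sqrt(lam["2015"]) + 3


class TestValidation:
    def test_zero_countries_rejected(self):
        cfg = SyntheticWorldConfig(countries=[])
        with pytest.raises(ValueError, match="zero countries"):
            generate_world(cfg)

    def test_bad_bbox_rejected(self):
        cfg = SyntheticWorldConfig(countries=[CountryConfig(
            code="US", economic_class="developed",
            bbox=(10, 10, 5, 20), baseline_rate=50)])
        with pytest.raises(ValueError, match="bbox"):
            generate_world(cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_world(n_countries=3, seed=4)
        path = tmp_path / "world.yaml"
        cfg.to_yaml(path)
        back = SyntheticWorldConfig.from_yaml(path)
        assert back == cfg


class TestFixturesAndSeries:
    def test_minimal_fixture_realises_declared_changes(self, tmp_path):
        fx = make_fixture("minimal")
        path = tmp_path / "occ.tsv"
        fx["occurrences"].to_csv(path, sep="\t", index=False)
        records = parse_occurrences(path).records
        from anthropause.ingest import count_records, lockdown_window
        t0 = count_records(records, lockdown_window(2019))
        t1 = count_records(records, lockdown_window(2020))
        table = change_table(t0, t1).set_index("country_code")
        for code, expected in fx["expected_change_pct"].items():
            assert table.loc[code, "change_pct"] == expected

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            make_fixture("nope")

    def test_trend_series_shock_reduces_focal_year(self, rng):
        years, clean = simulate_trend_series(rng, shock_sd=0.0)
        years2, shocked = simulate_trend_series(
            np.random.default_rng(0), shock_sd=6.0)
        _, unshocked = simulate_trend_series(
            np.random.default_rng(0), shock_sd=0.0)
        i = int(np.flatnonzero(years2 == 2020)[0])
        assert shocked[i] < unshocked[i]
        assert np.all(shocked[:i] == unshocked[:i])
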