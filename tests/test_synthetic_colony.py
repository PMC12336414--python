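import datetime as dt

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from burrowcall.synthetic_colony import (
    ColonyConfig,
    NightConditions,
    TarsusGrowth,
    build_chick_profiles,
    chick_call_curve,
    generate_colony,
    simulate_breeding_outcomes,
    simulate_night_conditions,
    simulate_nightly_calling,
    simulate_observer_check,
    simulate_playback_survey,
    NIGHT_WINDOW_S,
)


class TestGenerateColony:
    def test_empty_colony_is_valid(self):
        cfg = ColonyConfig(nests_per_plot_range=(0, 0), seed=1)
        plots, nests = generate_colony(cfg)
        assert len(plots) == cfg.n_plots
        assert len(nests) == 0

    def test_plot_and_nest_counts_in_configured_range(self):
        cfg = ColonyConfig(n_plots=10, nests_per_plot_range=(10, 30), seed=2)
        plots, nests = generate_colony(cfg)
        assert len(plots) == 10
        counts = nests.groupby("plot_id").size()
        assert len(counts) == 10
        assert counts.between(10, 30).all()

    def test_positions_within_wall_and_probs_in_range(self):
        cfg = ColonyConfig(seed=3)
        _, nests = generate_colony(cfg)
        assert nests["position_m"].abs().le(cfg.wall_halflength_m).all()
        lo, hi = cfg.response_prob_range
        assert nests["response_prob"].between(lo, hi).all()

    def test_same_seed_reproduces_identical_tables(self):
        cfg = ColonyConfig(seed=42)
        _, a = generate_colony(cfg)
        _, b = generate_colony(cfg)
        pdt.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(nests_per_plot_range=(5, 3)),
            dict(response_prob_range=(0.5, 1.2)),
            dict(wall_halflength_m=-1.0),
        ],
    )
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ValueError):
            ColonyConfig(**bad)


class TestBreedingOutcomes:
    def test_target_one_means_every_occupied_nest_succeeds(self):
        cfg = ColonyConfig(seed=5)
        _, nests = generate_colony(cfg)
        out = simulate_breeding_outcomes(nests, 1.0, 6, cfg)
        occ = out[out["occupied"]]
        assert (occ["outcome"] == "success").all()

    def test_realised_success_near_target(self):
        # binomial oracle: SE = sqrt(0.75 * 0.25 / 4000) ~ 0.007
        cfg = ColonyConfig(n_plots=200, nests_per_plot_range=(20, 20), seed=7)
        _, nests = generate_colony(cfg)
        out = simulate_breeding_outcomes(nests, 0.75, 8, cfg)
        occ = out[out["occupied"]]
        rate = (occ["outcome"] == "success").mean()
        assert rate == pytest.approx(0.75, abs=0.03)

    def test_failures_concentrated_before_day_24(self):
        cfg = ColonyConfig(n_plots=50, nests_per_plot_range=(20, 20), seed=9)
        _, nests = generate_colony(cfg)
        out = simulate_breeding_outcomes(nests, 0.75, 10, cfg)
        failed = out[out["outcome"].isin(["fail_incubation", "fail_chick"])]
        early = (
            (failed["outcome"] == "fail_incubation")
            | (failed["failure_day"] <= 24)
        )
        assert early.mean() >= 0.90

    def test_outcome_conservation(self, colony):
        _, _, nests, _ = colony
        counts = nests["outcome"].value_counts()
        assert counts.sum() == len(nests)

    def test_invalid_target_rejected(self, colony):
        _, _, nests, _ = colony
        with pytest.raises(ValueError):
            simulate_breeding_outcomes(nests, 1.4, 1)


class TestNightlyCalling:
    def test_unoccupied_colony_emits_no_events(self, august_night):
        cfg = ColonyConfig(occupancy_prob=0.0, seed=20)
        _, nests = generate_colony(cfg)
        nests = simulate_breeding_outcomes(nests, 0.75, 21, cfg)
        prof = build_chick_profiles(nests, cfg, 22)
        events = simulate_nightly_calling(nests, august_night, prof, 23)
        assert len(events) == 0

    def test_event_durations_and_window(self, colony, august_night):
        _, _, nests, prof = colony
        events = simulate_nightly_calling(nests, august_night, prof, 24)
        assert len(events) > 1000
        for ct, (lo, hi) in {
            "adult_purr": (1.0, 2.0),
            "adult_chat": (0.8, 1.5),
            "chick_beg": (0.2, 0.5),
        }.items():
            durs = events.loc[events["call_type"] == ct, "duration_s"]
            assert durs.between(lo, hi).all()
        assert (events["start_s"] >= 0).all()
        assert (events["start_s"] + events["duration_s"] <= NIGHT_WINDOW_S).all()

    def test_purr_durations_stay_in_one_to_two_seconds(self, colony):
        # pooled across nights to exceed 10,000 purr events
        _, _, nests, prof = colony
        all_durs = []
        for i, day in enumerate(range(5, 12)):
            night = NightConditions(dt.date(2023, 7, day), 0.1)
            ev = simulate_nightly_calling(nests, night, prof, 100 + i)
            all_durs.append(ev.loc[ev["call_type"] == "adult_purr", "duration_s"])
        durs = pd.concat(all_durs)
        assert len(durs) > 10_000
        assert durs.between(1.0, 2.0).all()

    def test_chicks_can_beg_from_day_zero(self):
        assert chick_call_curve(0) > 0
        assert (chick_call_curve(np.arange(0, 6)) > 0).all()

    def test_age_curve_shape(self):
        # rises to ~2 weeks, dips slightly, plateaus
        c2, c14, c25 = chick_call_curve([2.0, 14.0, 25.0])
        assert c14 > c2
        assert abs(c25 - c14) <= 0.5 * c14

    def test_simulated_seconds_follow_age_curve(self, colony):
        _, _, nests, prof = colony
        # same chicks observed at ages 2, 14 and 25 days
        means = {}
        for age in (2, 14, 25):
            totals = []
            for rep in range(6):
                date = pd.Timestamp(prof["hatch_date"].iloc[0]).date() + dt.timedelta(days=age)
                night = NightConditions(date, 0.0)
                one = prof.iloc[[0]].copy()
                ev = simulate_nightly_calling(
                    nests[nests["nest_id"] == one["nest_id"].iloc[0]],
                    night,
                    one,
                    rep,
                )
                totals.append(
                    ev.loc[ev["call_type"] == "chick_beg", "duration_s"].sum()
                )
            means[age] = np.mean(totals)
        assert means[14] > means[2]
        assert abs(means[25] - means[14]) <= 0.5 * means[14]


class TestPlaybackSurvey:
    def test_certain_responders_answer_every_visit(self):
        cfg = ColonyConfig(response_prob_range=(1.0, 1.0), seed=30)
        _, nests = generate_colony(cfg)
        hist = simulate_playback_survey(nests, 7, 31)
        assert (hist["response"] == 1).all()

    def test_unoccupied_nests_never_respond(self):
        cfg = ColonyConfig(occupancy_prob=0.0, seed=32)
        _, nests = generate_colony(cfg)
        hist = simulate_playback_survey(nests, 7, 33)
        assert (hist["response"] == 0).all()

    def test_never_detected_fraction_matches_closed_form(self):
        # 100 * (1 - 0.28)**7 = 10.03%
        cfg = ColonyConfig(
            n_plots=100,
            nests_per_plot_range=(400, 400),
            response_prob_range=(0.28, 0.28),
            seed=34,
        )
        _, nests = generate_colony(cfg)
        hist = simulate_playback_survey(nests, 7, 35)
        never = (hist.groupby("nest_id")["response"].sum() == 0).mean()
        assert never * 100 == pytest.approx(10.03, abs=0.4)

    def test_per_visit_response_calibration(self):
        # realised per-visit frequency within 3 binomial SEs of the prob
        p = 0.3
        n = 2000
        cfg = ColonyConfig(
            n_plots=20,
            nests_per_plot_range=(100, 100),
            response_prob_range=(p, p),
            seed=36,
        )
        _, nests = generate_colony(cfg)
        hist = simulate_playback_survey(nests, 7, 37)
        freq = hist["response"].mean()
        se = np.sqrt(p * (1 - p) / (len(nests) * 7))
        assert abs(freq - p) <= 3 * se

    def test_zero_visits_rejected(self, colony):
        _, _, nests, _ = colony
        with pytest.raises(ValueError):
            simulate_playback_survey(nests, 0, 1)


class TestObserverCheck:
    def test_incubation_failure_recorded_absent(self):
        nests = pd.DataFrame(
            [
                {
                    "nest_id": "P01-N001",
                    "plot_id": "P01",
                    "occupied": True,
                    "hatch_date": pd.NaT,
                    "outcome": "fail_incubation",
                    "failure_day": np.nan,
                }
            ]
        )
        rec = simulate_observer_check(nests, dt.date(2023, 8, 21))
        assert not rec["chick_present"].iloc[0]
        assert np.isnan(rec["tarsus_mm"].iloc[0])

    def test_age_estimated_within_one_day_at_24(self):
        hatch = pd.Timestamp("2023-07-28")
        nests = pd.DataFrame(
            [
                {
                    "nest_id": "P01-N001",
                    "plot_id": "P01",
                    "occupied": True,
                    "hatch_date": hatch,
                    "outcome": "success",
                    "failure_day": np.nan,
                }
            ]
        )
        for seed in range(10):
            rec = simulate_observer_check(
                nests, dt.date(2023, 8, 21), seed=seed
            )  # true age 24 d
            assert rec["chick_present"].iloc[0]
            assert abs(rec["est_age_days"].iloc[0] - 24) <= 1

    def test_growth_curve_round_trip(self):
        growth = TarsusGrowth()
        ages = np.arange(5.0, 31.0)
        tarsus = np.round(growth.age_to_tarsus(ages), 1)  # measured to 0.1 mm
        back = growth.tarsus_to_age(tarsus)
        assert np.all(np.abs(back - ages) <= 1.0)

    def test_growth_strictly_increasing(self):
        growth = TarsusGrowth()
        t = growth.age_to_tarsus(np.arange(0, 31))
        assert np.all(np.diff(t) > 0)


class TestNightConditions:
    def test_moon_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            NightConditions(dt.date(2023, 7, 1), 1.2)

    def test_season_table_covers_every_plot_night(self):
        cfg = ColonyConfig(seed=40)
        nights = simulate_night_conditions(cfg, 41)
        n_days = (cfg.season_end - cfg.season_start).days + 1
        assert len(nights) == n_days * cfg.n_plots
        assert nights["moon_fraction"].between(0, 1).all()
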