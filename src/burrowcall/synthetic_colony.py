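"""Synthetic storm-petrel colony generator.

Simulates the study system that the rest of the package analyses: a set of
survey plots along dry-stone walls, each holding burrow-nesting European
storm petrels (*Hydrobates pelagicus*), with

* nests placed uniformly along a 1-D wall (signed metres from plot centre),
* per-visit playback response probabilities per nest,
* nightly calling behaviour for three call types (adult purr, adult chat,
  chick beg) inside the fixed 22:00-02:00 recording window,
* an age-dependent chick begging-rate curve (rise to ~2 weeks, slight dip,
  then plateau) with per-chick and per-night satiation variation,
* breeding outcomes calibrated to an overall success target, with chick-stage
  failures concentrated in the first ~24 days post-hatch,
* observer nest checks with tarsus measurement and tarsus-based chick aging.

Everything is driven by :class:`ColonyConfig` plus integer seeds, and is
byte-reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ColonyConfig",
    "CallRateParams",
    "TarsusGrowth",
    "NightConditions",
    "generate_colony",
    "simulate_breeding_outcomes",
    "build_chick_profiles",
    "chick_call_curve",
    "simulate_night_conditions",
    "simulate_nightly_calling",
    "simulate_playback_survey",
    "simulate_observer_check",
    "NIGHT_WINDOW_S",
]

#: Length of the nightly recording window (22:00-02:00), in seconds.
NIGHT_WINDOW_S = 4 * 3600

# Whole-call duration ranges (s) used when drawing call events on the
# event-level fast path.  These mirror the acoustic call-type table in
# :mod:`burrowcall.acoustic_events`; kept numeric here so the colony module
# does not depend on the audio module.
_EVENT_DURATION_S = {
    "adult_purr": (1.0, 2.0),
    "adult_chat": (0.8, 1.5),
    "chick_beg": (0.2, 0.5),
}

_OUTCOMES = ("success", "fail_incubation", "fail_chick", "empty")


@dataclass(frozen=True)
class CallRateParams:
    """Nightly calling-rate parameters (seconds of voiced call per night).

    Defaults are chosen to match the study conditions: plot-level detected
    purr rates in excess of ~200 s/night and chat rates of ~40 s/night for
    plots of 10-30 pairs (roughly half of which sit within detection range),
    and chick begging peaking at tens of seconds per chick-night.
    """

    purr_s_per_nest: float = 20.0  #: voiced purr seconds per male per night
    chat_s_per_nest: float = 3.5  #: voiced chat seconds per occupied nest
    chick_peak_s: float = 60.0  #: peak begging seconds per chick-night (age ~14 d)
    nest_lognorm_sd: float = 0.5  #: between-nest heterogeneity (log scale)
    night_lognorm_sd: float = 0.35  #: shared colony-wide night effect
    plot_night_lognorm_sd: float = 0.25  #: plot x night effect
    satiation_lognorm_sd: float = 0.4  #: per-chick-night satiation factor
    moon_suppression: float = 0.5  #: calling multiplier is 1 - s * moon**3


@dataclass(frozen=True)
class TarsusGrowth:
    """Stand-in monotone tarsus-vs-age growth curve.

    A saturating (von Bertalanffy) curve ``tarsus(a) = A - (A - t0) exp(-k a)``
    with parameters held in config.  Only its strict monotonicity, and hence
    invertibility, up to ~30 days of age matters: it exists so that observer
    checks can age chicks from tarsus length to the nearest day, the way
    field workers do with a published growth model.
    """

    tarsus_hatch_mm: float = 8.0
    tarsus_asymptote_mm: float = 24.0
    rate_per_day: float = 0.10
    measurement_sd_mm: float = 0.05

    def age_to_tarsus(self, age_days):
        a = np.asarray(age_days, dtype=float)
        span = self.tarsus_asymptote_mm - self.tarsus_hatch_mm
        return self.tarsus_asymptote_mm - span * np.exp(-self.rate_per_day * a)

    def tarsus_to_age(self, tarsus_mm):
        t = np.asarray(tarsus_mm, dtype=float)
        span = self.tarsus_asymptote_mm - self.tarsus_hatch_mm
        # clip into the open range so the inverse is defined
        frac = np.clip(
            (self.tarsus_asymptote_mm - t) / span, 1e-9, 1.0
        )
        return -np.log(frac) / self.rate_per_day


@dataclass(frozen=True)
class NightConditions:
    """Conditions for one recording night."""

    date: dt.date
    moon_fraction: float
    usable: bool = True

    def __post_init__(self):
        if not 0.0 <= self.moon_fraction <= 1.0:
            raise ValueError(
                f"moon_fraction must be in [0, 1], got {self.moon_fraction}"
            )


@dataclass(frozen=True)
class ColonyConfig:
    """Configuration of a synthetic colony and its survey season.

    Defaults reproduce the study conditions: 10 plots of 10-30 nests along
    stone walls surveyed over a June-August season, per-visit playback
    response probabilities averaging ~0.3 (so that ~10% of nests go
    undetected over seven visits), a late-July mean hatch date, and overall
    breeding success near 0.75.
    """

    n_plots: int = 10
    nests_per_plot_range: tuple[int, int] = (10, 30)
    wall_halflength_m: float = 50.0
    plot_spacing_m: float = 55.0
    occupancy_prob: float = 1.0
    response_prob_range: tuple[float, float] = (0.20, 0.40)
    response_prob_per_nest: bool = True
    male_present_prob: float = 0.95
    season_start: dt.date = dt.date(2023, 6, 7)
    season_end: dt.date = dt.date(2023, 8, 29)
    hatch_date_mean: dt.date = dt.date(2023, 7, 28)
    hatch_date_sd: float = 4.0
    incubation_days: int = 41
    overall_success_target: float = 0.75
    incubation_failure_frac: float = 0.6
    chick_failure_scale_days: float = 8.5
    max_chick_failure_day: int = 45
    p_usable: float = 0.88
    full_moon_date: dt.date = dt.date(2023, 7, 3)
    lunar_period_days: float = 29.53
    rates: CallRateParams = field(default_factory=CallRateParams)
    tarsus: TarsusGrowth = field(default_factory=TarsusGrowth)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.nests_per_plot_range
        if lo > hi or lo < 0:
            raise ValueError(f"invalid nests_per_plot_range {self.nests_per_plot_range}")
        rlo, rhi = self.response_prob_range
        if not (0.0 <= rlo <= rhi <= 1.0):
            raise ValueError(f"invalid response_prob_range {self.response_prob_range}")
        if self.wall_halflength_m <= 0:
            raise ValueError("wall_halflength_m must be > 0")
        for p in (self.occupancy_prob, self.overall_success_target, self.p_usable):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.season_start >= self.season_end:
            raise ValueError("season_start must precede season_end")

    def with_seed(self, seed: int) -> "ColonyConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# colony generation
# ---------------------------------------------------------------------------

def generate_colony(config: ColonyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the plots and nests of a colony.

    Returns ``(plots, nests)``.  ``plots`` has columns ``plot_id, centre_m``
    (global position of the plot centre along the collinear wall system);
    ``nests`` has ``nest_id, plot_id, position_m`` (signed metres from the
    plot centre), ``occupied``, ``response_prob`` and ``male_present``.
    Breeding columns are filled by :func:`simulate_breeding_outcomes`.
    """
    rng = np.random.default_rng(config.seed)
    plot_ids = [f"P{i + 1:02d}" for i in range(config.n_plots)]
    plots = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "centre_m": np.arange(config.n_plots) * config.plot_spacing_m,
        }
    )

    lo, hi = config.nests_per_plot_range
    rows = []
    for plot_id in plot_ids:
        n = int(rng.integers(lo, hi + 1))
        pos = rng.uniform(-config.wall_halflength_m, config.wall_halflength_m, n)
        occ = rng.random(n) < config.occupancy_prob
        if config.response_prob_per_nest:
            rp = rng.uniform(*config.response_prob_range, n)
        else:
            rp = np.full(n, rng.uniform(*config.response_prob_range))
        male = rng.random(n) < config.male_present_prob
        for j in range(n):
            rows.append(
                {
                    "nest_id": f"{plot_id}-N{j + 1:03d}",
                    "plot_id": plot_id,
                    "position_m": pos[j],
                    "occupied": bool(occ[j]),
                    "response_prob": float(rp[j]),
                    "male_present": bool(male[j] and occ[j]),
                }
            )
    columns = ["nest_id", "plot_id", "position_m", "occupied", "response_prob", "male_present"]
    nests = pd.DataFrame(rows, columns=columns)
    nests["lay_date"] = pd.NaT
    nests["hatch_date"] = pd.NaT
    nests["outcome"] = pd.array([None] * len(nests), dtype="string")
    nests["failure_day"] = np.nan
    return plots, nests


def simulate_breeding_outcomes(
    nests: pd.DataFrame,
    overall_success_target: float,
    seed: int,
    config: ColonyConfig | None = None,
) -> pd.DataFrame:
    """Assign breeding outcomes, hatch dates and failure timing to nests.

    Occupied nests succeed independently with probability
    ``overall_success_target``.  Failures split into incubation-stage
    failures (no hatch date) and chick-stage failures whose failure day
    post-hatch follows a truncated exponential calibrated so ~94% of
    chick-stage failures fall by day 24, matching published storm-petrel
    survival schedules.  Unoccupied nests get outcome ``"empty"``.
    """
    if not 0.0 <= overall_success_target <= 1.0:
        raise ValueError("overall_success_target must be in [0, 1]")
    cfg = config or ColonyConfig()
    rng = np.random.default_rng(seed)
    out = nests.copy()

    n = len(out)
    occ = out["occupied"].to_numpy(dtype=bool)
    u = rng.random(n)
    success = occ & (u < overall_success_target)
    failed = occ & ~success
    inc_fail = failed & (rng.random(n) < cfg.incubation_failure_frac)
    chick_fail = failed & ~inc_fail

    outcome = np.full(n, "empty", dtype=object)
    outcome[success] = "success"
    outcome[inc_fail] = "fail_incubation"
    outcome[chick_fail] = "fail_chick"
    out["outcome"] = pd.array(outcome, dtype="string")

    # hatch dates for nests that reached hatching
    hatched = success | chick_fail
    mean_ord = cfg.hatch_date_mean.toordinal()
    hatch_ord = np.round(rng.normal(mean_ord, cfg.hatch_date_sd, n)).astype(int)
    # keep hatch dates inside the season so chicks exist while recording
    hatch_ord = np.clip(
        hatch_ord,
        cfg.season_start.toordinal() + 7,
        cfg.season_end.toordinal() - 1,
    )
    hatch = pd.Series(pd.NaT, index=out.index, dtype="datetime64[ns]")
    hatch.loc[hatched] = pd.to_datetime(
        [dt.date.fromordinal(o).isoformat() for o in hatch_ord[hatched]]
    )
    out["hatch_date"] = hatch
    out["lay_date"] = out["hatch_date"] - pd.Timedelta(days=cfg.incubation_days)

    # chick-stage failure day: truncated exponential, ~94% of mass by day 24
    fail_day = np.full(n, np.nan)
    n_cf = int(chick_fail.sum())
    if n_cf:
        cap = 1.0 - math.exp(-cfg.max_chick_failure_day / cfg.chick_failure_scale_days)
        q = rng.random(n_cf) * cap
        fail_day[chick_fail] = np.floor(
            -cfg.chick_failure_scale_days * np.log1p(-q)
        )
    out["failure_day"] = fail_day
    return out


# ---------------------------------------------------------------------------
# chick ontogeny
# ---------------------------------------------------------------------------

# Anchor points of the relative begging-rate curve: calling can start on the
# day of hatching, rises through the first two weeks, dips slightly after the
# peak and then plateaus.  The optional late rise after day 30 (reported from
# very few individuals) is disabled by default.
_CURVE_ANCHORS = [(0.0, 0.08), (2.0, 0.18), (7.0, 0.60), (14.0, 1.00),
                  (20.0, 0.78), (25.0, 0.80), (30.0, 0.80), (45.0, 0.80)]
_CURVE_ANCHORS_LATE_RISE = _CURVE_ANCHORS[:-2] + [(30.0, 0.85), (38.0, 1.15), (45.0, 1.25)]


def chick_call_curve(age_days, late_rise: bool = False):
    """Relative chick begging rate vs age (peak at ~14 d normalised to 1).

    Piecewise-smooth monotone-segment interpolation (PCHIP) through fixed
    anchors; zero before hatching.
    """
    anchors = _CURVE_ANCHORS_LATE_RISE if late_rise else _CURVE_ANCHORS
    xs, ys = zip(*anchors)
    f = PchipInterpolator(xs, ys, extrapolate=False)
    a = np.asarray(age_days, dtype=float)
    out = f(np.clip(a, 0.0, xs[-1]))
    out = np.where(a < 0, 0.0, out)
    return out


def build_chick_profiles(
    nests: pd.DataFrame, config: ColonyConfig, seed: int
) -> pd.DataFrame:
    """Per-chick calling profiles for nests whose egg hatched.

    ``baseline_call_s_per_night`` is the chick's begging seconds per night at
    the age-curve peak; ``satiation_factor`` is a per-chick lognormal
    multiplier with mean 1 (per-night satiation jitter is applied on top of
    this at simulation time).
    """
    rng = np.random.default_rng(seed)
    hatched = nests[nests["hatch_date"].notna()].copy()
    n = len(hatched)
    sd = config.rates.nest_lognorm_sd
    base = config.rates.chick_peak_s * rng.lognormal(-0.5 * sd**2, sd, n)
    ssd = config.rates.satiation_lognorm_sd
    sat = rng.lognormal(-0.5 * ssd**2, ssd, n)
    return pd.DataFrame(
        {
            "nest_id": hatched["nest_id"].to_numpy(),
            "plot_id": hatched["plot_id"].to_numpy(),
            "hatch_date": hatched["hatch_date"].to_numpy(),
            "failure_day": hatched["failure_day"].to_numpy(),
            "baseline_call_s_per_night": base,
            "satiation_factor": sat,
        }
    )


# ---------------------------------------------------------------------------
# night conditions
# ---------------------------------------------------------------------------

def moon_fraction_on(date: dt.date, config: ColonyConfig) -> float:
    """Synthetic illuminated moon fraction from a cosine lunar cycle."""
    phase = 2.0 * math.pi * (date - config.full_moon_date).days / config.lunar_period_days
    return 0.5 * (1.0 + math.cos(phase))


def simulate_night_conditions(
    config: ColonyConfig, seed: int, plots: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Night table for the whole season.

    One row per plot-night with ``plot_id, date, moon_fraction, usable``.
    Moon fraction follows a deterministic synthetic lunar cycle (shared by
    all plots); usability (wind/noise) is an independent Bernoulli flag per
    plot-night.
    """
    rng = np.random.default_rng(seed)
    dates = [
        config.season_start + dt.timedelta(days=i)
        for i in range((config.season_end - config.season_start).days + 1)
    ]
    plot_ids = (
        list(plots["plot_id"])
        if plots is not None
        else [f"P{i + 1:02d}" for i in range(config.n_plots)]
    )
    rows = []
    for date in dates:
        moon = moon_fraction_on(date, config)
        usable = rng.random(len(plot_ids)) < config.p_usable
        for pid, u in zip(plot_ids, usable):
            rows.append(
                {"plot_id": pid, "date": date, "moon_fraction": moon, "usable": bool(u)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nightly calling
# ---------------------------------------------------------------------------

def _draw_events(rng, target_s, dur_lo, dur_hi):
    """Draw event voiced-durations totalling ~``target_s`` seconds.

    The number of events is Poisson with mean ``target_s / E[duration]`` so
    that expected summed seconds equal the target.
    """
    mean_dur = 0.5 * (dur_lo + dur_hi)
    n = rng.poisson(max(target_s, 0.0) / mean_dur)
    return rng.uniform(dur_lo, dur_hi, n)


def simulate_nightly_calling(
    nests: pd.DataFrame,
    night: NightConditions,
    chick_profiles: pd.DataFrame,
    seed: int,
    params: CallRateParams | None = None,
) -> pd.DataFrame:
    """True call events for one night across all nests.

    Returns a table of events with ``nest_id, plot_id, call_type, start_s,
    duration_s, position_m`` where ``start_s`` is seconds from 22:00 and
    ``duration_s`` is the voiced duration of the call.  Chick events are
    only produced for hatched chicks alive on the night, scaled by the
    age-dependent begging curve and satiation.  Bright moonlight suppresses
    calling smoothly (multiplier ``1 - s * moon**3``).
    """
    p = params or CallRateParams()
    rng = np.random.default_rng(seed)
    moon_factor = 1.0 - p.moon_suppression * night.moon_fraction**3
    night_factor = rng.lognormal(-0.5 * p.night_lognorm_sd**2, p.night_lognorm_sd)

    occupied = nests[nests["occupied"]].copy()
    plot_factors = {
        pid: rng.lognormal(-0.5 * p.plot_night_lognorm_sd**2, p.plot_night_lognorm_sd)
        for pid in sorted(occupied["plot_id"].unique())
    }
    rows = []

    def emit(nest_id, plot_id, position, call_type, target_s):
        lo, hi = _EVENT_DURATION_S[call_type]
        durs = _draw_events(rng, target_s, lo, hi)
        if len(durs) == 0:
            return
        starts = rng.uniform(0.0, NIGHT_WINDOW_S - hi, len(durs))
        for s, d in zip(starts, durs):
            rows.append(
                {
                    "nest_id": nest_id,
                    "plot_id": plot_id,
                    "call_type": call_type,
                    "start_s": float(s),
                    "duration_s": float(d),
                    "position_m": float(position),
                }
            )

    sd = p.nest_lognorm_sd
    for nest in occupied.itertuples(index=False):
        pf = plot_factors[nest.plot_id]
        scale = moon_factor * night_factor * pf
        nest_f = rng.lognormal(-0.5 * sd**2, sd)
        if nest.male_present:
            emit(
                nest.nest_id, nest.plot_id, nest.position_m, "adult_purr",
                p.purr_s_per_nest * nest_f * scale,
            )
        emit(
            nest.nest_id, nest.plot_id, nest.position_m, "adult_chat",
            p.chat_s_per_nest * nest_f * scale,
        )

    # chick begging
    if len(chick_profiles):
        night_ts = pd.Timestamp(night.date)
        pos_by_nest = occupied.set_index("nest_id")["position_m"]
        for chick in chick_profiles.itertuples(index=False):
            if chick.nest_id not in pos_by_nest.index:
                continue
            age = (night_ts - pd.Timestamp(chick.hatch_date)).days
            if age < 0:
                continue
            if not np.isnan(chick.failure_day) and age >= chick.failure_day:
                continue
            rel = float(chick_call_curve(age))
            if rel <= 0:
                continue
            ssd = p.satiation_lognorm_sd
            sat_night = rng.lognormal(-0.5 * ssd**2, ssd)
            target = (
                chick.baseline_call_s_per_night
                * rel
                * chick.satiation_factor
                * sat_night
                * moon_factor
                * night_factor
            )
            emit(
                chick.nest_id,
                chick.plot_id,
                float(pos_by_nest[chick.nest_id]),
                "chick_beg",
                target,
            )

    cols = ["nest_id", "plot_id", "call_type", "start_s", "duration_s", "position_m"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# playback survey and observer checks
# ---------------------------------------------------------------------------

def simulate_playback_survey(
    nests: pd.DataFrame, n_visits: int, seed: int
) -> pd.DataFrame:
    """Repeated daytime playback survey over all nests.

    Each occupied nest responds independently on each visit with its
    ``response_prob``; unoccupied nests never respond.  Returns the full
    long-format history (``plot_id, nest_id, visit, response``) including
    nests that never responded — downstream abundance estimation keeps only
    discovered (>= 1 response) nests, mirroring the field protocol where
    silent nests are simply never found.
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(nests)
    probs = np.where(
        nests["occupied"].to_numpy(dtype=bool),
        nests["response_prob"].to_numpy(dtype=float),
        0.0,
    )
    resp = rng.random((n, n_visits)) < probs[:, None]
    rows = []
    for i, nest in enumerate(nests.itertuples(index=False)):
        for v in range(n_visits):
            rows.append(
                {
                    "plot_id": nest.plot_id,
                    "nest_id": nest.nest_id,
                    "visit": v + 1,
                    "response": int(resp[i, v]),
                }
            )
    return pd.DataFrame(rows, columns=["plot_id", "nest_id", "visit", "response"])


def simulate_observer_check(
    nests: pd.DataFrame,
    check_date: dt.date,
    tarsus_growth: TarsusGrowth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Endoscope nest check on ``check_date`` with tarsus-based chick aging.

    A chick is present iff the egg hatched on or before the check date and
    the nest had not failed by then.  Tarsus length comes from the stand-in
    growth curve plus measurement noise, rounded to 0.1 mm; estimated age is
    the inverse growth curve of the rounded tarsus, rounded to whole days.
    """
    growth = tarsus_growth or TarsusGrowth()
    rng = np.random.default_rng(seed)
    check_ts = pd.Timestamp(check_date)
    rows = []
    for nest in nests.itertuples(index=False):
        age = np.nan
        present = False
        if pd.notna(nest.hatch_date):
            age = (check_ts - pd.Timestamp(nest.hatch_date)).days
            if age >= 0:
                if nest.outcome == "success":
                    present = True
                elif nest.outcome == "fail_chick":
                    present = bool(age < nest.failure_day)
        if present:
            tarsus = float(growth.age_to_tarsus(age))
            tarsus = round(tarsus + rng.normal(0.0, growth.measurement_sd_mm), 1)
            est_age = int(round(float(growth.tarsus_to_age(tarsus))))
        else:
            tarsus = np.nan
            est_age = np.nan
        rows.append(
            {
                "nest_id": nest.nest_id,
                "plot_id": nest.plot_id,
                "chick_present": present,
                "tarsus_mm": tarsus,
                "est_age_days": est_age,
                "true_age_days": age if present else np.nan,
            }
        )
    return pd.DataFrame(rows)
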