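"""Experiment orchestration, table formats and reproducibility manifest.

The end-to-end runner chains the stages on the event-level fast path:

    simulate colony -> nightly call events -> detection-range bookkeeping
    -> nightly call-rate records -> night filters + period split -> mean
    rates and accumulation plateaus -> playback survey -> corrected AON
    estimates -> comparative models

All randomness derives from one master seed (stage seeds spawned from it),
so two runs with the same configuration produce identical reports.  Every
table crosses stage boundaries as a validated CSV schema, and a run
manifest records the configuration snapshot, seeds, library versions and
SHA-256 digests of written files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .acoustic_events import DetectionRanges, apply_detection_range
from .call_metrics import (
    PERIOD_SPLIT_DATE,
    accumulation_plateau,
    build_call_rate_series,
    filter_nights,
    mean_call_rate,
    split_periods,
)
from .playback_abundance import (
    estimate_aon,
    history_from_table,
    percent_undetected,
    restrict_to_detection_range,
)
from .population_models import (
    acoustic_breeding_success,
    correlate,
    fit_abundance_index,
    fit_breeding_success,
    fit_chick_age_curve,
    fit_chick_count,
)
from .synthetic_colony import (
    ColonyConfig,
    NightConditions,
    build_chick_profiles,
    generate_colony,
    moon_fraction_on,
    simulate_breeding_outcomes,
    simulate_night_conditions,
    simulate_nightly_calling,
    simulate_observer_check,
    simulate_playback_survey,
)

__all__ = [
    "ExperimentConfig",
    "TableSchema",
    "NIGHT_RATE_SCHEMA",
    "DETECTION_HISTORY_SCHEMA",
    "NEST_SCHEMA",
    "PLOT_SUMMARY_SCHEMA",
    "read_table",
    "write_table",
    "run_experiment",
    "analyze_field_tables",
    "save_report",
]

log = logging.getLogger("burrowcall")

CALL_TYPES = ("adult_purr", "adult_chat", "chick_beg")


# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Declared CSV schema: column name -> kind.

    Kinds: ``str``, ``int``, ``float``, ``date`` (ISO-8601), ``bool01``.
    Validation errors name the offending row (1-based, excluding header)
    and column.
    """

    name: str
    columns: dict

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"{self.name}: missing columns {missing}")
        out = df.copy()
        for col, kind in self.columns.items():
            series = out[col]
            try:
                if kind == "int":
                    converted = pd.to_numeric(series, errors="coerce")
                    bad = converted.isna() | (converted != converted.round())
                    converted = converted.astype("float").round()
                elif kind == "float":
                    converted = pd.to_numeric(series, errors="coerce")
                    bad = converted.isna() & series.notna()
                elif kind == "date":
                    converted = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
                    bad = converted.isna()
                elif kind == "bool01":
                    converted = pd.to_numeric(series, errors="coerce")
                    bad = ~converted.isin([0, 1])
                else:  # str
                    converted = series.astype(str)
                    bad = series.isna()
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{self.name}: column {col!r}: {exc}") from exc
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValueError(
                    f"{self.name}: row {row}, column {col!r}: "
                    f"invalid {kind} value {series.iloc[row - 1]!r}"
                )
            if kind == "int":
                out[col] = converted.astype(int)
            elif kind == "bool01":
                out[col] = converted.astype(int)
            elif kind == "date":
                out[col] = converted.dt.date
            else:
                out[col] = converted
        return out


NEST_SCHEMA = TableSchema(
    "nests",
    {
        "nest_id": "str",
        "plot_id": "str",
        "position_m": "float",
        "occupied": "bool01",
        "response_prob": "float",
    },
)

NIGHT_RATE_SCHEMA = TableSchema(
    "nightly_rates",
    {
        "plot_id": "str",
        "date": "date",
        "call_type": "str",
        "seconds": "float",
        "moon_fraction": "float",
        "usable": "bool01",
    },
)

DETECTION_HISTORY_SCHEMA = TableSchema(
    "detection_history",
    {"plot_id": "str", "nest_id": "str", "visit": "int", "response": "bool01"},
)

PLOT_SUMMARY_SCHEMA = TableSchema(
    "plot_summary",
    {
        "plot_id": "str",
        "aons": "int",
        "mean_purr_s": "float",
        "mean_chat_s": "float",
        "mean_chick_s": "float",
        "n_chicks": "int",
        "successes": "int",
        "failures": "int",
        "response_rate": "float",
    },
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    return schema.validate(pd.read_csv(path))


def write_table(path, df: pd.DataFrame, schema: TableSchema | None = None) -> Path:
    path = Path(path)
    out = df.copy()
    if schema is not None:
        for col, kind in schema.columns.items():
            if kind == "bool01" and col in out:
                out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one synthetic monitoring experiment."""

    colony: ColonyConfig = field(default_factory=ColonyConfig)
    ranges: DetectionRanges = field(default_factory=DetectionRanges)
    n_visits: int = 7
    n_boot: int = 999
    check_date: dt.date = dt.date(2023, 8, 21)
    period_split: dt.date = PERIOD_SPLIT_DATE
    plateau_orderings: int = 100
    plateau_window: int = 5
    plateau_slope_threshold: float = 0.1
    n_nestboxes: int = 9
    seed: int = 0

    def to_dict(self) -> dict:
        return _to_jsonable(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        colony = d.pop("colony", {})
        if isinstance(colony, dict):
            for key in ("season_start", "season_end", "hatch_date_mean", "full_moon_date"):
                if key in colony and isinstance(colony[key], str):
                    colony[key] = dt.date.fromisoformat(colony[key])
            for key in ("rates", "tarsus"):
                if key in colony and isinstance(colony[key], dict):
                    sub = {
                        "rates": __import__(
                            "burrowcall.synthetic_colony", fromlist=["CallRateParams"]
                        ).CallRateParams,
                        "tarsus": __import__(
                            "burrowcall.synthetic_colony", fromlist=["TarsusGrowth"]
                        ).TarsusGrowth,
                    }[key]
                    colony[key] = sub(**colony[key])
            for key in ("nests_per_plot_range", "response_prob_range"):
                if key in colony:
                    colony[key] = tuple(colony[key])
            colony = ColonyConfig(**colony)
        ranges = d.pop("ranges", {})
        if isinstance(ranges, dict):
            ranges = DetectionRanges(**ranges)
        for key in ("check_date", "period_split"):
            if key in d and isinstance(d[key], str):
                d[key] = dt.date.fromisoformat(d[key])
        return cls(colony=colony, ranges=ranges, **d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def _spawn_seeds(master_seed: int, names) -> dict:
    """Named stage seeds derived from the master seed (each < 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def simulate_night_records(
    nests: pd.DataFrame,
    chick_profiles: pd.DataFrame,
    nights: pd.DataFrame,
    config: ExperimentConfig,
    seed: int,
) -> pd.DataFrame:
    """Per-plot-night detected call seconds on the event-level fast path.

    For each night, true call events are simulated, flagged by the
    detection-range rule, and detected voiced seconds are summed per plot
    and call type.  Returns the long nightly-rate table (zeros are genuine
    quiet nights; unusable nights are kept here and removed by the filter
    stage).
    """
    rng_seeds = np.random.SeedSequence(seed).spawn(nights["date"].nunique())
    plot_ids = sorted(nests["plot_id"].unique())
    night_info = nights.drop_duplicates(["plot_id", "date"]).set_index(["plot_id", "date"])
    rows = []
    for night_seed, (date, moon) in zip(
        rng_seeds,
        nights.drop_duplicates("date")[["date", "moon_fraction"]].itertuples(index=False),
    ):
        cond = NightConditions(date=date, moon_fraction=float(moon))
        events = simulate_nightly_calling(
            nests, cond, chick_profiles,
            seed=int(night_seed.generate_state(1, dtype=np.uint32)[0] % (2**31)),
            params=config.colony.rates,
        )
        if len(events):
            events = apply_detection_range(events, config.ranges)
            det = events[events["detected"]]
            sums = det.groupby(["plot_id", "call_type"])["duration_s"].sum()
        else:
            sums = pd.Series(dtype=float)
        for pid in plot_ids:
            usable = bool(night_info.loc[(pid, date), "usable"])
            for ct in CALL_TYPES:
                rows.append(
                    {
                        "plot_id": pid,
                        "date": date,
                        "call_type": ct,
                        "seconds": float(sums.get((pid, ct), 0.0)),
                        "moon_fraction": float(moon),
                        "usable": usable,
                    }
                )
    return pd.DataFrame(rows)


def _simulate_nestbox_study(
    chick_profiles: pd.DataFrame,
    config: ExperimentConfig,
    seed: int,
) -> pd.DataFrame:
    """Nightly begging seconds for chicks in recorder-equipped nest boxes.

    Nest-box recorders sit inside the chamber, so the chick's true nightly
    begging seconds are observed without distance attenuation, from hatch
    through the end of the season.
    """
    from .synthetic_colony import chick_call_curve

    rng = np.random.default_rng(seed)
    profiles = chick_profiles.sort_values("nest_id")
    take = min(config.n_nestboxes, len(profiles))
    idx = rng.choice(len(profiles), size=take, replace=False)
    chosen = profiles.iloc[np.sort(idx)]
    p = config.colony.rates
    rows = []
    for chick in chosen.itertuples(index=False):
        hatch = pd.Timestamp(chick.hatch_date).date()
        day = 0
        date = hatch
        while date <= config.colony.season_end:
            if not np.isnan(chick.failure_day) and day >= chick.failure_day:
                break
            rel = float(chick_call_curve(day))
            sat = rng.lognormal(-0.5 * p.satiation_lognorm_sd**2, p.satiation_lognorm_sd)
            night_f = rng.lognormal(-0.5 * p.night_lognorm_sd**2, p.night_lognorm_sd)
            moon = moon_fraction_on(date, config.colony)
            moon_f = 1.0 - p.moon_suppression * moon**3
            secs = chick.baseline_call_s_per_night * rel * chick.satiation_factor
            secs *= sat * night_f * moon_f
            rows.append(
                {
                    "nest_id": chick.nest_id,
                    "date": date,
                    "age_days": day,
                    "seconds": float(secs),
                    "night_index": (date - config.colony.season_start).days,
                }
            )
            day += 1
            date = date + dt.timedelta(days=1)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

def run_experiment(
    config: ExperimentConfig | None = None,
    out_dir=None,
) -> tuple[dict, dict]:
    """Run the full synthetic monitoring experiment.

    Returns ``(report, manifest)``.  The report holds per-plot AON estimates
    with bootstrap CIs, mean call rates and plateau statistics per call
    type, every comparative model fit, the chick-age smooth, and summary
    rates (mean percent undetected, overall breeding success).  When
    ``out_dir`` is given, stage tables, the report JSON and the manifest are
    written there and their digests recorded.
    """
    config = config or ExperimentConfig()
    t_start = time.time()
    seeds = _spawn_seeds(
        config.seed,
        [
            "colony", "outcomes", "profiles", "nights", "calling",
            "survey", "check", "plateau", "boot", "nestbox",
        ],
    )
    manifest: dict = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "stages": [],
        "files": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append({"name": name, "t_s": round(time.time() - t_start, 2)})

    # --- simulate -----------------------------------------------------
    stage("simulate")
    colony_cfg = config.colony.with_seed(seeds["colony"])
    plots, nests = generate_colony(colony_cfg)
    nests = simulate_breeding_outcomes(
        nests, colony_cfg.overall_success_target, seeds["outcomes"], colony_cfg
    )
    profiles = build_chick_profiles(nests, colony_cfg, seeds["profiles"])
    nights = simulate_night_conditions(colony_cfg, seeds["nights"], plots)

    # --- nightly call rates (event-level fast path) -------------------
    stage("calling")
    night_records = simulate_night_records(nests, profiles, nights, config, seeds["calling"])

    # --- metrics ------------------------------------------------------
    stage("metrics")
    retained = filter_nights(night_records)
    adult_recs, chick_recs = split_periods(retained, config.period_split)
    adult_series = {
        (s.plot_id, s.call_type): s
        for s in build_call_rate_series(adult_recs)
        if s.call_type in ("adult_purr", "adult_chat")
    }
    chick_series = {
        s.plot_id: s
        for s in build_call_rate_series(chick_recs)
        if s.call_type == "chick_beg"
    }
    plot_ids = list(plots["plot_id"])
    mean_rates = {
        pid: {
            "adult_purr": mean_call_rate(
                adult_series[(pid, "adult_purr")].nightly_seconds
            ) if (pid, "adult_purr") in adult_series else float("nan"),
            "adult_chat": mean_call_rate(
                adult_series[(pid, "adult_chat")].nightly_seconds
            ) if (pid, "adult_chat") in adult_series else float("nan"),
            "chick_beg": mean_call_rate(
                chick_series[pid].nightly_seconds
            ) if pid in chick_series else float("nan"),
        }
        for pid in plot_ids
    }

    plateau_rng = np.random.SeedSequence(seeds["plateau"]).spawn(
        len(adult_series) + len(chick_series)
    )
    plateaus = []
    for child, ((pid, ct), series) in zip(plateau_rng, sorted(adult_series.items())):
        plateaus.append(
            accumulation_plateau(
                series.nightly_seconds,
                slope_threshold=config.plateau_slope_threshold,
                n_orderings=config.plateau_orderings,
                window=config.plateau_window,
                seed=child,
                plot_id=pid,
                call_type=ct,
            )
        )
    for child, (pid, series) in zip(
        plateau_rng[len(adult_series):], sorted(chick_series.items())
    ):
        plateaus.append(
            accumulation_plateau(
                series.nightly_seconds,
                slope_threshold=config.plateau_slope_threshold,
                n_orderings=config.plateau_orderings,
                window=config.plateau_window,
                seed=child,
                plot_id=pid,
                call_type="chick_beg",
            )
        )

    # --- playback survey + AON estimation -----------------------------
    stage("abundance")
    nests_in_range = restrict_to_detection_range(
        nests, config.ranges, "adult_purr", plots
    )
    survey = simulate_playback_survey(nests_in_range, config.n_visits, seeds["survey"])
    boot_children = np.random.SeedSequence(seeds["boot"]).spawn(len(plot_ids))
    aon_estimates = {}
    for child, pid in zip(boot_children, plot_ids):
        sub = survey[survey["plot_id"] == pid]
        if sub["response"].sum() == 0:
            continue
        history = history_from_table(sub, pid)
        aon_estimates[pid] = estimate_aon(
            history,
            n_boot=config.n_boot,
            seed=int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)),
        )

    # --- observer breeding check --------------------------------------
    stage("observer")
    discovered = set(
        survey.groupby("nest_id")["response"].sum().pipe(lambda s: s[s > 0]).index
    )
    checked = nests_in_range[nests_in_range["nest_id"].isin(discovered)]
    check = simulate_observer_check(
        checked, config.check_date, colony_cfg.tarsus, seeds["check"]
    )
    per_plot_check = check.groupby("plot_id")["chick_present"].agg(["sum", "count"])

    # --- plot summary --------------------------------------------------
    summary_rows = []
    for pid in plot_ids:
        if pid not in aon_estimates:
            continue
        est = aon_estimates[pid]
        n_chicks = int(per_plot_check.loc[pid, "sum"]) if pid in per_plot_check.index else 0
        n_checked = int(per_plot_check.loc[pid, "count"]) if pid in per_plot_check.index else 0
        summary_rows.append(
            {
                "plot_id": pid,
                "aons": int(round(est.corrected_aons)),
                "observed_aons": est.observed_aons,
                "mean_purr_s": mean_rates[pid]["adult_purr"],
                "mean_chat_s": mean_rates[pid]["adult_chat"],
                "mean_chick_s": mean_rates[pid]["chick_beg"],
                "n_chicks": n_chicks,
                "successes": n_chicks,
                "failures": n_checked - n_chicks,
                "response_rate": est.response_rate,
                "pct_undetected": est.pct_undetected,
            }
        )
    summary = pd.DataFrame(summary_rows)

    # --- comparative models -------------------------------------------
    stage("models")
    fits = {}
    fits["abundance_purr"] = fit_abundance_index(
        summary["aons"], summary["mean_purr_s"], "adult_purr"
    )
    fits["abundance_chat"] = fit_abundance_index(
        summary["aons"], summary["mean_chat_s"], "adult_chat"
    )
    fits["chick_count"] = fit_chick_count(summary["n_chicks"], summary["mean_chick_s"])
    fits["breeding_success"] = fit_breeding_success(
        summary["successes"], summary["failures"], summary["mean_chick_s"]
    )
    for adult in ("purr", "chat"):
        ratio = acoustic_breeding_success(
            summary["mean_chick_s"], summary[f"mean_{adult}_s"]
        )
        ok = np.isfinite(ratio)
        fits[f"acoustic_success_{adult}"] = fit_breeding_success(
            summary["successes"][ok],
            summary["failures"][ok],
            ratio[ok],
            predictor_name=f"chick_over_{adult}_rate",
        )
    cor_adult = correlate(summary["mean_purr_s"], summary["mean_chat_s"])
    success_prop = summary["successes"] / (summary["successes"] + summary["failures"])
    cor_chicks_success = correlate(summary["n_chicks"], success_prop)

    # --- chick-age study (nest boxes) ----------------------------------
    stage("chick_age")
    nestbox = _simulate_nestbox_study(profiles, config, seeds["nestbox"])
    chick_age_fit = None
    if nestbox["nest_id"].nunique() >= 2 and len(nestbox) >= 20:
        chick_age_fit = fit_chick_age_curve(
            nestbox["seconds"],
            nestbox["age_days"],
            nestbox["nest_id"],
            nestbox["night_index"],
        )

    # --- report ---------------------------------------------------------
    plateau_by_type = {}
    for ct in CALL_TYPES:
        vals = [p.nights_to_plateau for p in plateaus if p.call_type == ct and p.reached]
        plateau_by_type[ct] = {
            "mean_nights": float(np.mean(vals)) if vals else None,
            "sd_nights": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            "n_plots_reached": len(vals),
            "n_plots": sum(1 for p in plateaus if p.call_type == ct),
        }

    report = {
        "plot_summary": summary.to_dict(orient="records"),
        "aon_estimates": {pid: _to_jsonable(est) for pid, est in aon_estimates.items()},
        "mean_call_rates": mean_rates,
        "plateaus": [_to_jsonable(p) for p in plateaus],
        "plateau_by_type": plateau_by_type,
        "model_fits": {k: _to_jsonable(v) for k, v in fits.items()},
        "correlations": {
            "purr_vs_chat": _to_jsonable(cor_adult),
            "chicks_vs_success": _to_jsonable(cor_chicks_success),
        },
        "mean_pct_undetected": float(np.mean([e.pct_undetected for e in aon_estimates.values()])),
        "overall_breeding_success": float(
            summary["successes"].sum() / (summary["successes"].sum() + summary["failures"].sum())
        ),
        "chick_age_fit": _to_jsonable(chick_age_fit) if chick_age_fit else None,
        "n_nights_recorded": int(nights["date"].nunique()),
        "seed": config.seed,
    }
    report = _to_jsonable(report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {
            "nests.csv": nests.assign(occupied=nests["occupied"].astype(int)),
            "nightly_rates.csv": night_records.assign(
                usable=night_records["usable"].astype(int)
            ),
            "detection_history.csv": survey,
            "plot_summary.csv": summary,
        }
        for name, df in files.items():
            path = out_dir / name
            df.to_csv(path, index=False)
            manifest["files"][name] = _sha256(path)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["files"]["report.json"] = _sha256(report_path)
        try:
            _write_figures(report, nestbox, chick_age_fit, out_dir)
            for name in ("fig_rate_vs_aons.png", "fig_chick_age_curve.png"):
                if (out_dir / name).exists():
                    manifest["files"][name] = _sha256(out_dir / name)
        except Exception as exc:  # plotting must never sink a run
            log.warning("figure generation failed: %s", exc)
        manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    else:
        manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()

    return report, manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_figures(report, nestbox, chick_age_fit, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = pd.DataFrame(report["plot_summary"])
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, (col, label, fit_key) in zip(
        axes,
        [
            ("mean_purr_s", "mean purr rate (s/night)", "abundance_purr"),
            ("mean_chat_s", "mean chat rate (s/night)", "abundance_chat"),
        ],
    ):
        ax.scatter(summary[col], summary["aons"], color="k")
        fit = report["model_fits"][fit_key]
        xs = np.linspace(summary[col].min(), summary[col].max(), 100)
        z = (xs - summary[col].mean()) / summary[col].std(ddof=1)
        coefs = fit["coefficients"]
        ax.plot(xs, np.exp(coefs[0] + coefs[1] * z), "k-")
        ax.set_xlabel(label)
    axes[0].set_ylabel("AONs (corrected)")
    fig.tight_layout()
    fig.savefig(out_dir / "fig_rate_vs_aons.png", dpi=120)
    plt.close(fig)

    if chick_age_fit is not None and len(nestbox):
        fig, ax = plt.subplots(figsize=(6, 4))
        for nid, grp in nestbox.groupby("nest_id"):
            ax.scatter(grp["age_days"], grp["seconds"], s=8, alpha=0.5)
        ages = np.linspace(0, nestbox["age_days"].max(), 120)
        ax.plot(ages, chick_age_fit.predict(ages), "k-", lw=2)
        ax.set_xlabel("chick age (days)")
        ax.set_ylabel("nightly begging (s)")
        fig.tight_layout()
        fig.savefig(out_dir / "fig_chick_age_curve.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# analysis of processed field tables
# ---------------------------------------------------------------------------

def analyze_field_tables(data_dir, n_visits: int = 7, plateau_seed: int = 1) -> dict:
    """Run the comparative analysis on processed field tables.

    Expects ``plot_summary.csv`` (per-plot AONs, mean call rates per type,
    chick counts, successes/failures, per-visit response rate) and
    optionally ``nightly_rates.csv`` for the accumulation plateaus, in the
    layout this package writes.  Returns the model coefficients, the
    chick-count/success correlation, mean percent undetected, overall
    breeding success and plateau means — the quantities the comparative
    analysis reports.
    """
    data_dir = Path(data_dir)
    summary = read_table(data_dir / "plot_summary.csv", PLOT_SUMMARY_SCHEMA)

    fits = {
        "abundance_purr": fit_abundance_index(
            summary["aons"], summary["mean_purr_s"], "adult_purr"
        ),
        "abundance_chat": fit_abundance_index(
            summary["aons"], summary["mean_chat_s"], "adult_chat"
        ),
        "chick_count": fit_chick_count(summary["n_chicks"], summary["mean_chick_s"]),
        "breeding_success": fit_breeding_success(
            summary["successes"], summary["failures"], summary["mean_chick_s"]
        ),
    }
    success_prop = summary["successes"] / (summary["successes"] + summary["failures"])
    out = {
        "model_fits": {k: _to_jsonable(v) for k, v in fits.items()},
        "cor_chicks_success": _to_jsonable(
            correlate(summary["n_chicks"], success_prop)
        ),
        "cor_purr_chat": _to_jsonable(
            correlate(summary["mean_purr_s"], summary["mean_chat_s"])
        ),
        "mean_pct_undetected": float(
            np.mean([percent_undetected(r, n_visits) for r in summary["response_rate"]])
        ),
        "overall_breeding_success": float(
            summary["successes"].sum()
            / (summary["successes"].sum() + summary["failures"].sum())
        ),
    }

    nightly_path = data_dir / "nightly_rates.csv"
    if nightly_path.exists():
        records = read_table(nightly_path, NIGHT_RATE_SCHEMA)
        retained = filter_nights(records)
        adult, chick = split_periods(retained)
        plateau_means = {}
        children = iter(np.random.SeedSequence(plateau_seed).spawn(64))
        for ct, recs in (
            ("adult_purr", adult),
            ("adult_chat", adult),
            ("chick_beg", chick),
        ):
            vals = []
            for series in build_call_rate_series(recs):
                if series.call_type != ct or series.n_nights < 7:
                    continue
                res = accumulation_plateau(series.nightly_seconds, seed=next(children))
                if res.reached:
                    vals.append(res.nights_to_plateau)
            plateau_means[ct] = float(np.mean(vals)) if vals else None
        out["plateau_means"] = plateau_means
    return out


def save_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True))
    return path
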