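import datetime as dt

import numpy as np
import pandas as pd
import pytest

from burrowcall.synthetic_colony import (
    ColonyConfig,
    NightConditions,
    build_chick_profiles,
    generate_colony,
    simulate_breeding_outcomes,
)


@pytest.fixture(scope="session")
def colony():
    """A default-sized colony with breeding outcomes and chick profiles."""
    cfg = ColonyConfig(seed=11)
    plots, nests = generate_colony(cfg)
    nests = simulate_breeding_outcomes(nests, cfg.overall_success_target, 12, cfg)
    profiles = build_chick_profiles(nests, cfg, 13)
    return cfg, plots, nests, profiles


@pytest.fixture
def august_night():
    return NightConditions(date=dt.date(2023, 8, 10), moon_fraction=0.2)


@pytest.fixture
def single_call_events():
    """Factory for one-event tables for rendering tests."""

    def make(call_type, position_m, duration_s, start_s=3.0):
        return pd.DataFrame(
            [
                {
                    "call_type": call_type,
                    "start_s": start_s,
                    "duration_s": duration_s,
                    "position_m": float(position_m),
                }
            ]
        )

    return make


@pytest.fixture(scope="session")
def labelled_scene():
    """A rendered clip of 60 labelled calls (20 per type) at close range."""
    from burrowcall.acoustic_events import DEFAULT_SPECS, render_plot_night

    rng = np.random.default_rng(7)
    rows, t = [], 2.0
    for k in range(60):
        ct = ["adult_purr", "adult_chat", "chick_beg"][k % 3]
        spec = DEFAULT_SPECS[ct]
        d = rng.uniform(spec.dur_lo, spec.dur_hi)
        rows.append(
            dict(call_type=ct, start_s=t, duration_s=d, position_m=rng.uniform(-8, 8))
        )
        t += d + rng.uniform(1.2, 2.5)
    events = pd.DataFrame(rows)
    clip = render_plot_night(events, seed=99, duration_s=t + 2)
    return events, clip
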