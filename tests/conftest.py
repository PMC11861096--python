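import datetime as dt

import pandas as pd
import pytest

import thermalgxe as tg

START = dt.date(2019, 5, 1)


def weather_from_pairs(pairs, start=START) -> pd.DataFrame:
    """Consecutive-day weather frame from (tmin, tmax) pairs."""
    return pd.DataFrame(
        {
            "date": [start + dt.timedelta(days=i) for i in range(len(pairs))],
            "tmin": [p[0] for p in pairs],
            "tmax": [p[1] for p in pairs],
        }
    )


def window(n_days: int, start=START) -> tg.StageWindow:
    return tg.StageWindow(start, start + dt.timedelta(days=int(n_days) - 1))


@pytest.fixture(scope="session")
def default_trial():
    """One default-scenario simulated trial shared across the suite."""
    panel = tg.default_panel(seed=11)
    plots, weather = tg.simulate_trial(panel, seed=11)
    profiles = tg.profiles_table(plots, weather)
    return {"panel": panel, "plots": plots, "weather": weather, "profiles": profiles}
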