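import datetime as dt

import numpy as np
import pandas as pd
import pytest

from emasim import ParticipantStream, load_preset, saturating_day

DATE = dt.date(2023, 3, 6)


@pytest.fixture(scope="session")
def ie_fr():
    return load_preset("ie_fr_relaxed")


@pytest.fixture(scope="session")
def cz_de():
    return load_preset("cz_de_original")


@pytest.fixture(scope="session")
def optimal():
    return load_preset("optimal")


def make_epochs(steps, hr=None, start="2023-03-06 00:00"):
    """Build an epoch frame from plain lists (one value per minute)."""
    n = len(steps)
    hr = hr if hr is not None else [1] * n
    return pd.DataFrame(
        {
            "minute_start": pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="m"),
            "steps": np.asarray(steps, dtype=np.int64),
            "hr_samples": np.asarray(hr, dtype=np.int64),
        }
    )


def make_stream(pid, steps, hr=None, site="CZ", start="2023-03-06 00:00"):
    return ParticipantStream(pid, site, make_epochs(steps, hr, start))


@pytest.fixture()
def sedentary_week():
    """One participant, seven saturating sedentary days."""
    frames = [
        saturating_day("sedentary", DATE + dt.timedelta(days=d)) for d in range(7)
    ]
    return ParticipantStream("P001", "IE", pd.concat(frames, ignore_index=True))


def random_stream(rng, n_minutes=90, gap_prob=0.05):
    """A jagged random stream exercising gaps, non-wear and all step regimes."""
    minutes = []
    m = 0
    while len(minutes) < n_minutes:
        if rng.random() > gap_prob:
            minutes.append(m)
        m += 1
    regimes = rng.choice([0, 1, 30, 60, 100, 139, 140, 180], size=len(minutes))
    hr = (rng.random(len(minutes)) > 0.1).astype(np.int64)
    return pd.DataFrame(
        {
            "minute_start": pd.Timestamp("2023-03-06")
            + pd.to_timedelta(np.asarray(minutes), unit="m"),
            "steps": regimes.astype(np.int64),
            "hr_samples": hr,
        }
    )
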