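import datetime as dt

import numpy as np
import pytest

import typerhythm as tr

D1 = dt.date(2024, 3, 4)


def make_record(hour, minute=0, delays=(100.0, 200.0), keys=3, upright=True,
                moving=False, day=D1, offset=0, sid=None):
    return tr.SessionRecord(
        start_time=dt.datetime.combine(
            day, dt.time(hour, minute), tzinfo=dt.timezone.utc
        ),
        utc_offset_min=offset,
        inter_key_delays=tuple(delays),
        n_keypresses=keys,
        upright=upright,
        moving=moving,
        session_id=sid,
    )


@pytest.fixture(scope="session")
def simulated_user_60d():
    """Default 60-day scenario with 8 h mean sleep (shared; read-only)."""
    return tr.simulate_user(tr.UserScenario(n_days=60, seed=2))


@pytest.fixture(scope="session")
def fitted_60d(simulated_user_60d):
    """Standardised tensor + default-pipeline artefacts for the 60-day user."""
    sim = simulated_user_60d
    art = tr.run_pipeline(
        tr.RunConfig(seed=2), records=sim.records, offsets=sim.offsets,
        write=False,
    )
    return sim, art


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
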