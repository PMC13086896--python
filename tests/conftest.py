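import numpy as np
import pytest

import qivikit as qk
from qivikit.pbk import build_model, simulate
from qivikit.records import DoseEvent, DosingSchedule

#: loose-but-adequate solver settings for test-suite runtimes
FAST = dict(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def rat_phys():
    return qk.default_physiology("rat")


@pytest.fixture(scope="session")
def human_phys():
    return qk.default_physiology("human")


@pytest.fixture(scope="session")
def teb():
    return qk.TEBUCONAZOLE


@pytest.fixture(scope="session")
def cyr():
    return qk.CYROMAZINE


def gavage(amount_mg, duration=36.0):
    return DosingSchedule(
        events=[DoseEvent(time=0.0, amount=amount_mg)], duration=duration
    )


@pytest.fixture(scope="session")
def teb_rat_sim(rat_phys, teb):
    """Single 2 mg/kg tebuconazole gavage in the rat, shared across tests."""
    model = build_model(teb, rat_phys)
    dose = 2.0 * rat_phys.body_weight
    ts = simulate(model, gavage(dose, 48.0), 48.0, rtol=1e-8, atol=1e-11)
    return model, ts


@pytest.fixture(scope="session")
def cyr_rat_sim(rat_phys, cyr):
    """Single 3 mg/kg cyromazine gavage in the rat."""
    model = build_model(cyr, rat_phys)
    dose = 3.0 * rat_phys.body_weight
    ts = simulate(model, gavage(dose, 36.0), 36.0, rtol=1e-8, atol=1e-11)
    return model, ts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
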