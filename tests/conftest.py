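import dataclasses

import numpy as np
import pytest

from adedbs import drinkometer as dk
from adedbs import simulate as sim


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small two-group cohort with programmed multipliers and zero sensor noise."""
    sham, dbs = sim.study_defaults()
    sham = dataclasses.replace(sham, noise_sd=0.0)
    dbs = dataclasses.replace(dbs, noise_sd=0.0)
    return sim.generate_cohort(sham, dbs, n_per_group=3, seed=11)


@pytest.fixture
def flat_series():
    """Constant dose-unit series (one day)."""
    t = np.arange(dk.BINS_PER_DAY) * dk.BIN_MINUTES
    return dk.DrinkometerSeries(
        animal_id="a", bottle="etoh10", t=t, y=np.full(t.size, 0.3),
        body_weight=400.0, units="g/kg",
    )


def bout_series(bouts_per_day=6, amount=0.5, n_days=1, spacing=None, bottle="etoh10"):
    """Deterministic dose-unit series with evenly spaced single-bin bouts."""
    n = n_days * dk.BINS_PER_DAY
    t = np.arange(n) * dk.BIN_MINUTES
    y = np.zeros(n)
    if bouts_per_day:
        step = dk.BINS_PER_DAY // bouts_per_day if spacing is None else spacing
        for d in range(n_days):
            for k in range(bouts_per_day):
                y[d * dk.BINS_PER_DAY + k * step] = amount
    return dk.DrinkometerSeries(
        animal_id="a", bottle=bottle, t=t, y=y, body_weight=400.0, units="g/kg"
    )
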