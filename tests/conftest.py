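import numpy as np
import pandas as pd
import pytest

from evquant.events import EventMeta, EventTable
from evquant.simulate import (
    EV_POPULATION,
    NOISE_POPULATION,
    AntibodyModel,
    SampleConfig,
    gen_sample_events,
)


def make_table(n=10, seed=0, trigger_fsc=0.0, trigger_ssc=0.0, **meta_kwargs):
    """Small random event table with all invariants satisfied."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {c: rng.uniform(1.0, 1e4, size=n)
         for c in ("fsc_h", "ssc_h", "fl1", "fl2", "fl3", "fl4")}
    )
    meta = EventMeta(
        trigger_fsc_h=trigger_fsc, trigger_ssc_h=trigger_ssc, **meta_kwargs
    )
    return EventTable(df, meta)


@pytest.fixture
def noise_control():
    return gen_sample_events(
        SampleConfig(populations=(NOISE_POPULATION,), seed=101, sample_id="control")
    )


@pytest.fixture
def ev_sample_half_display():
    ab = AntibodyModel(amount_ug=1000.0, display_prob=0.5)  # saturating
    return gen_sample_events(
        SampleConfig(populations=(EV_POPULATION,), antibody=ab, seed=202)
    )
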