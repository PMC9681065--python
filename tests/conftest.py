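import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from declinemeta.corpus import CORPUS_COLUMNS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


RECORD_DEFAULTS = {
    "record_id": "r1",
    "study_id": "s1",
    "year_online": 2012,
    "year_print": 2012,
    "species": "Amphiprion percula",
    "life_stage": "larva",
    "cue_type": "predator",
    "behaviour_metric": "time_in_cue",
    "scale_type": "percentage",
    "control_mean": 40.0,
    "treatment_mean": 60.0,
    "control_sd": 8.0,
    "treatment_sd": 12.0,
    "control_n": 10,
    "treatment_n": 10,
    "co2_uatm": 1000.0,
    "is_sham": False,
    "is_fluctuating_co2": False,
    "is_procedural_control": False,
    "direction_opposite": False,
}


def make_record(**overrides) -> dict:
    rec = dict(RECORD_DEFAULTS)
    rec.update(overrides)
    return rec


def make_corpus(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(CORPUS_COLUMNS))


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_corpus():
    rows = []
    rng = np.random.default_rng(42)
    for i in range(12):
        year = 2009 + i % 4
        rows.append(
            make_record(
                record_id=f"r{i}",
                study_id=f"s{i // 3}",
                year_online=year,
                year_print=year,
                control_mean=float(rng.uniform(20, 60)),
                treatment_mean=float(rng.uniform(20, 80)),
                control_sd=float(rng.uniform(2, 10)),
                treatment_sd=float(rng.uniform(2, 10)),
                co2_uatm=float(rng.uniform(600, 1200)),
            )
        )
    return make_corpus(rows)
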