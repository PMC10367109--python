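import numpy as np
import pandas as pd
import pytest

from esoikit import CohortConfig, Contamination, PressureMixture, generate_cohort
from esoikit.sas import SinhArcsinhParams
from esoikit.scoring import ITEM_COLUMNS, score_table


def make_record(items, **overrides):
    """One raw-record dict with sane defaults and the given 18 item values."""
    rec = {
        "record_id": "r0",
        "user_key": "u0",
        "timestamp": "2020-01-01 10:00:00",
        "label": "unsure",
        "distress": 1,
        "uncertainty": 1,
        "changed_so": False,
        "fluency": 10,
        "age": 25,
        "gender": "female",
        "race": "white",
        "education": "bachelors",
        "country": "US",
    }
    rec.update(dict(zip(ITEM_COLUMNS, items)))
    rec.update(overrides)
    return rec


@pytest.fixture
def toy_records():
    """Five hand-built records exercising each cleaning rule once."""
    nan = float("nan")
    rows = [
        # 8 answered items -> removed as incomplete
        make_record([1] * 8 + [nan] * 10, record_id="r_inc", user_key="u1"),
        # fluency 5 -> removed
        make_record([2] * 18, record_id="r_flu", user_key="u2", fluency=5),
        # same user, same day, earlier timestamp -> kept
        make_record([1] * 18, record_id="r_dup_first", user_key="u3",
                    timestamp="2020-03-05 09:00:00"),
        # same user, same day, later -> removed as duplicate
        make_record([1] * 18, record_id="r_dup_second", user_key="u3",
                    timestamp="2020-03-05 17:30:00"),
        # clean
        make_record([0] * 18, record_id="r_clean", user_key="u4"),
    ]
    return pd.DataFrame(rows)


def symmetric_config(n, seed, **overrides):
    """Cohort config with a symmetric latent law centred at 9, no contamination."""
    comp = SinhArcsinhParams(mu=9.0, sigma=3.0)
    defaults = dict(
        n=n,
        seed=seed,
        base_model=PressureMixture(comp_nonss=comp, comp_ss=comp),
        contamination=Contamination(0.0, 0.0, 0.0),
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def symmetric_cohort_scored():
    """Scored symmetric cohort, n = 1e5 (shared across distribution tests)."""
    table, _ = generate_cohort(symmetric_config(100_000, seed=20240901))
    return score_table(table)
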