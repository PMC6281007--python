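import numpy as np
import pandas as pd
import pytest

import acekit as ak
from acekit.derivation import ItemTable
from acekit.synthetic import scenario_suite


@pytest.fixture(scope="session")
def small_scenarios():
    """Scenario suite at a size small enough for per-module tests."""
    return scenario_suite(n_participants=800, seed=11)


@pytest.fixture(scope="session")
def complete_cohort(small_scenarios):
    return ak.generate_cohort(small_scenarios["complete"])


@pytest.fixture(scope="session")
def mar_cohort(small_scenarios):
    return ak.generate_cohort(small_scenarios["mar-ses"])


@pytest.fixture(scope="session")
def mar_constructs(mar_cohort):
    items = ak.split_dual_period(
        ak.eligibility_filter(ak.apply_dictionary(mar_cohort.responses, mar_cohort.dictionary))
    )
    return ak.derive_all(items, window=(0, 16))


def random_item_table(rng, n_participants, n_aces=3, max_items=6, missing=0.3):
    """A random post-split item table with metadata, for oracle comparisons."""
    aces = list(ak.ACE_CATEGORIES[:n_aces])
    cols, meta_rows = {}, {}
    for ace in aces:
        for i in range(int(rng.integers(1, max_items + 1))):
            item_id = f"{ace}_r{i}"
            vals = rng.integers(0, 2, n_participants).astype(float)
            vals[rng.random(n_participants) < missing] = np.nan
            cols[item_id] = vals
            ws = int(rng.integers(0, 17))
            meta_rows[item_id] = {
                "ace_category": ace,
                "window_start": ws,
                "window_end": int(rng.integers(ws, 17)),
                "report_age": 10,
                "reporter": "mother",
                "timing": "prospective",
                "dual_period": False,
                "second_window_start": None,
                "second_window_end": None,
            }
    data = pd.DataFrame(cols, index=pd.RangeIndex(1, n_participants + 1))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return ItemTable(data=data, meta=meta), aces


def brute_force_constructs(items, aces, window=(0, 16)):
    """Independent per-participant, per-ACE loop oracle for derive_all:
    coverage answered*2 >= in-window item count, any-positive coding."""
    out = {}
    for ace in aces:
        ids = [
            c
            for c in items.data.columns
            if items.meta.at[c, "ace_category"] == ace
            and window[0] <= items.meta.at[c, "window_start"]
            and items.meta.at[c, "window_end"] <= window[1]
        ]
        col = []
        for pid in items.data.index:
            vals = [items.data.at[pid, c] for c in ids]
            answered = [v for v in vals if not np.isnan(v)]
            if not ids or len(answered) * 2 < len(ids):
                col.append(np.nan)
            else:
                col.append(1.0 if any(v == 1.0 for v in answered) else 0.0)
        out[ace] = col
    return pd.DataFrame(out, index=items.data.index)
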