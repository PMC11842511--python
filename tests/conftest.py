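import numpy as np
import pandas as pd
import pytest

from elembench import ElementPanel
from elembench.qc import METADATA_COLUMNS, TREND_LEVELS, flag_col


def make_table(conc: dict, *, trend=None, population=None, growth_year=None,
               collection=None, age_class=None, sex=None,
               flags: dict | None = None) -> pd.DataFrame:
    """Assemble a sample table from per-element concentration lists."""
    n = len(next(iter(conc.values())))
    df = pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "population": population if population is not None else ["p1"] * n,
        "growth_year": growth_year if growth_year is not None else [2017] * n,
        "trend": trend if trend is not None else ["stable"] * n,
        "collection": collection if collection is not None else ["capture"] * n,
        "age_class": age_class if age_class is not None else ["adult"] * n,
        "sex": sex if sex is not None else ["female"] * n,
    })
    df["growth_year"] = df["growth_year"].astype("Int64")
    df["trend"] = pd.Categorical(df["trend"], categories=TREND_LEVELS, ordered=True)
    for el, vals in conc.items():
        df[el] = np.asarray(vals, float)
        df[flag_col(el)] = (np.asarray(flags[el], bool) if flags and el in flags
                            else np.zeros(n, bool))
    return df


@pytest.fixture
def two_element_panel():
    return ElementPanel(names=("Cu", "Co"), loq={"Cu": 0.05, "Co": 0.2})
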