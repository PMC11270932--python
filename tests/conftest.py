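import numpy as np
import pandas as pd
import pytest

from agingccd.indicators import IndicatorPanel, IndicatorSpec
from agingccd.national import builtin_national_panel


@pytest.fixture(scope="session")
def national_panel():
    return builtin_national_panel()


def make_panel(values_by_indicator, polarities=None, subsystems=None,
               regions=("r0",), start_year=2000):
    """Small panel builder: values_by_indicator maps id → per-year list
    (shared by every region)."""
    ids = list(values_by_indicator)
    polarities = polarities or {i: "positive" for i in ids}
    subsystems = subsystems or {i: "elderly_population" for i in ids}
    spec = [
        IndicatorSpec(i, i, subsystems[i], polarities[i]) for i in ids
    ]
    n = len(next(iter(values_by_indicator.values())))
    years = list(range(start_year, start_year + n))
    idx = pd.MultiIndex.from_product([list(regions), years],
                                     names=["region", "year"])
    df = pd.DataFrame(
        {i: np.tile(np.asarray(v, float), len(regions))
         for i, v in values_by_indicator.items()},
        index=idx,
    )
    return IndicatorPanel(df, spec)


@pytest.fixture
def tiny_panel():
    """4 years × 3 indicators, one region, mixed polarity."""
    return make_panel(
        {"a": [1.0, 2.0, 3.0, 5.0],
         "b": [10.0, 7.0, 6.0, 2.0],
         "c": [0.5, 0.9, 0.8, 1.1]},
        polarities={"a": "positive", "b": "negative", "c": "positive"},
        subsystems={"a": "elderly_population", "b": "demand", "c": "supply"},
    )
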