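"""Packaged national indicator panel for China, 2012–2022.

Twenty indicators — seven for the elderly-population subsystem, seven for
healthcare-resource demand and six for supply — transcribed from published
national statistics (statistical yearbooks and health-development bulletins).
Values are stored exactly as printed in the source tables; units are metadata
only and are never converted.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .indicators import IndicatorPanel, IndicatorSpec, load_indicator_spec

__all__ = ["national_indicator_spec", "builtin_national_panel"]


def _data_path(name: str):
    return resources.files("agingccd.data").joinpath(name)


def national_indicator_spec() -> list[IndicatorSpec]:
    """The 20-indicator national specification set (with published weights
    retained as ``reference_weight`` metadata)."""
    with resources.as_file(_data_path("national_indicators.yaml")) as p:
        return load_indicator_spec(p)


def builtin_national_panel() -> IndicatorPanel:
    """Single-region ("china") panel, years 2012–2022, all 20 indicators."""
    spec = national_indicator_spec()
    with resources.as_file(_data_path("national_panel_wide.csv")) as p:
        df = pd.read_csv(p)
    return IndicatorPanel.from_wide(df, spec)
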