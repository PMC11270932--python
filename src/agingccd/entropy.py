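"""Entropy-weight method: polarity-aware normalization, information entropy,
objective indicator weights and subsystem composite scores.

The chain is the classic objective-weighting scheme for composite indices:

1.  Min–max normalize each indicator over a sample set, respecting polarity:
    positive indicators map ``min → 0, max → 1``; negative indicators map
    ``max → 0, min → 1``.
2.  Convert the normalized column to proportions ``Y = x' / Σ x'`` over the
    samples.
3.  Information entropy ``e = −k Σ Y ln Y`` with ``k = 1/ln m`` (``m`` the
    number of samples) and the convention ``0·ln 0 := 0`` (implemented by
    masking, never by adding an epsilon).
4.  Redundancy ``d = 1 − e``; weights ``w = d / Σ d`` renormalized *within
    each subsystem*, so that each subsystem's weights sum to one.
5.  Subsystem composite score ``U = Σ w_j x'_j`` per region-year.

The *sample axis* selects what counts as a sample: for a single-region time
series it is the years; for multi-region panels the default is per-year
cross-sections over regions with weights averaged across years; pooled
region-years is also supported.

A constant indicator (max = min over its sample group) carries no
information: its normalized values are set to 0, it is excluded from the
entropy computation and it receives weight 0, with a warning recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .indicators import IndicatorPanel, IndicatorSpec, SUBSYSTEMS

SampleAxis = Literal["years", "regions", "region_years"]
ScoreBase = Literal["normalized", "proportion"]

#: subsystem → conventional score name
SCORE_NAMES = {"elderly_population": "U1", "demand": "U2", "supply": "U3"}


# ---------------------------------------------------------------------------
# grouping helpers

def _group_keys(index: pd.MultiIndex, sample_axis: SampleAxis) -> pd.Series:
    """Series mapping each (region, year) row to its sample-group key."""
    if sample_axis == "years":
        return pd.Series(index.get_level_values("region"), index=index)
    if sample_axis == "regions":
        return pd.Series(index.get_level_values("year"), index=index)
    if sample_axis == "region_years":
        return pd.Series(["__all__"] * len(index), index=index)
    raise ValueError(f"unknown sample_axis {sample_axis!r}")


# ---------------------------------------------------------------------------
# containers

@dataclass
class NormalizedPanel:
    """Min–max normalized values in [0, 1] on the panel's own axes.

    ``minmax`` records, per sample group and indicator, the (min, max) of the
    raw values actually used — which may come from a wider window panel than
    the one being normalized.  ``constant`` lists (group, indicator) pairs
    whose raw column was constant over the window.
    """

    values: pd.DataFrame
    sample_axis: SampleAxis
    spec: list[IndicatorSpec]
    minmax: pd.DataFrame
    constant: list[tuple[object, str]] = field(default_factory=list)

    @property
    def groups(self) -> pd.Series:
        return _group_keys(self.values.index, self.sample_axis)


@dataclass
class ProportionMatrix:
    """Per-indicator shares ``Y`` summing to one over each sample group."""

    values: pd.DataFrame
    sample_axis: SampleAxis
    spec: list[IndicatorSpec]
    constant: list[tuple[object, str]] = field(default_factory=list)


@dataclass
class EntropyTable:
    """Per (group, indicator) entropy ``e``, redundancy ``d = 1 − e``,
    sample count ``m`` and normalizer ``k = 1/ln m``."""

    table: pd.DataFrame  # columns: group, indicator_id, m, k, e, d, constant
    sample_axis: SampleAxis
    spec: list[IndicatorSpec]


@dataclass
class WeightTable:
    """Entropy weights per indicator, normalized within each subsystem.

    ``weights`` is indexed by indicator_id with columns ``subsystem`` and
    ``weight``; ``per_group`` retains the group-level weights that were
    averaged (relevant for multi-region panels with per-year entropy).
    """

    weights: pd.DataFrame
    per_group: pd.DataFrame

    def weight(self, indicator_id: str) -> float:
        return float(self.weights.loc[indicator_id, "weight"])

    def subsystem_sums(self) -> pd.Series:
        return self.weights.groupby("subsystem")["weight"].sum()


# ---------------------------------------------------------------------------
# window padding

def pad_panel_years(
    panel: IndicatorPanel, first_year: int, last_year: int
) -> IndicatorPanel:
    """Extend a panel's year span by linear extrapolation at the boundaries.

    Each indicator series is extended per region using the slope of its two
    outermost observed years, clipped at zero (yearbook-style quantities are
    nonnegative).  The result is intended as a *min–max window* companion to
    :func:`normalize` — the synthetic boundary years widen the normalization
    range so that genuine boundary observations do not collapse to exactly
    0 or 1, mirroring a study design whose normalization window extends one
    year beyond the reporting window on each side.
    """
    years = panel.years
    if first_year > years[0] or last_year < years[-1]:
        raise ValueError("padding window must contain the panel's year span")
    rows = []
    for region in panel.regions:
        block = panel.values.xs(region, level="region").sort_index()
        lo_slope = block.loc[years[1]] - block.loc[years[0]]
        hi_slope = block.loc[years[-1]] - block.loc[years[-2]]
        for y in range(first_year, years[0]):
            rows.append(
                (region, y, (block.loc[years[0]] - lo_slope * (years[0] - y)).clip(lower=0.0))
            )
        for y in years:
            rows.append((region, y, block.loc[y]))
        for y in range(years[-1] + 1, last_year + 1):
            rows.append(
                (region, y, (block.loc[years[-1]] + hi_slope * (y - years[-1])).clip(lower=0.0))
            )
    idx = pd.MultiIndex.from_tuples(
        [(r, y) for r, y, _ in rows], names=["region", "year"]
    )
    df = pd.DataFrame([v for _, _, v in rows], index=idx)
    return IndicatorPanel(df, panel.spec)


# ---------------------------------------------------------------------------
# the chain

def normalize(
    panel: IndicatorPanel,
    sample_axis: SampleAxis = "years",
    minmax_panel: IndicatorPanel | None = None,
) -> NormalizedPanel:
    """Polarity-aware min–max normalization of a raw panel.

    ``minmax_panel`` optionally supplies the sample set over which min and
    max are taken (e.g. a year-padded panel from :func:`pad_panel_years`);
    the returned values cover only ``panel``'s own cells and are clipped to
    [0, 1].  A constant indicator within a sample group is set to 0 and
    recorded in ``constant`` (it will receive weight 0 downstream).
    """
    src = minmax_panel if minmax_panel is not None else panel
    if src.indicators != panel.indicators:
        raise ValueError("minmax_panel must carry the same indicators")

    src_groups = _group_keys(src.values.index, sample_axis)
    stats = src.values.groupby(src_groups.to_numpy()).agg(["min", "max"])
    # stats: index = group key, columns = (indicator, min/max)

    groups = _group_keys(panel.values.index, sample_axis)
    gmin = stats.xs("min", axis=1, level=1).reindex(groups.to_numpy())
    gmax = stats.xs("max", axis=1, level=1).reindex(groups.to_numpy())
    gmin.index = panel.values.index
    gmax.index = panel.values.index

    span = gmax - gmin
    constant_mask = span == 0

    out = pd.DataFrame(
        np.nan, index=panel.values.index, columns=panel.values.columns
    )
    for s in panel.spec:
        col = panel.values[s.indicator_id]
        if s.polarity == "positive":
            x = (col - gmin[s.indicator_id]) / span[s.indicator_id]
        else:
            x = (gmax[s.indicator_id] - col) / span[s.indicator_id]
        out[s.indicator_id] = x.clip(0.0, 1.0)

    constant: list[tuple[object, str]] = []
    if constant_mask.to_numpy().any():
        for ind in panel.indicators:
            bad_groups = set(groups[constant_mask[ind]].unique()) if constant_mask[
                ind
            ].any() else set()
            for g in sorted(bad_groups, key=str):
                constant.append((g, ind))
                warnings.warn(
                    f"indicator {ind!r} constant over sample group {g!r}; "
                    "normalized to 0 and assigned weight 0",
                    stacklevel=2,
                )
        out = out.where(~constant_mask, 0.0)

    minmax = pd.concat(
        {"min": stats.xs("min", axis=1, level=1), "max": stats.xs("max", axis=1, level=1)},
        axis=1,
    )
    return NormalizedPanel(
        values=out,
        sample_axis=sample_axis,
        spec=panel.spec,
        minmax=minmax,
        constant=constant,
    )


def proportions(norm: NormalizedPanel) -> ProportionMatrix:
    """Shares ``Y = x' / Σ x'`` over each sample group (columns of constant
    indicators stay identically zero)."""
    groups = norm.groups
    sums = norm.values.groupby(groups.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = norm.values / sums
    Y = Y.where(sums > 0, 0.0)
    return ProportionMatrix(
        values=Y, sample_axis=norm.sample_axis, spec=norm.spec, constant=norm.constant
    )


def entropy(prop: ProportionMatrix) -> EntropyTable:
    """Information entropy and redundancy per (sample group, indicator).

    ``e = −(1/ln m) Σ Y ln Y`` with ``0·ln 0 := 0`` by masking.  Requires at
    least two samples per group (``k`` is undefined at m = 1).  Constant
    indicators are flagged and given ``d = 0`` so they drop out of the
    weights.
    """
    groups = _group_keys(prop.values.index, prop.sample_axis)
    records = []
    constant = set(prop.constant)
    for g, block in prop.values.groupby(groups.to_numpy()):
        m = len(block)
        if m < 2:
            raise ValueError(
                f"sample group {g!r} has m = {m} < 2 samples; entropy undefined"
            )
        k = 1.0 / math.log(m)
        for ind in block.columns:
            y = block[ind].to_numpy()
            is_const = (g, ind) in constant
            if is_const:
                e = 1.0  # convention: no information ⇒ zero redundancy
            else:
                nz = y[y > 0]
                e = float(-k * np.sum(nz * np.log(nz)))
                e = min(max(e, 0.0), 1.0)  # clamp fp noise at the ends
            records.append(
                {
                    "group": g,
                    "indicator_id": ind,
                    "m": m,
                    "k": k,
                    "e": e,
                    "d": 1.0 - e,
                    "constant": is_const,
                }
            )
    table = pd.DataFrame.from_records(records)
    return EntropyTable(table=table, sample_axis=prop.sample_axis, spec=prop.spec)


def weights(ent: EntropyTable, spec: Sequence[IndicatorSpec] | None = None) -> WeightTable:
    """Redundancy-proportional weights, renormalized within each subsystem.

    Within every sample group and subsystem, ``w_j = d_j / Σ d_j``; group
    weights are then averaged across groups (the "average weighting" used
    when entropy is computed on per-year cross-sections).  A subsystem in
    which every indicator has zero redundancy admits no weighting and raises.
    """
    spec = list(spec) if spec is not None else ent.spec
    subsys = {s.indicator_id: s.subsystem for s in spec}
    t = ent.table.copy()
    t["subsystem"] = t["indicator_id"].map(subsys)

    per_group_rows = []
    for (g, sub), block in t.groupby(["group", "subsystem"]):
        dsum = block["d"].sum()
        if dsum <= 0:
            raise ValueError(
                f"no discriminating indicators in subsystem {sub!r} "
                f"(sample group {g!r}): all redundancies are zero"
            )
        for _, row in block.iterrows():
            per_group_rows.append(
                {
                    "group": g,
                    "subsystem": sub,
                    "indicator_id": row["indicator_id"],
                    "weight": row["d"] / dsum,
                }
            )
    per_group = pd.DataFrame.from_records(per_group_rows)

    mean_w = per_group.groupby("indicator_id")["weight"].mean()
    wt = pd.DataFrame(
        {
            "subsystem": pd.Series(subsys),
            "weight": mean_w,
        }
    ).loc[[s.indicator_id for s in spec]]
    # mean of unit-sum vectors is unit-sum; renormalize to kill fp drift
    wt["weight"] = wt["weight"] / wt.groupby("subsystem")["weight"].transform("sum")
    wt.index.name = "indicator_id"
    return WeightTable(weights=wt, per_group=per_group)


def composite_scores(
    norm: NormalizedPanel,
    w: WeightTable,
    score_base: ScoreBase = "normalized",
) -> pd.DataFrame:
    """Subsystem composite scores per (region, year).

    Returns a DataFrame with columns ``U1`` (elderly population), ``U2``
    (healthcare demand) and ``U3`` (healthcare supply):
    ``U = Σ_j w_j · b_j`` with base ``b`` either the normalized values
    (default; scores live on [0, 1] and reach 1 when every indicator is at
    its best) or the proportion shares ``Y``.
    """
    if score_base == "normalized":
        base = norm.values
    elif score_base == "proportion":
        base = proportions(norm).values
    else:
        raise ValueError(f"unknown score_base {score_base!r}")

    subsys = {s.indicator_id: s.subsystem for s in norm.spec}
    out = {}
    for sub in SUBSYSTEMS:
        cols = [i for i in base.columns if subsys[i] == sub]
        wv = w.weights.loc[cols, "weight"]
        out[SCORE_NAMES[sub]] = base[cols].mul(wv, axis=1).sum(axis=1)
    return pd.DataFrame(out, index=base.index)


def entropy_weight_scores(
    panel: IndicatorPanel,
    sample_axis: SampleAxis = "years",
    minmax_panel: IndicatorPanel | None = None,
    score_base: ScoreBase = "normalized",
) -> tuple[NormalizedPanel, WeightTable, pd.DataFrame]:
    """Run the full chain and return (normalized panel, weights, U scores)."""
    norm = normalize(panel, sample_axis=sample_axis, minmax_panel=minmax_panel)
    w = weights(entropy(proportions(norm)))
    scores = composite_scores(norm, w, score_base=score_base)
    return norm, w, scores
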