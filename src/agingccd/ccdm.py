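"""Coupling coordination degree model (CCDM) for three subsystems.

Given per-region-year composite scores U1 (elderly population), U2
(healthcare demand) and U3 (healthcare supply), the model computes

* the coupling degree ``C = [U1·U2·U3 / ((U1+U2+U3)/3)^3]^(1/3)`` — a [0, 1]
  balance statistic, maximal exactly when the three scores are equal (an
  AM–GM ratio raised to 1/3);
* the comprehensive development level ``T = β1·U1 + β2·U2 + β3·U3`` with
  nonnegative coefficients summing to one (equal thirds by default);
* the coupling coordination degree ``D = sqrt(C · T)``, the headline
  statistic combining balance with overall level.

Three classification schemes label the results: a six-class coupling-stage
scheme on C (with point classes at 0 and 1), a five-class coordination
scheme on D with an associated coordination type, and an objective-quartile
four-level scheme on a series of T values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .entropy import (
    SampleAxis,
    ScoreBase,
    entropy_weight_scores,
    pad_panel_years,
)
from .indicators import IndicatorPanel

DEFAULT_BETAS: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

COUPLING_DISORDERLY = "Stages of Disorderly Development"
COUPLING_LOW = "Low-level coupling development stage"
COUPLING_ANTAGONISTIC = "Antagonistic developmental stage"
COUPLING_BREAK_IN = "Break-in development stage"
COUPLING_HIGH = "High-level coupling development stage"
COUPLING_RESONANCE = "Benign resonance stage"

TYPE_DYSFUNCTIONAL = "Dysfunctional recession category"
TYPE_OVERDEVELOPMENT = "Overdevelopment category"
TYPE_COORDINATED = "Coordinated development category"

LEVEL_LABELS = ("Low level", "Medium level", "Relatively high level", "High level")


# ---------------------------------------------------------------------------
# core quantities

def coupling_degree(u1: float, u2: float, u3: float) -> float:
    """Coupling degree C of three nonnegative subsystem scores.

    C = (geometric mean / arithmetic mean)^... precisely
    ``[u1·u2·u3 / ((u1+u2+u3)/3)^3]^(1/3)``, symmetric in its arguments,
    in [0, 1], equal to 1 iff the three scores are equal and positive.
    The degenerate all-zero triple is defined as C = 0 (the disorderly
    stage) with a warning, avoiding the 0/0.
    """
    if u1 < 0 or u2 < 0 or u3 < 0:
        raise ValueError("subsystem scores must be nonnegative")
    s = u1 + u2 + u3
    if s == 0:
        warnings.warn(
            "all three subsystem scores are zero; coupling degree defined as 0",
            stacklevel=2,
        )
        return 0.0
    num, den = u1 * u2 * u3, (s / 3.0) ** 3
    if num == 0.0 or den == 0.0:  # zero factor, or denormal underflow
        return 0.0
    ratio = num / den
    return float(min(max(ratio, 0.0), 1.0) ** (1.0 / 3.0))


def comprehensive_level(
    u1: float, u2: float, u3: float, betas: Sequence[float] = DEFAULT_BETAS
) -> float:
    """Comprehensive development level T = β1·U1 + β2·U2 + β3·U3."""
    b = np.asarray(betas, dtype=float)
    if b.shape != (3,) or (b < 0).any():
        raise ValueError("betas must be three nonnegative coefficients")
    if abs(b.sum() - 1.0) > 1e-9:
        raise ValueError(f"betas must sum to 1, got {b.sum()}")
    return float(b[0] * u1 + b[1] * u2 + b[2] * u3)


def coordination_degree(c: float, t: float) -> float:
    """Coupling coordination degree D = sqrt(C · T)."""
    if not (0.0 <= c <= 1.0 and 0.0 <= t <= 1.0):
        raise ValueError("C and T must lie in [0, 1]")
    return float(np.sqrt(c * t))


# ---------------------------------------------------------------------------
# classification

def classify_coupling(c: float) -> str:
    """Six-stage coupling classification with point classes at 0 and 1.

    0 → disorderly; (0, 0.3) → low-level; [0.3, 0.5) → antagonistic;
    [0.5, 0.8) → break-in; [0.8, 1) → high-level; 1 → benign resonance.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"coupling degree {c} outside [0, 1]")
    if c == 0.0:
        return COUPLING_DISORDERLY
    if c == 1.0:
        return COUPLING_RESONANCE
    if c < 0.3:
        return COUPLING_LOW
    if c < 0.5:
        return COUPLING_ANTAGONISTIC
    if c < 0.8:
        return COUPLING_BREAK_IN
    return COUPLING_HIGH


def classify_coordination(d: float) -> tuple[str, str]:
    """Five-class coordination degree with its coordination type.

    <0.20 serious dissonance and [0.20, 0.40) mild disorder (dysfunctional
    recession); [0.40, 0.60) general coordination (overdevelopment);
    [0.60, 0.80) moderate and [0.80, 1] highly coordinated (coordinated
    development).  Intervals are left-closed right-open except the last,
    which is closed at 1.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"coordination degree {d} outside [0, 1]")
    if d < 0.20:
        return "Serious dissonance", TYPE_DYSFUNCTIONAL
    if d < 0.40:
        return "Mild disorder", TYPE_DYSFUNCTIONAL
    if d < 0.60:
        return "General coordination", TYPE_OVERDEVELOPMENT
    if d < 0.80:
        return "Moderate coordination", TYPE_COORDINATED
    return "Highly coordinated", TYPE_COORDINATED


def classify_level_quartiles(t_series: Iterable[float]) -> list[str]:
    """Objective-quartile classification of a comprehensive-level series.

    The empirical quartiles Q1, Q2, Q3 (linear interpolation, the common
    "type 7" rule) split the series into four ordered classes: below Q1 →
    low; [Q1, Q2) → medium; [Q2, Q3) → relatively high; at or above Q3 →
    high.  Ties on a boundary deterministically take the higher class.
    """
    t = np.asarray(list(t_series), dtype=float)
    if t.size < 4:
        raise ValueError("quartile classification needs at least 4 values")
    q1, q2, q3 = np.quantile(t, [0.25, 0.5, 0.75], method="linear")
    out = []
    for v in t:
        if v >= q3:
            out.append(LEVEL_LABELS[3])
        elif v >= q2:
            out.append(LEVEL_LABELS[2])
        elif v >= q1:
            out.append(LEVEL_LABELS[1])
        else:
            out.append(LEVEL_LABELS[0])
    return out


# ---------------------------------------------------------------------------
# end-to-end evaluation

@dataclass
class EvalConfig:
    """Options for the end-to-end panel evaluation.

    ``window`` optionally widens the min–max normalization window by linear
    extrapolation to the given (first_year, last_year); the extrapolated
    boundary years participate in min/max only, never in entropy or scores.
    """

    sample_axis: SampleAxis = "years"
    score_base: ScoreBase = "normalized"
    window: tuple[int, int] | None = None
    betas: tuple[float, float, float] = DEFAULT_BETAS

    def as_dict(self) -> dict:
        return {
            "sample_axis": self.sample_axis,
            "score_base": self.score_base,
            "window": list(self.window) if self.window else None,
            "betas": list(self.betas),
            "quartile_rule": "type7_linear_ties_up",
        }


@dataclass
class CCDResult:
    """One region-year's coupling coordination outcome."""

    region: str
    year: int
    U1: float
    U2: float
    U3: float
    C: float
    T: float
    D: float
    betas: tuple[float, float, float]
    coupling_class: str
    coordination_class: str
    coordination_type: str
    level_class: str


def evaluate_scores(
    scores: pd.DataFrame, betas: Sequence[float] = DEFAULT_BETAS
) -> pd.DataFrame:
    """Compute C, T, D and all class labels from a U1/U2/U3 score frame.

    Quartile levels for T are taken per region over that region's years.
    Returns a DataFrame indexed like ``scores`` with columns U1..D and the
    three classification labels.
    """
    out = scores.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero triples handled as C = 0
        out["C"] = [
            coupling_degree(r.U1, r.U2, r.U3) for r in scores.itertuples()
        ]
    out["T"] = [
        comprehensive_level(r.U1, r.U2, r.U3, betas) for r in scores.itertuples()
    ]
    out["D"] = [coordination_degree(c, t) for c, t in zip(out["C"], out["T"])]
    out["coupling_class"] = [classify_coupling(c) for c in out["C"]]
    cls = [classify_coordination(d) for d in out["D"]]
    out["coordination_class"] = [c for c, _ in cls]
    out["coordination_type"] = [t for _, t in cls]
    level = pd.Series(index=out.index, dtype=object)
    for region, block in out.groupby(level="region", sort=False):
        level.loc[block.index] = classify_level_quartiles(block["T"])
    out["level_class"] = level
    return out


def evaluate_panel(
    panel: IndicatorPanel, config: EvalConfig | None = None
) -> pd.DataFrame:
    """Full chain: raw panel → weights → U scores → C/T/D → classes.

    Deterministic given the panel and config.  Returns one row per
    (region, year) with columns U1, U2, U3, C, T, D, coupling_class,
    coordination_class, coordination_type, level_class.
    """
    cfg = config or EvalConfig()
    minmax_panel = (
        pad_panel_years(panel, *cfg.window) if cfg.window is not None else None
    )
    _, _, scores = entropy_weight_scores(
        panel,
        sample_axis=cfg.sample_axis,
        minmax_panel=minmax_panel,
        score_base=cfg.score_base,
    )
    return evaluate_scores(scores, betas=cfg.betas)


def results_as_records(results: pd.DataFrame, betas=DEFAULT_BETAS) -> list[CCDResult]:
    """View an evaluate_panel frame as a list of CCDResult records."""
    return [
        CCDResult(
            region=r.Index[0],
            year=int(r.Index[1]),
            U1=r.U1,
            U2=r.U2,
            U3=r.U3,
            C=r.C,
            T=r.T,
            D=r.D,
            betas=tuple(betas),
            coupling_class=r.coupling_class,
            coordination_class=r.coordination_class,
            coordination_type=r.coordination_type,
            level_class=r.level_class,
        )
        for r in results.itertuples()
    ]
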