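"""Synthetic multi-region indicator panels with known structure.

Two generators support testing every pipeline stage without any download:

* :func:`generate_panel` emulates a provincial-style panel: per-region
  monotone trends with Gaussian noise on the raw scale (truncated at zero,
  matching strictly positive yearbook-style data), a polarity mix per
  subsystem, once-per-region heterogeneity in trend levels (a stylized
  east–west development gradient), and a controllable *imbalance* knob that
  bends the three subsystems' trajectories apart.  At ``imbalance = 0`` and
  zero noise all indicators share one normalized trajectory, so the coupling
  degree is exactly 1 in every region-year — a sharp downstream oracle.

* :func:`generate_coordinated_panel` inverts the model: given a target
  coordination-degree profile ``D_t`` it constructs subsystem trajectories
  whose end-to-end evaluation reproduces the profile (exactly at zero
  noise), for parameter-recovery tests.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indicators import SUBSYSTEMS, IndicatorPanel, IndicatorSpec

#: polarity mix of the national indicator system (positive, negative)
DEFAULT_POLARITY_MIX: dict[str, tuple[int, int]] = {
    "elderly_population": (7, 0),
    "demand": (4, 3),
    "supply": (6, 0),
}

#: mean relative growth over the whole span, per subsystem
DEFAULT_TREND_SLOPES: dict[str, float] = {
    "elderly_population": 0.45,
    "demand": 0.6,
    "supply": 0.7,
}

# trajectory-curvature offsets that the imbalance knob scales; chosen to
# push the three subsystems apart symmetrically
_IMBALANCE_OFFSETS = {"elderly_population": -1.0, "demand": 0.0, "supply": 1.0}


@dataclass
class SyntheticConfig:
    """Configuration of the trend-plus-noise panel generator.

    ``noise_sd`` is the Gaussian noise standard deviation *relative to the
    indicator's base level*; ``imbalance`` bends the subsystems' trajectories
    apart (0 = identical normalized trajectories, hence perfect coupling).
    """

    n_regions: int = 31
    years: tuple[int, int] = (2012, 2022)
    trend_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREND_SLOPES)
    )
    noise_sd: float = 0.03
    polarity_mix: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_POLARITY_MIX)
    )
    imbalance: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.years[1] < self.years[0] + 1:
            raise ValueError("need at least two years")
        for sub in SUBSYSTEMS:
            npos, nneg = self.polarity_mix.get(sub, (0, 0))
            if npos + nneg < 1:
                raise ValueError(f"subsystem {sub!r} needs at least one indicator")


def synthetic_spec(cfg: SyntheticConfig) -> list[IndicatorSpec]:
    """Indicator specification implied by the config's polarity mix."""
    spec = []
    for sub in SUBSYSTEMS:
        npos, nneg = cfg.polarity_mix[sub]
        for i in range(npos):
            spec.append(
                IndicatorSpec(f"{sub}_p{i}", f"{sub} positive {i}", sub, "positive")
            )
        for i in range(nneg):
            spec.append(
                IndicatorSpec(f"{sub}_n{i}", f"{sub} negative {i}", sub, "negative")
            )
    return spec


def generate_panel(cfg: SyntheticConfig) -> IndicatorPanel:
    """Simulate a multi-region indicator panel.

    Each indicator follows ``base · (1 + slope · f(τ))`` for positive
    polarity (declining analogue for negative), where ``τ`` is the fraction
    of the year span elapsed and ``f(τ) = τ^γ`` with a subsystem- and
    region-specific exponent ``γ = exp(imbalance · offset · (1 + η_r))``.
    Gaussian noise with standard deviation ``noise_sd · base`` is added on
    the raw scale and truncated at zero.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = synthetic_spec(cfg)
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    tau = (years - y0) / (y1 - y0)

    regions = [f"region_{i:02d}" for i in range(cfg.n_regions)]
    # once-per-region heterogeneity: development level and imbalance tilt
    level = rng.uniform(0.5, 1.5, size=cfg.n_regions)
    tilt = rng.uniform(-0.5, 0.5, size=cfg.n_regions)

    frames = {}
    for ri, region in enumerate(regions):
        cols = {}
        for s in spec:
            base = 10.0 ** rng.uniform(1.0, 5.0)
            slope = cfg.trend_slopes.get(s.subsystem, 0.5) * level[ri]
            gamma = float(
                np.exp(cfg.imbalance * _IMBALANCE_OFFSETS[s.subsystem] * (1.0 + tilt[ri]))
            )
            f = tau**gamma
            if s.polarity == "positive":
                mu = base * (1.0 + slope * f)
            else:
                # negative indicators decline as the subsystem improves
                mu = base * (1.0 + slope * (1.0 - f))
            x = mu + rng.normal(0.0, cfg.noise_sd * base, size=mu.shape)
            cols[s.indicator_id] = np.maximum(x, 0.0)
        frames[region] = pd.DataFrame(cols, index=years)

    df = pd.concat(frames, names=["region", "year"])
    return IndicatorPanel(df, spec)


def generate_coordinated_panel(
    target_d: Sequence[float],
    seed: int = 0,
    start_year: int = 2012,
    n_indicators: int = 1,
    noise_sd: float = 0.0,
) -> IndicatorPanel:
    """Construct a single-region panel whose evaluated D matches a target.

    The construction makes the three subsystems identical, so the coupling
    degree is 1 and ``D = sqrt(T) = sqrt(U)``; the common subsystem score at
    each target year must therefore be ``u_t = D_t²``.  Raw indicator values
    are set to ``u_t`` (times an arbitrary per-indicator scale — min–max
    normalization is scale invariant) and two *anchor years* are appended
    just outside the target span carrying the subsystem minimum (0) and
    maximum (1), pinning the normalization so that the normalized value at
    each target year is exactly ``u_t``.  At zero noise the evaluated D then
    reproduces the target exactly; with noise the match degrades gracefully.

    Profiles must lie in (0, 1]; a target of 1 yields the all-max year.
    """
    d = np.asarray(list(target_d), dtype=float)
    if d.size < 1:
        raise ValueError("target profile must be non-empty")
    if (d <= 0).any() or (d > 1).any():
        raise ValueError(
            "target D values must lie in (0, 1]; a coupling degree above 1 "
            "would be required otherwise"
        )
    rng = np.random.default_rng(seed)
    u = d**2

    years = np.arange(start_year - 1, start_year + d.size + 1)
    traj = np.concatenate([[0.0], u, [1.0]])  # anchors pin min/max
    spec = []
    cols = {}
    for sub in SUBSYSTEMS:
        for i in range(n_indicators):
            iid = f"{sub}_i{i}"
            spec.append(IndicatorSpec(iid, f"{sub} indicator {i}", sub, "positive"))
            scale = 10.0 ** rng.uniform(0.0, 3.0)
            x = traj * scale
            if noise_sd > 0:
                x = np.maximum(x + rng.normal(0.0, noise_sd * scale, x.shape), 0.0)
            cols[iid] = x
    df = pd.DataFrame(cols, index=pd.MultiIndex.from_product(
        [["synthetic"], years], names=["region", "year"]
    ))
    return IndicatorPanel(df, spec)
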