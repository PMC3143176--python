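"""Synthetic survey, productivity-target, and ovitrap-positivity generators.

No field data ship with the package; these generators emulate the statistical
structure of the inputs the pipeline consumes: a household container survey on
a 17x9 block of 153 houses holding 871 water-filled containers across 14
categories, a pupal-productivity target distribution over those categories,
and a weekly ovitrap-positivity series for temperate- or equatorial-climate
monitoring.  All draws are seeded and deterministic.

Default type frequencies and volume scales are plausible order-of-magnitude
choices (cans and bottles common and small, large tanks and wells rare and
big); they are configuration, not reconstructions of any real survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import PositivitySeries, ProductivityTable
from .habitat import CONTAINER_TYPES, ContainerSpec, House

__all__ = [
    "SurveyGenParams",
    "TargetGenParams",
    "generate_survey_subset",
    "generate_target_productivity",
    "generate_positivity_series",
]


def _default_type_weights() -> dict[str, float]:
    w = {
        "plastic": 0.16,
        "medium storage": 0.09,
        "large tanks": 0.05,
        "tires": 0.07,
        "non-traditional": 0.06,
        "cooking": 0.06,
        "miscellaneous": 0.08,
        "flower pots": 0.07,
        "cans": 0.12,
        "bath": 0.04,
        "bottles": 0.10,
        "natural": 0.04,
        "wells": 0.02,
        "pet": 0.04,
    }
    assert abs(sum(w.values()) - 1.0) < 1e-9
    return w


def _default_volume_params() -> dict[str, tuple[float, float]]:
    # lognormal (mu of log-liters, sigma) per type
    big = (4.0, 0.5)      # ~55 L median
    medium = (2.3, 0.6)   # ~10 L
    small = (0.0, 0.7)    # ~1 L
    tiny = (-1.2, 0.6)    # ~0.3 L
    return {
        "plastic": medium,
        "medium storage": (3.0, 0.5),
        "large tanks": big,
        "tires": (1.6, 0.4),
        "non-traditional": small,
        "cooking": small,
        "miscellaneous": small,
        "flower pots": small,
        "cans": tiny,
        "bath": (3.4, 0.4),
        "bottles": tiny,
        "natural": small,
        "wells": (4.6, 0.5),
        "pet": tiny,
    }


@dataclass(frozen=True)
class SurveyGenParams:
    """Study conditions of the synthetic household container survey."""

    n_rows: int = 17
    n_cols: int = 9
    target_container_total: int = 871
    type_weights: dict[str, float] = field(default_factory=_default_type_weights)
    volume_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_volume_params
    )
    indoor_fraction: float = 0.35
    lid_fraction: float = 0.25
    #: probabilities of (manual, passive-rain, assisted-rain) fill
    fill_mix: tuple[float, float, float] = (0.45, 0.35, 0.20)

    def __post_init__(self) -> None:
        w = np.array([self.type_weights.get(t, 0.0) for t in CONTAINER_TYPES])
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("type weights must be >= 0 and sum to 1")
        if abs(sum(self.fill_mix) - 1.0) > 1e-9:
            raise ValueError("fill_mix must sum to 1")


def generate_survey_subset(p: SurveyGenParams, seed: int = 0) -> list[House]:
    """Draw a synthetic surveyed block of houses with container inventories.

    Produces exactly ``n_rows * n_cols`` houses and exactly
    ``target_container_total`` containers.  Per-house counts are iid-Poisson
    conditioned on the total — drawn multinomially with equal cell
    probabilities, which is that conditional law exactly.
    """
    rng = np.random.default_rng(seed)
    n_houses = p.n_rows * p.n_cols
    per_house = rng.multinomial(
        p.target_container_total, np.full(n_houses, 1.0 / n_houses)
    )
    weights = np.array([p.type_weights.get(t, 0.0) for t in CONTAINER_TYPES])

    houses: list[House] = []
    cid = 0
    for hi in range(n_houses):
        row, col = divmod(hi, p.n_cols)
        containers = []
        for _ in range(per_house[hi]):
            ti = rng.choice(len(CONTAINER_TYPES), p=weights)
            tname = CONTAINER_TYPES[ti]
            mu, sigma = p.volume_params[tname]
            vol = float(np.round(rng.lognormal(mu, sigma), 2))
            vol = max(vol, 0.05)
            inside = rng.random() < p.indoor_fraction
            fill = ("manual", "passive-rain", "assisted-rain")[
                rng.choice(3, p=np.asarray(p.fill_mix))
            ]
            if inside:
                fill = "manual"  # indoor containers cannot catch rain
            sun = float(np.round(rng.random(), 2)) if not inside else 0.0
            containers.append(
                ContainerSpec(
                    container_id=f"c{cid:05d}",
                    house_id=f"h{hi:03d}",
                    type_name=tname,
                    location="inside" if inside else "outside",
                    sun_exposure=sun,
                    has_lid=bool(rng.random() < p.lid_fraction),
                    fill_method=fill,
                    volume_l=vol,
                )
            )
            cid += 1
        houses.append(
            House(house_id=f"h{hi:03d}", row=row, col=col,
                  containers=tuple(containers))
        )
    return houses


@dataclass(frozen=True)
class TargetGenParams:
    """Dirichlet draw over the 14 type shares, optionally order-constrained."""

    concentration: float = 2.0
    enforce_order: bool = True  # decreasing share along the canonical type order


def generate_target_productivity(
    p: TargetGenParams, seed: int = 0
) -> ProductivityTable:
    """Draw a valid productivity target distribution over the 14 types.

    With ``enforce_order`` the shares are sorted decreasing along the
    canonical category order (the order the field literature reports, from
    plastic down to pet containers).
    """
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(len(CONTAINER_TYPES), p.concentration))
    if p.enforce_order:
        shares = np.sort(shares)[::-1]
    return ProductivityTable.from_array(shares)


def generate_positivity_series(
    regime: str,
    n_weeks: int = 52,
    noise: float = 0.03,
    seed: int = 0,
) -> PositivitySeries:
    """Synthetic weekly ovitrap-positivity series.

    ``temperate``: a single broad summer peak with zero positivity through
    the cold half of the year (Southern-hemisphere phase: weeks count from
    the start of the calendar year, trough at mid-year).  ``equatorial``:
    high, weakly varying positivity all year.  Values are clipped to [0, 1];
    with ``noise=0`` the temperate cold-season weeks are exactly zero.
    """
    if n_weeks < 52:
        raise ValueError("n_weeks must be >= 52")
    rng = np.random.default_rng(seed)
    w = np.arange(n_weeks)
    phase = np.cos(2.0 * np.pi * w / 52.0)
    if regime == "temperate":
        base = np.maximum(0.0, 0.9 * phase - 0.25)
    elif regime == "equatorial":
        base = 0.75 + 0.05 * phase
    else:
        raise ValueError("regime must be 'temperate' or 'equatorial'")
    frac = base + np.where(base > 0, rng.normal(0.0, noise, n_weeks), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return PositivitySeries(w, frac)
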