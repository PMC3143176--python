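"""Daily-step stochastic simulation of container-breeding mosquito populations.

Each house on the grid holds surveyed water containers; within every container
the model tracks water, a food pool, and cohorts of immature stages (eggs,
larvae, pupae); adult females are counted per house.  Food follows a four-term
daily balance — baseline input, decay, larval consumption, cadaver recycling —
and is the mechanistic basis of larval density dependence: crowded containers
run out of food, larvae starve, die more, and pupate later.

The daily food input into a container of type *i* at location *j* with volume
*V* is ``F = F0 * alpha_i * beta_j * V`` with the normalization
``alpha(large tanks) = 1`` and ``beta(outside) = 1``; only relative values of
the type and location coefficients are identifiable, the overall scale being
absorbed by ``F0``.

The detailed enzyme-kinetic development and weight-gain equations of the
CIMSiM lineage are deliberately replaced by a simplified cohort model:
degree-day development above a temperature threshold, linear conversion of
ingested food into weight, and a starvation clock with multiplied mortality.
The simplification preserves the contract that matters here — food-mediated
density dependence — while keeping the model fully specified by the
parameters below.

Implementation: a single vectorized engine steps all containers (age-indexed
cohort arrays) and all houses at once; the per-entity ``step_container`` and
``step_house`` operations run the same kernels on single-entity batches, so
there is exactly one code path for the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .habitat import (
    CONTAINER_TYPES,
    REFERENCE_LOCATION,
    REFERENCE_TYPE,
    ContainerSpec,
    House,
    SimulationGrid,
)
from .weather import WeatherSeries

__all__ = [
    "BiologyParams",
    "LarvalCohort",
    "EggBatch",
    "PupalCohort",
    "ContainerState",
    "HouseState",
    "SimOutput",
    "daily_food_input",
    "step_container",
    "step_house",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# parameters

def _default_alpha() -> dict[str, float]:
    return {t: 1.0 for t in CONTAINER_TYPES}


def _default_beta() -> dict[str, float]:
    return {"outside": 1.0, "inside": 0.7}


@dataclass(frozen=True)
class BiologyParams:
    """All tunable biology of the simplified cohort model.

    Units: food in liver-powder-equivalent mg, weights in mg, volumes in
    liters, temperatures in degC, rates per day.
    """

    #: baseline food input, mg per liter of container volume per day
    F0: float = 0.3
    #: container-type coefficients; alpha["large tanks"] must equal 1
    alpha: Mapping[str, float] = field(default_factory=_default_alpha)
    #: location coefficients; beta["outside"] must equal 1
    beta: Mapping[str, float] = field(default_factory=_default_beta)
    #: fraction of the food pool lost per day
    food_decay_rate: float = 0.1
    #: fraction of dead immature biomass returned to the food pool
    cadaver_conversion: float = 0.5
    #: ad-libitum ingestion ceiling, mg food per mg larva per day
    larval_intake_rate: float = 1.0
    #: mg of larval weight gained per mg of food ingested
    growth_efficiency: float = 0.3
    #: minimum weight for pupation, mg
    pupation_weight: float = 1.0
    #: hatch is blocked below this water temperature
    min_hatch_water_temp: float = 22.0
    #: development fraction gained per degree-day above dev_base_temp
    dev_rate_coeff: float = 0.009
    #: lower development threshold temperature
    dev_base_temp: float = 13.4
    #: daily survival, eggs in a wet container
    egg_daily_survival: float = 0.99
    #: daily survival, eggs in a dry container (desiccation-resistant but reduced)
    dry_egg_daily_survival: float = 0.98
    larval_daily_survival: float = 0.95
    pupal_daily_survival: float = 0.97
    #: multiplier applied to larval daily mortality while starving
    starvation_mortality_multiplier: float = 3.0
    #: consecutive starving days a cohort survives on reserves
    starvation_reserve_days: int = 3
    #: intake below this fraction of the ad-libitum demand counts as starving
    starvation_intake_fraction: float = 0.2
    initial_larval_weight: float = 0.02
    max_larval_age_days: int = 45
    pupal_duration_days: int = 2
    egg_maturation_days: int = 3
    gonotrophic_cycle_days: int = 4
    eggs_per_batch: int = 60
    adult_daily_survival: float = 0.89
    emergence_female_fraction: float = 0.5
    #: per-day probability a female moves to a Manhattan-adjacent house
    dispersal_prob: float = 0.3
    #: water model: fraction of standing water evaporating per day
    evaporation_rate: float = 0.03
    fill_efficiency_passive: float = 2.0
    fill_efficiency_assisted: float = 6.0
    #: a container counts as wet above this fraction of its volume
    wet_fraction: float = 0.05

    def __post_init__(self) -> None:
        if abs(self.alpha[REFERENCE_TYPE] - 1.0) > 1e-9:
            raise ValueError(f"alpha[{REFERENCE_TYPE!r}] must be 1 (normalization)")
        if abs(self.beta[REFERENCE_LOCATION] - 1.0) > 1e-9:
            raise ValueError(f"beta[{REFERENCE_LOCATION!r}] must be 1 (normalization)")
        for name, lo, hi in [
            ("food_decay_rate", 0, 1), ("cadaver_conversion", 0, 1),
            ("egg_daily_survival", 0, 1), ("dry_egg_daily_survival", 0, 1),
            ("larval_daily_survival", 0, 1), ("pupal_daily_survival", 0, 1),
            ("adult_daily_survival", 0, 1), ("dispersal_prob", 0, 1),
            ("emergence_female_fraction", 0, 1), ("starvation_intake_fraction", 0, 1),
            ("evaporation_rate", 0, 1), ("wet_fraction", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.F0 < 0:
            raise ValueError("F0 must be >= 0")
        if any(a < 0 for a in self.alpha.values()):
            raise ValueError("alpha coefficients must be >= 0")
        if any(b < 0 for b in self.beta.values()):
            raise ValueError("beta coefficients must be >= 0")

    def with_food_coefficients(self, F0=None, alpha=None, beta=None) -> "BiologyParams":
        return replace(
            self,
            F0=self.F0 if F0 is None else F0,
            alpha=dict(self.alpha) if alpha is None else dict(alpha),
            beta=dict(self.beta) if beta is None else dict(beta),
        )


def daily_food_input(spec: ContainerSpec, params: BiologyParams) -> float:
    """Daily food input F = F0 * alpha_type * beta_location * volume (mg/day)."""
    return (
        params.F0
        * params.alpha[spec.type_name]
        * params.beta[spec.location]
        * spec.volume_l
    )


# ---------------------------------------------------------------------------
# object-level state (thin, converts to/from the array engine)

@dataclass
class EggBatch:
    n: int
    days_mature: int  # days since laid; hatch-competent once >= egg_maturation_days
    wet: bool = True


@dataclass
class LarvalCohort:
    n: int
    age: int
    mean_weight: float
    dev_fraction: float = 0.0
    starving_days: int = 0


@dataclass
class PupalCohort:
    n: int
    days: int


@dataclass
class ContainerState:
    spec: ContainerSpec
    water_volume: float
    water_temp: float = 25.0
    food: float = 0.0
    egg_batches: list[EggBatch] = field(default_factory=list)
    larval_cohorts: list[LarvalCohort] = field(default_factory=list)
    pupal_cohorts: list[PupalCohort] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.food < 0:
            raise ValueError("food must be >= 0")
        if not 0 <= self.water_volume <= self.spec.volume_l + 1e-9:
            raise ValueError("water volume outside [0, container volume]")

    @property
    def n_eggs(self) -> int:
        return sum(b.n for b in self.egg_batches)

    @property
    def n_larvae(self) -> int:
        return sum(c.n for c in self.larval_cohorts)

    @property
    def n_pupae(self) -> int:
        return sum(c.n for c in self.pupal_cohorts)


@dataclass
class HouseState:
    house: House
    containers: list[ContainerState]
    females_pre: int = 0       # not yet gravid (progress tracked internally)
    females_gravid: int = 0
    cumulative_pupae: int = 0


# ---------------------------------------------------------------------------
# array engine

_FILL_CODE = {"manual": 0, "passive-rain": 1, "assisted-rain": 2}


class _Engine:
    """Vectorized daily-step engine over all containers and houses of a grid."""

    def __init__(self, grid: SimulationGrid, params: BiologyParams,
                 rng: np.random.Generator):
        self.grid = grid
        self.p = params
        self.rng = rng

        houses = grid.houses
        self.H = len(houses)
        specs: list[ContainerSpec] = []
        house_of: list[int] = []
        self.cont_slices: list[slice] = []
        start = 0
        for hi, h in enumerate(houses):
            for c in h.containers:
                specs.append(c)
                house_of.append(hi)
            self.cont_slices.append(slice(start, start + len(h.containers)))
            start += len(h.containers)
        self.specs = specs
        self.C = len(specs)
        self.house_of = np.asarray(house_of, dtype=np.intp)

        p = params
        self.vol = np.array([c.volume_l for c in specs], dtype=float)
        self.sun = np.array([c.sun_exposure for c in specs], dtype=float)
        self.inside = np.array([c.location == "inside" for c in specs], dtype=bool)
        self.lid = np.array([c.has_lid for c in specs], dtype=bool)
        self.fill = np.array([_FILL_CODE[c.fill_method] for c in specs], dtype=np.intp)
        self.type_idx = np.array([c.type_index for c in specs], dtype=np.intp)
        self.food_in = np.array([daily_food_input(c, p) for c in specs], dtype=float)
        self.ovi_weight = self.vol ** (2.0 / 3.0)
        self.area = self.vol ** (2.0 / 3.0)  # catch/evaporation surface, dm^2

        # neighbor structure (Manhattan-adjacent houses) for dispersal
        pos = {(h.row, h.col): i for i, h in enumerate(houses)}
        nbr = np.full((self.H, 4), -1, dtype=np.intp)
        for i, h in enumerate(houses):
            for k, (dr, dc) in enumerate(((1, 0), (-1, 0), (0, 1), (0, -1))):
                j = pos.get((h.row + dr, h.col + dc))
                if j is not None:
                    nbr[i, k] = j
        self.nbr = nbr
        valid = nbr >= 0
        with np.errstate(invalid="ignore"):
            self.nbr_p = np.where(valid, 1.0, 0.0)
            self.nbr_p /= np.maximum(self.nbr_p.sum(axis=1, keepdims=True), 1)

        # dynamic state
        E = p.egg_maturation_days
        L = p.max_larval_age_days
        P = p.pupal_duration_days
        G = p.gonotrophic_cycle_days
        self.water = self.vol.copy()
        self.water_temp = np.full(self.C, 25.0)
        self.food = self.food_in * 2.0  # two days' input as initial pool
        self.eggs_imm = np.zeros((self.C, E), dtype=np.int64)
        self.eggs_mat = np.zeros(self.C, dtype=np.int64)
        self.ln = np.zeros((self.C, L), dtype=np.int64)
        self.lw = np.zeros((self.C, L))
        self.ldev = np.zeros((self.C, L))
        self.lstv = np.zeros((self.C, L), dtype=np.int64)
        self.pup = np.zeros((self.C, P), dtype=np.int64)
        self.females = np.zeros((self.H, G), dtype=np.int64)
        self.gravid = np.zeros(self.H, dtype=np.int64)

    # -- initialization ----------------------------------------------------
    def seed_inoculum(self, eggs: int = 10, larvae: int = 5) -> None:
        if self.C == 0:
            return
        self.eggs_mat += eggs
        if larvae > 0:
            self.ln[:, 0] += larvae
            self.lw[:, 0] = self.p.initial_larval_weight

    # -- one day -----------------------------------------------------------
    def step_day(self, tmean: float, rain: float) -> dict:
        t = self._container_phase(tmean, rain)
        t.update(self._adult_phase(t["emerged"], t["wet"]))
        return t

    def _container_phase(self, tmean: float, rain: float) -> dict:
        p, rng = self.p, self.rng
        t = {}

        # 1. aging shifts; age-capped larvae die, oldest pupae emerge
        emerged = self.pup[:, -1].copy()
        self.pup[:, 1:] = self.pup[:, :-1]
        self.pup[:, 0] = 0

        overflow_n = self.ln[:, -1].copy()
        overflow_mass = overflow_n * self.lw[:, -1]
        for a in (self.ln, self.lw, self.ldev, self.lstv):
            a[:, 1:] = a[:, :-1]
            a[:, 0] = 0

        matured = self.eggs_imm[:, -1].copy()
        self.eggs_imm[:, 1:] = self.eggs_imm[:, :-1]
        self.eggs_imm[:, 0] = 0
        self.eggs_mat += matured

        # 2. water volume and temperature
        self.water_temp = np.where(
            self.inside, tmean - 1.0, tmean + 3.0 * self.sun
        )
        lid_factor = np.where(self.lid, 0.5, 1.0)
        evap = self.water * p.evaporation_rate * lid_factor
        eff = np.choose(self.fill, [0.0, p.fill_efficiency_passive,
                                    p.fill_efficiency_assisted])
        gain = 0.01 * rain * self.area * eff * lid_factor  # liters
        self.water = np.minimum(self.vol, self.water - evap + gain)
        self.water[self.fill == 0] = self.vol[self.fill == 0]  # manual: kept full
        wet = self.water >= p.wet_fraction * self.vol

        # 3. food input and decay
        food0 = self.food
        pool = food0 + self.food_in
        decay = pool * p.food_decay_rate
        self.food = pool - decay

        # 4. hatch (mature + wet + warm enough)
        can_hatch = wet & (self.water_temp >= p.min_hatch_water_temp)
        hatched = np.where(can_hatch, self.eggs_mat, 0)
        self.eggs_mat -= hatched
        self.ln[:, 0] = hatched
        self.lw[:, 0] = np.where(hatched > 0, p.initial_larval_weight, 0.0)

        # 5. consumption, growth, starvation clock
        demand = p.larval_intake_rate * self.lw * self.ln  # (C, L)
        tot_demand = demand.sum(axis=1)
        intake_tot = np.minimum(self.food, tot_demand)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(tot_demand > 0, intake_tot / tot_demand, 1.0)
        self.food = self.food - intake_tot
        grow = 1.0 + p.growth_efficiency * p.larval_intake_rate * ratio[:, None]
        self.lw = np.where(self.ln > 0, self.lw * grow, self.lw)
        starving = (ratio < p.starvation_intake_fraction)[:, None] & (self.ln > 0)
        self.lstv = np.where(starving, self.lstv + 1, 0)

        # 6. degree-day development
        dd = np.maximum(0.0, self.water_temp - p.dev_base_temp)
        self.ldev = np.where(
            self.ln > 0, self.ldev + p.dev_rate_coeff * dd[:, None], self.ldev
        )

        # 7. pupation
        ready = (self.ln > 0) & (self.ldev >= 1.0) & (self.lw >= p.pupation_weight)
        pupated = np.where(ready, self.ln, 0).sum(axis=1)
        self.pup[:, 0] += pupated
        self.ln[ready] = 0
        self.lw[ready] = 0.0
        self.ldev[ready] = 0.0
        self.lstv[ready] = 0

        # 8. survival draws; deaths feed the cadaver pool
        egg_p = np.where(wet, p.egg_daily_survival, p.dry_egg_daily_survival)
        eggs_imm_new = rng.binomial(self.eggs_imm, egg_p[:, None])
        eggs_mat_new = rng.binomial(self.eggs_mat, egg_p)
        egg_deaths = (self.eggs_imm - eggs_imm_new).sum(axis=1) + (
            self.eggs_mat - eggs_mat_new
        )
        self.eggs_imm, self.eggs_mat = eggs_imm_new, eggs_mat_new

        q = 1.0 - p.larval_daily_survival
        q_slot = np.where(self.lstv > 0,
                          np.minimum(1.0, q * p.starvation_mortality_multiplier), q)
        surv_slot = np.where(self.lstv > p.starvation_reserve_days, 0.0, 1.0 - q_slot)
        ln_new = rng.binomial(self.ln, surv_slot)
        larval_dead = self.ln - ln_new
        cadaver_mass = overflow_mass.copy()
        cadaver_mass += (larval_dead * self.lw).sum(axis=1)
        larval_deaths = larval_dead.sum(axis=1) + overflow_n
        self.ln = ln_new

        pup_new = rng.binomial(self.pup, p.pupal_daily_survival)
        pupal_deaths = (self.pup - pup_new).sum(axis=1)
        cadaver_mass += (self.pup - pup_new).sum(axis=1) * p.pupation_weight
        self.pup = pup_new

        cadaver = p.cadaver_conversion * cadaver_mass
        self.food = self.food + cadaver

        t.update(
            emerged=emerged, pupated=pupated, hatched=hatched,
            egg_deaths=egg_deaths, larval_deaths=larval_deaths,
            pupal_deaths=pupal_deaths, wet=wet,
            water_temp=self.water_temp.copy(),
            food_end=self.food.copy(), food_start=food0,
            food_input=self.food_in.copy(), food_decay=decay,
            food_consumed=intake_tot, food_cadaver=cadaver,
        )
        return t

    def _adult_phase(self, emerged: np.ndarray, wet: np.ndarray) -> dict:
        p, rng = self.p, self.rng
        t = {}

        # 9. adults: emergence, survival, gonotrophic aging, dispersal
        emerged_h = np.zeros(self.H, dtype=np.int64)
        np.add.at(emerged_h, self.house_of, emerged)
        new_females = rng.binomial(emerged_h, p.emergence_female_fraction)

        adults_before = self.females.sum() + self.gravid.sum()
        self.females = rng.binomial(self.females, p.adult_daily_survival)
        self.gravid = rng.binomial(self.gravid, p.adult_daily_survival)
        completing = self.females[:, -1].copy()
        self.females[:, 1:] = self.females[:, :-1]
        self.females[:, 0] = new_females
        self.gravid = self.gravid + completing

        disp_in = np.zeros(self.H, dtype=np.int64)
        disp_out = np.zeros(self.H, dtype=np.int64)
        if p.dispersal_prob > 0 and self.H > 1:
            cols = [self.females[:, g] for g in range(self.females.shape[1])]
            cols.append(self.gravid)
            for idx, col in enumerate(cols):
                movers = rng.binomial(col, p.dispersal_prob)
                has_nbr = self.nbr_p.sum(axis=1) > 0
                movers = np.where(has_nbr, movers, 0)
                if movers.sum() == 0:
                    continue
                dirs = rng.multinomial(movers, self.nbr_p)
                col -= movers
                disp_out += movers
                flat_idx = self.nbr.ravel()
                flat_cnt = dirs.ravel()
                ok = flat_idx >= 0
                arrivals = np.zeros(self.H, dtype=np.int64)
                np.add.at(arrivals, flat_idx[ok], flat_cnt[ok])
                col += arrivals
                disp_in += arrivals
                if idx < self.females.shape[1]:
                    self.females[:, idx] = col
                else:
                    self.gravid = col

        # 10. oviposition: each gravid female lays one batch into one wet
        #     container of her house, chosen with probability ~ V^(2/3)
        laid = np.zeros(self.C, dtype=np.int64)
        ovi = np.zeros(self.C, dtype=bool)
        for hi in np.nonzero(self.gravid)[0]:
            sl = self.cont_slices[hi]
            wet_local = wet[sl]
            if not wet_local.any():
                continue  # stays gravid, retries tomorrow
            w = np.where(wet_local, self.ovi_weight[sl], 0.0)
            counts = self.rng.multinomial(self.gravid[hi], w / w.sum())
            laid[sl] += counts * p.eggs_per_batch
            ovi[sl] |= counts > 0
            self.females[hi, 0] += self.gravid[hi]
            self.gravid[hi] = 0
        self.eggs_imm[:, 0] += laid

        t.update(
            laid=laid, ovi=ovi,
            emerged_females=new_females,
            adult_deaths=int(
                adults_before
                - (self.females.sum() + self.gravid.sum())
                + new_females.sum()
            ),
            disp_in=disp_in, disp_out=disp_out,
        )
        return t

    # -- snapshots ---------------------------------------------------------
    def stage_totals(self) -> tuple[int, int, int, int]:
        eggs = int(self.eggs_imm.sum() + self.eggs_mat.sum())
        larvae = int(self.ln.sum())
        pupae = int(self.pup.sum())
        adults = int(self.females.sum() + self.gravid.sum())
        return eggs, larvae, pupae, adults

    def pupae_per_house(self) -> np.ndarray:
        out = np.zeros(self.H, dtype=np.int64)
        np.add.at(out, self.house_of, self.pup.sum(axis=1))
        return out


# ---------------------------------------------------------------------------
# object-level wrappers (single-entity batches through the same kernels)

def _load_container(engine: _Engine, ci: int, state: ContainerState) -> None:
    p = engine.p
    engine.water[ci] = state.water_volume
    engine.water_temp[ci] = state.water_temp
    engine.food[ci] = state.food
    for b in state.egg_batches:
        if b.days_mature >= p.egg_maturation_days:
            engine.eggs_mat[ci] += b.n
        else:
            engine.eggs_imm[ci, b.days_mature] += b.n
    for c in state.larval_cohorts:
        a = min(c.age, p.max_larval_age_days - 1)
        engine.ln[ci, a] += c.n
        engine.lw[ci, a] = c.mean_weight
        engine.ldev[ci, a] = c.dev_fraction
        engine.lstv[ci, a] = c.starving_days
    for c in state.pupal_cohorts:
        engine.pup[ci, min(c.days, p.pupal_duration_days - 1)] += c.n


def _dump_container(engine: _Engine, ci: int, spec: ContainerSpec) -> ContainerState:
    p = engine.p
    batches = [
        EggBatch(int(n), days_mature=a, wet=bool(engine.water[ci] > 0))
        for a, n in enumerate(engine.eggs_imm[ci])
        if n > 0
    ]
    if engine.eggs_mat[ci] > 0:
        batches.append(
            EggBatch(int(engine.eggs_mat[ci]), days_mature=p.egg_maturation_days)
        )
    larvae = [
        LarvalCohort(
            int(engine.ln[ci, a]), age=a, mean_weight=float(engine.lw[ci, a]),
            dev_fraction=float(engine.ldev[ci, a]),
            starving_days=int(engine.lstv[ci, a]),
        )
        for a in range(engine.ln.shape[1])
        if engine.ln[ci, a] > 0
    ]
    pupae = [
        PupalCohort(int(engine.pup[ci, d]), days=d)
        for d in range(engine.pup.shape[1])
        if engine.pup[ci, d] > 0
    ]
    return ContainerState(
        spec=spec,
        water_volume=float(engine.water[ci]),
        water_temp=float(engine.water_temp[ci]),
        food=float(engine.food[ci]),
        egg_batches=batches,
        larval_cohorts=larvae,
        pupal_cohorts=pupae,
    )


def _one_house_grid(containers: Sequence[ContainerSpec]) -> SimulationGrid:
    house = House(house_id="h0", row=0, col=0, containers=tuple(containers))
    return SimulationGrid((house,), 1, 1, 1, (1, 1))


def step_container(
    state: ContainerState,
    day,
    params: BiologyParams,
    rng: np.random.Generator,
) -> tuple[ContainerState, int, dict]:
    """Advance one container by one day.

    ``day`` is any object with ``t_min``/``t_max`` and ``rainfall`` attributes
    (or a weather-frame row with ``tmin``/``tmax``/``rain``).  Returns the new
    state, the number of adults emerging from the container, and a tally dict
    (hatched, pupated, deaths per stage, food-balance terms).
    """
    tmin = getattr(day, "t_min", None)
    if tmin is None:
        tmin, tmax, rain = day["tmin"], day["tmax"], day["rain"]
    else:
        tmax, rain = day.t_max, day.rainfall
    engine = _Engine(_one_house_grid([state.spec]), params, rng)
    engine.eggs_imm[:] = 0
    engine.eggs_mat[:] = 0
    _load_container(engine, 0, state)
    # suppress the adult/oviposition phase for a pure container step
    engine.females[:] = 0
    engine.gravid[:] = 0
    t = engine.step_day(0.5 * (tmin + tmax), rain)
    new_state = _dump_container(engine, 0, state.spec)
    tallies = {
        k: (int(v[0]) if isinstance(v, np.ndarray) else v)
        for k, v in t.items()
        if k in (
            "hatched", "pupated", "egg_deaths", "larval_deaths", "pupal_deaths",
            "food_input", "food_decay", "food_consumed", "food_cadaver",
        )
    }
    return new_state, int(t["emerged"][0]), tallies


def step_house(
    house_state: HouseState,
    day,
    params: BiologyParams,
    rng: np.random.Generator,
) -> tuple[HouseState, list[tuple[str, int]]]:
    """Advance the adult population of one house by one day.

    Applies adult survival, gonotrophic progression, and oviposition of each
    gravid female into one wet container of the house (selection probability
    proportional to the water-surface proxy V^(2/3)).  Returns the updated
    house state and the list of (container_id, eggs laid) oviposition events.
    """
    specs = [cs.spec for cs in house_state.containers]
    engine = _Engine(_one_house_grid(specs), params, rng)
    engine.eggs_imm[:] = 0
    engine.eggs_mat[:] = 0
    for ci, cs in enumerate(house_state.containers):
        _load_container(engine, ci, cs)
    # spread pre-gravid females uniformly over cycle stages (object API keeps
    # a single count; the array engine tracks per-day progress)
    G = params.gonotrophic_cycle_days
    base, rem = divmod(house_state.females_pre, G)
    engine.females[0, :] = base
    engine.females[0, :rem] += 1
    engine.gravid[0] = house_state.females_gravid
    wet = engine.water >= params.wet_fraction * engine.vol
    t = engine._adult_phase(np.zeros(engine.C, dtype=np.int64), wet)
    events = [
        (specs[ci].container_id, int(t["laid"][ci]))
        for ci in range(len(specs))
        if t["laid"][ci] > 0
    ]
    new_containers = [
        _dump_container(engine, ci, specs[ci]) for ci in range(len(specs))
    ]
    new_state = HouseState(
        house=house_state.house,
        containers=new_containers,
        females_pre=int(engine.females.sum()),
        females_gravid=int(engine.gravid.sum()),
        cumulative_pupae=house_state.cumulative_pupae,
    )
    return new_state, events


# ---------------------------------------------------------------------------
# full run

@dataclass
class SimOutput:
    """Recorded output of one simulation run (burn-in excluded)."""

    grid: SimulationGrid
    params: BiologyParams
    seed: int
    burn_in_days: int
    #: per-day totals of eggs/larvae/pupae/adults (DataFrame, len = horizon)
    totals: pd.DataFrame
    #: standing pupae per house per day, shape (horizon, n_houses)
    pupae_per_house: np.ndarray
    #: pupation events per container per day, shape (horizon, n_containers)
    pupae_produced: np.ndarray
    #: oviposition indicator per container per day, shape (horizon, n_containers)
    ovi_indicator: np.ndarray
    #: optional exact per-container-day ledger (audit mode)
    audit: dict | None = None

    @property
    def horizon(self) -> int:
        return len(self.totals)

    def per_type_pupae(self) -> pd.Series:
        """Cumulative pupal production by container type over the horizon."""
        per_cont = self.pupae_produced.sum(axis=0)
        type_idx = np.array(
            [c.type_index for h in self.grid.houses for c in h.containers]
        )
        out = np.zeros(len(CONTAINER_TYPES), dtype=np.int64)
        np.add.at(out, type_idx, per_cont)
        return pd.Series(out, index=list(CONTAINER_TYPES), name="pupae")

    def per_type_shares(self) -> pd.Series:
        counts = self.per_type_pupae()
        total = counts.sum()
        if total == 0:
            return counts.astype(float)
        return counts / total

    def write(self, out_dir) -> None:
        """Write stage totals, per-house pupae, oviposition indicator (CSV)
        and run metadata (JSON) into a directory."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.totals.to_csv(out / "stage_totals.csv", index=False)
        pd.DataFrame(self.pupae_per_house).to_csv(
            out / "pupae_per_house.csv", index=False
        )
        pd.DataFrame(self.ovi_indicator.astype(int)).to_csv(
            out / "oviposition_indicator.csv", index=False
        )
        meta = {
            "seed": self.seed,
            "burn_in_days": self.burn_in_days,
            "horizon": self.horizon,
            "n_houses": self.grid.n_houses,
            "n_containers": self.grid.n_containers,
            "F0": self.params.F0,
            "alpha": dict(self.params.alpha),
            "beta": dict(self.params.beta),
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))

    def pupae_produced_per_house(self) -> np.ndarray:
        """Total pupation events per house over the horizon (spatial-stat input)."""
        house_of = np.array(
            [hi for hi, h in enumerate(self.grid.houses) for _ in h.containers],
            dtype=np.intp,
        )
        out = np.zeros(self.grid.n_houses, dtype=np.int64)
        np.add.at(out, house_of, self.pupae_produced.sum(axis=0))
        return out


def run_simulation(
    grid: SimulationGrid,
    weather: WeatherSeries,
    params: BiologyParams,
    burn_in_days: int,
    seed: int,
    horizon: int | None = None,
    inoculum: tuple[int, int] = (10, 5),
    audit: bool = False,
) -> SimOutput:
    """Run the full grid for ``burn_in_days + horizon`` days.

    Every container starts with a small egg/larva inoculum; the first
    ``burn_in_days`` days let the population equilibrate and are excluded from
    all recorded output.  The same seed always reproduces identical output.
    """
    if horizon is None:
        horizon = len(weather) - burn_in_days
    n_days = burn_in_days + horizon
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if len(weather) < n_days:
        raise ValueError(
            f"weather series has {len(weather)} days, need {n_days} "
            "(burn-in + horizon)"
        )
    rng = np.random.default_rng(seed)
    engine = _Engine(grid, params, rng)
    engine.seed_inoculum(*inoculum)

    C, H = engine.C, engine.H
    totals = np.zeros((horizon, 4), dtype=np.int64)
    pph = np.zeros((horizon, H), dtype=np.int64)
    produced = np.zeros((horizon, C), dtype=np.int32)
    ovi = np.zeros((horizon, C), dtype=bool)
    audit_rec: dict[str, list] | None = None
    if audit:
        audit_rec = {
            k: []
            for k in (
                "food_start", "food_end", "food_input", "food_decay",
                "food_consumed", "food_cadaver",
                "eggs", "larvae", "pupae",
                "laid", "hatched", "egg_deaths", "larval_deaths",
                "pupated", "pupal_deaths", "emerged", "water_temp",
            )
        }

    tmean = weather.tmean
    rain = weather.rain
    for d in range(n_days):
        t = engine.step_day(tmean[d], rain[d])
        r = d - burn_in_days
        if r < 0 and not audit:
            continue
        if r >= 0:
            totals[r] = engine.stage_totals()
            pph[r] = engine.pupae_per_house()
            produced[r] = t["pupated"]
            ovi[r] = t["ovi"]
        if audit_rec is not None and r >= 0:
            eggs_c = engine.eggs_imm.sum(axis=1) + engine.eggs_mat
            audit_rec["eggs"].append(eggs_c)
            audit_rec["larvae"].append(engine.ln.sum(axis=1))
            audit_rec["pupae"].append(engine.pup.sum(axis=1))
            for k in (
                "food_start", "food_end", "food_input", "food_decay",
                "food_consumed", "food_cadaver", "laid", "hatched",
                "egg_deaths", "larval_deaths", "pupated", "pupal_deaths",
                "emerged", "water_temp",
            ):
                audit_rec[k].append(np.asarray(t[k]))

    totals_df = pd.DataFrame(totals, columns=["eggs", "larvae", "pupae", "adults"])
    audit_out = None
    if audit_rec is not None:
        audit_out = {k: np.stack(v) for k, v in audit_rec.items()}
    return SimOutput(
        grid=grid, params=params, seed=seed, burn_in_days=burn_in_days,
        totals=totals_df, pupae_per_house=pph, pupae_produced=produced,
        ovi_indicator=ovi, audit=audit_out,
    )
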