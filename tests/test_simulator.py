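"""Container/house daily-step biology: food balance, development, demography."""

import math

import numpy as np
import pandas as pd
import pytest

from aedespop.habitat import ContainerSpec, House, SimulationGrid
from aedespop.simulator import (
    BiologyParams,
    ContainerState,
    EggBatch,
    HouseState,
    LarvalCohort,
    _Engine,
    daily_food_input,
    run_simulation,
    step_container,
    step_house,
)
from conftest import constant_weather


def make_container(volume=20.0, type_name="large tanks", location="outside",
                   sun=0.0, fill="manual", cid="c0", hid="h0"):
    return ContainerSpec(
        container_id=cid, house_id=hid, type_name=type_name, location=location,
        sun_exposure=sun, has_lid=False, fill_method=fill, volume_l=volume,
    )


def single_container_grid(spec):
    house = House(house_id=spec.house_id, row=0, col=0, containers=(spec,))
    return SimulationGrid((house,), 1, 1, 1, (1, 1))


def day_row(tmin, tmax, rain=0.0):
    return pd.Series({"tmin": tmin, "tmax": tmax, "rain": rain, "rh": 80.0})


def immortal_params(**kw):
    base = dict(
        egg_daily_survival=1.0, dry_egg_daily_survival=1.0,
        larval_daily_survival=1.0, pupal_daily_survival=1.0,
        adult_daily_survival=1.0,
    )
    base.update(kw)
    return BiologyParams(**base)


class TestFoodInput:
    def test_reference_container_is_f0_times_volume(self):
        # large tank outside: both coefficients are 1 by normalization
        spec = make_container(volume=100.0)
        params = BiologyParams(F0=0.5)
        assert daily_food_input(spec, params) == pytest.approx(50.0)

    def test_zero_baseline_gives_zero(self):
        spec = make_container(volume=100.0)
        assert daily_food_input(spec, BiologyParams(F0=0.0)) == 0.0

    def test_direct_product(self):
        spec = make_container(volume=10.0, type_name="cans", location="inside")
        alpha = {t: 1.0 for t in BiologyParams().alpha}
        alpha["cans"] = 2.0
        params = BiologyParams(F0=0.1, alpha=alpha, beta={"outside": 1.0, "inside": 0.5})
        assert daily_food_input(spec, params) == pytest.approx(1.0)

    def test_normalization_enforced(self):
        alpha = {t: 1.0 for t in BiologyParams().alpha}
        alpha["large tanks"] = 2.0
        with pytest.raises(ValueError):
            BiologyParams(alpha=alpha)


class TestContainerStep:
    def test_food_balance_without_consumers(self, rng):
        spec = make_container()
        params = BiologyParams()
        state = ContainerState(spec=spec, water_volume=spec.volume_l, food=10.0)
        new, _, t = step_container(state, day_row(24, 30), params, rng)
        expected = (10.0 + daily_food_input(spec, params)) * (1 - params.food_decay_rate)
        assert new.food == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("tmean,expect_hatch", [(21.0, False), (23.0, True)])
    def test_hatch_blocked_below_min_water_temp(self, rng, tmean, expect_hatch):
        # mature, wet eggs hatch only at water temperature >= 22 degC
        spec = make_container(sun=0.0)
        params = immortal_params()
        state = ContainerState(
            spec=spec, water_volume=spec.volume_l, food=5.0,
            egg_batches=[EggBatch(n=50, days_mature=params.egg_maturation_days)],
        )
        new, _, t = step_container(state, day_row(tmean, tmean), params, rng)
        if expect_hatch:
            assert t["hatched"] == 50
            assert new.n_larvae == 50
        else:
            assert t["hatched"] == 0
            assert new.n_larvae == 0
            assert new.n_eggs == 50

    def test_degree_day_pupation_matches_closed_form(self, rng):
        # unlimited food, constant 27 degC water: the pupation day solves
        # dev = t * c * (T - T0) >= 1 and weight = w0 * (1 + eff*rate)^t >= wp
        params = immortal_params()
        t_dev = math.ceil(1.0 / (params.dev_rate_coeff * (27.0 - params.dev_base_temp)))
        growth = 1.0 + params.growth_efficiency * params.larval_intake_rate
        t_wt = math.ceil(
            math.log(params.pupation_weight / params.initial_larval_weight)
            / math.log(growth)
        )
        oracle_day = max(t_dev, t_wt)

        spec = make_container(sun=0.0)
        state = ContainerState(
            spec=spec, water_volume=spec.volume_l, food=1e12,
            larval_cohorts=[LarvalCohort(n=10, age=0,
                                         mean_weight=params.initial_larval_weight)],
        )
        first_pupation = None
        for day in range(1, oracle_day + 5):
            state, _, t = step_container(state, day_row(27, 27), params, rng)
            if t["pupated"] > 0 and first_pupation is None:
                first_pupation = day
        assert first_pupation == oracle_day


class TestHouseStep:
    def test_empty_house_no_events(self, rng):
        spec = make_container()
        hs = HouseState(
            house=House("h0", 0, 0, (spec,)),
            containers=[ContainerState(spec=spec, water_volume=spec.volume_l)],
        )
        new, events = step_house(hs, day_row(24, 30), BiologyParams(), rng)
        assert events == []
        assert new.females_pre == 0 and new.females_gravid == 0

    def test_single_gravid_female_forced_choice(self, rng):
        spec = make_container()
        params = immortal_params()
        hs = HouseState(
            house=House("h0", 0, 0, (spec,)),
            containers=[ContainerState(spec=spec, water_volume=spec.volume_l)],
            females_gravid=1,
        )
        new, events = step_house(hs, day_row(24, 30), params, rng)
        assert events == [(spec.container_id, params.eggs_per_batch)]
        assert new.containers[0].n_eggs == params.eggs_per_batch

    def test_site_choice_follows_surface_weighting(self, rng):
        # choice probability ~ V^(2/3): volumes 1, 8, 27 -> weights 1:4:9
        specs = [make_container(volume=v, cid=f"c{v}") for v in (1.0, 8.0, 27.0)]
        params = immortal_params()
        hs = HouseState(
            house=House("h0", 0, 0, tuple(specs)),
            containers=[ContainerState(spec=s, water_volume=s.volume_l)
                        for s in specs],
            females_gravid=5000,
        )
        _, events = step_house(hs, day_row(24, 30), params, rng)
        laid = dict(events)
        total = sum(laid.values())
        expected = np.array([1.0, 4.0, 9.0]) / 14.0
        observed = np.array(
            [laid.get(s.container_id, 0) / total for s in specs]
        )
        # binomial error at n=5000: 3 sigma < 0.02 for each component
        np.testing.assert_allclose(observed, expected, atol=0.025)


class TestDispersal:
    def test_one_step_locality(self):
        houses = tuple(
            House(f"h{r}_{c}", r, c, ()) for r in range(9) for c in range(9)
        )
        grid = SimulationGrid(houses, 9, 9, 1, (1, 1))
        params = immortal_params(dispersal_prob=0.5)
        engine = _Engine(grid, params, np.random.default_rng(5))
        center = 4 * 9 + 4
        engine.females[center, 0] = 200
        for day in range(1, 6):
            engine.step_day(25.0, 0.0)
            occupied = np.nonzero(engine.females.sum(axis=1) + engine.gravid)[0]
            rows, cols = divmod(occupied, 9)
            dist = np.abs(rows - 4) + np.abs(cols - 4)
            assert dist.max() <= day
            assert engine.females.sum() + engine.gravid.sum() == 200


class TestRunSimulation:
    def test_seeded_runs_identical(self, tiny_grid):
        wx = constant_weather(60, 24, 30)
        a = run_simulation(tiny_grid, wx, BiologyParams(), 0, seed=11, horizon=60)
        b = run_simulation(tiny_grid, wx, BiologyParams(), 0, seed=11, horizon=60)
        pd.testing.assert_frame_equal(a.totals, b.totals)
        np.testing.assert_array_equal(a.pupae_produced, b.pupae_produced)
        np.testing.assert_array_equal(a.ovi_indicator, b.ovi_indicator)

    def test_no_inoculum_stays_extinct(self, tiny_grid):
        wx = constant_weather(40, 24, 30)
        out = run_simulation(tiny_grid, wx, BiologyParams(), 0, seed=1,
                             horizon=40, inoculum=(0, 0))
        assert (out.totals.to_numpy() == 0).all()

    def test_weather_too_short_rejected(self, tiny_grid):
        wx = constant_weather(30, 24, 30)
        with pytest.raises(ValueError):
            run_simulation(tiny_grid, wx, BiologyParams(), 20, seed=1, horizon=30)

    def test_conservation_ledger_short_run(self, tiny_grid):
        wx = constant_weather(30, 24, 30)
        out = run_simulation(tiny_grid, wx, BiologyParams(), 0, seed=2,
                             horizon=30, audit=True)
        a = out.audit
        # stage bookkeeping: count(t) = count(t-1) + inflow - outflow - deaths
        eggs, larvae, pupae = a["eggs"], a["larvae"], a["pupae"]
        np.testing.assert_array_equal(
            eggs[1:] - eggs[:-1],
            a["laid"][1:] - a["hatched"][1:] - a["egg_deaths"][1:],
        )
        np.testing.assert_array_equal(
            larvae[1:] - larvae[:-1],
            a["hatched"][1:] - a["pupated"][1:] - a["larval_deaths"][1:],
        )
        np.testing.assert_array_equal(
            pupae[1:] - pupae[:-1],
            a["pupated"][1:] - a["emerged"][1:] - a["pupal_deaths"][1:],
        )
        # food balance: end = start + input - decay - consumed + cadaver
        np.testing.assert_allclose(
            a["food_end"],
            a["food_start"] + a["food_input"] - a["food_decay"]
            - a["food_consumed"] + a["food_cadaver"],
            atol=1e-9,
        )
        assert (a["food_end"] >= 0).all()

    def test_density_dependence_direction(self):
        # doubling larvae in a food-limited container lowers per-capita
        # pupation and delays development (averaged over seeds)
        spec = make_container(volume=10.0)
        grid = single_container_grid(spec)
        wx = constant_weather(60, 24, 30)
        params = BiologyParams(F0=0.05)

        def outcome(n0, seed):
            out = run_simulation(grid, wx, params, 0, seed=seed, horizon=60,
                                 inoculum=(0, n0))
            prod = out.pupae_produced[:, 0]
            total = prod.sum()
            mean_day = (
                float((np.arange(60) * prod).sum() / total) if total else 60.0
            )
            return total / n0, mean_day

        # paired seeds keep the weather/rng structure comparable across densities
        low = [outcome(20, s) for s in range(10)]
        high = [outcome(80, s) for s in range(10)]
        assert np.mean([x[0] for x in high]) < np.mean([x[0] for x in low])
        assert np.mean([x[1] for x in high]) > np.mean([x[1] for x in low])

    def test_output_writers(self, tiny_grid, tmp_path):
        wx = constant_weather(40, 24, 30)
        out = run_simulation(tiny_grid, wx, BiologyParams(), 0, seed=4, horizon=40)
        out.write(tmp_path)
        for name in ("stage_totals.csv", "pupae_per_house.csv",
                     "oviposition_indicator.csv", "run_metadata.json"):
            assert (tmp_path / name).exists()

    def test_no_secular_trend_under_constant_climate(self, tiny_grid):
        wx = constant_weather(1095, 24, 30, rain=5.0)
        out = run_simulation(tiny_grid, wx, BiologyParams(), 365, seed=3,
                             horizon=730)
        p = out.totals["pupae"].to_numpy()
        y2, y3 = p[:365].mean(), p[365:].mean()
        assert y2 > 0
        assert 0.5 < y3 / y2 < 2.0
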