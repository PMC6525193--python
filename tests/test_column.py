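"""Reactive transport: tracer physics, operator splitting and mass balance."""

import numpy as np
import pandas as pd
import pytest

from soursim.batch import KineticParams, ReactionSystem, simulate_batch
from soursim.column import (
    ColumnGrid,
    PortSpec,
    Schedule,
    ScheduleError,
    constant_schedule,
    estimate_influent_sulfate,
    reaction_step,
    run_column,
    transport_step,
)
from soursim.synth import default_column_truth


@pytest.fixture(scope="module")
def grid():
    return ColumnGrid()


@pytest.fixture(scope="module")
def column_truth():
    return default_column_truth()


@pytest.fixture(scope="module")
def column_network(communities, column_truth):
    return [communities[n] for n in column_truth.scenario.communities()]


def tracer_breakthrough(grid, flow_ml_h=9.0, dt_days=0.01, horizon_days=3.0):
    conc = np.zeros((grid.n_cells, 1))
    c_in = np.array([1.0])
    t, rows = 0.0, []
    while t < horizon_days * 86400.0:
        conc, _, _ = transport_step(conc, grid, flow_ml_h, c_in, dt_days * 86400.0)
        t += dt_days * 86400.0
        rows.append((t / 86400.0, conc[5:7, 0].mean(), conc[61:63, 0].mean()))
    return np.array(rows)


class TestTransport:
    def test_no_flow_no_dispersion_is_identity(self):
        grid = ColumnGrid(molecular_diffusion_m2_s=0.0)
        conc = np.linspace(0, 1, grid.n_cells)[:, None]
        out, influx, outflux = transport_step(conc, grid, 0.0, np.array([5.0]), 3600.0)
        assert np.array_equal(out, conc)
        assert influx[0] == outflux[0] == 0.0

    def test_tracer_mass_balance(self, grid):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0, 2.0, size=(grid.n_cells, 1))
        stored0 = conc.sum() * grid.cell_pore_volume_l
        c_in = np.array([1.5])
        influx = outflux = 0.0
        for _ in range(200):
            conc, fin, fout = transport_step(conc, grid, 9.0, c_in, 0.02 * 86400.0)
            influx += fin[0]
            outflux += fout[0]
        stored = conc.sum() * grid.cell_pore_volume_l
        residual = stored0 + influx - outflux - stored
        assert abs(residual) / influx < 1e-10

    def test_interport_travel_time_analytic(self, grid):
        """At 9 ml/h and porosity 0.375 the 56 cm between the first and last
        ports takes about 1.55 days to traverse."""
        assert grid.travel_time_days(56.0, 9.0) == pytest.approx(1.55, rel=0.02)

    def test_interport_travel_time_simulated(self, grid):
        rows = tracer_breakthrough(grid)
        t1 = np.interp(0.5, rows[:, 1], rows[:, 0])
        t5 = np.interp(0.5, rows[:, 2], rows[:, 0])
        assert t5 - t1 == pytest.approx(1.55, rel=0.02)

    def test_grid_refinement_changes_breakthrough_little(self, grid):
        fine = ColumnGrid(n_cells=128)
        rows_c = tracer_breakthrough(grid, dt_days=0.005)
        conc = np.zeros((fine.n_cells, 1))
        rows_f = []
        t = 0.0
        while t < 3.0 * 86400.0:
            conc, _, _ = transport_step(conc, fine, 9.0, np.array([1.0]), 0.005 * 86400.0)
            t += 0.005 * 86400.0
            rows_f.append((t / 86400.0, conc[122:126, 0].mean()))
        rows_f = np.array(rows_f)
        t5_c = np.interp(0.5, rows_c[:, 2], rows_c[:, 0])
        t5_f = np.interp(0.5, rows_f[:, 1], rows_f[:, 0])
        assert abs(t5_f - t5_c) / t5_c < 0.02


class TestReactionStep:
    def test_zero_dt_is_identity(self, column_network, column_truth):
        sysm = ReactionSystem(column_network, column_truth.params, grow_biomass=True)
        state = np.tile(sysm.initial_state({"sulfate": 1e-2, "lactate": 2e-2}), (4, 1))
        out = reaction_step(state, sysm, 0.0)
        assert np.array_equal(out, state)

    def test_single_cell_equals_batch_simulation(self, column_network, column_truth):
        """The reaction operator on one cell is the batch model."""
        sysm = ReactionSystem(column_network, column_truth.params, grow_biomass=True)
        init = {"sulfate": 1e-2, "lactate": 2.5e-2, "nitrate": 5e-3, "ammonium": 1e-3}
        state = sysm.initial_state(init)[None, :]
        dt = 0.5 * 86400.0
        stepped = reaction_step(state, sysm, dt, rtol=1e-8, atol=1e-10)[0]
        df = simulate_batch(
            column_network, column_truth.params, init, np.array([0.0, dt]),
            grow_biomass=True, rtol=1e-8, atol=1e-10,
        )
        assert np.allclose(stepped, df.iloc[-1].to_numpy(), rtol=1e-8, atol=1e-10)

    def test_per_cell_sulfur_conservation(self, column_network, column_truth):
        sysm = ReactionSystem(column_network, column_truth.params, grow_biomass=True)
        rng = np.random.default_rng(1)
        state = np.stack(
            [
                sysm.initial_state(
                    {
                        "sulfate": rng.uniform(1e-3, 1e-2),
                        "sulfide": rng.uniform(0, 5e-3),
                        "lactate": 2.5e-2,
                        "nitrate": rng.uniform(0, 5e-3),
                        "ammonium": 1e-3,
                    }
                )
                for _ in range(5)
            ]
        )
        out = reaction_step(state, sysm, 86400.0)
        idx = [sysm.sp_index[s] for s in ("sulfate", "sulfide") if s in sysm.sp_index]
        before = state[:, idx].sum(axis=1)
        after = out[:, idx].sum(axis=1)
        assert np.allclose(before, after, atol=1e-9)


class TestSchedules:
    def test_times_must_increase_from_zero(self):
        with pytest.raises(ScheduleError):
            Schedule([(1.0, 1.0, {})])
        with pytest.raises(ScheduleError):
            Schedule([(0.0, 1.0, {}), (0.0, 2.0, {})])

    def test_negative_values_rejected(self):
        with pytest.raises(ScheduleError):
            Schedule([(0.0, -1.0, {})])
        with pytest.raises(ScheduleError):
            Schedule([(0.0, 1.0, {"nitrate": -2.0})])

    def test_piecewise_lookup(self):
        s = Schedule([(0.0, 1.0, {"nitrate": 0.0}), (5.0, 2.0, {"nitrate": 2.5})])
        assert s.at(4.99) == (1.0, {"nitrate": 0.0})
        assert s.at(5.0) == (2.0, {"nitrate": 2.5})


class TestRunColumn:
    def test_zero_biomass_effluent_equals_influent(self, column_network, grid):
        """With no biomass the column is a tracer column: after a few pore
        volumes the last port sits at the influent composition."""
        params = {
            n: KineticParams(1e-5, 1e-4, 1e-4, I=1e-4 if n == "SRB" else None, X0=0.0)
            for n in ("SRB", "NRSOB1", "NRSOB2")
        }
        sched = constant_schedule(9.0, {"sulfate": 10.0, "lactate": 25.0})
        res = run_column(
            grid, column_network, params, sched,
            horizon_days=8.0, dt_days=0.02, skip_startup=True,
        )
        ps = res.port_series
        last = ps[(ps.port == 5) & (ps.time_d == ps.time_d.max())]
        assert last[last.species == "sulfate"].value_mM.iloc[0] == pytest.approx(10.0, rel=1e-3)
        assert last[last.species == "lactate"].value_mM.iloc[0] == pytest.approx(25.0, rel=1e-3)

    def test_srb_only_complete_conversion(self, communities, grid):
        """With ample residence time nearly all injected sulfate is reduced
        before the last port: port-5 sulfide approaches the influent sulfate."""
        params = {"SRB": KineticParams(2e-5, 1e-4, 1e-4, I=1e-4, b=1e-6, X0=10.0)}
        sched = constant_schedule(4.0, {"sulfate": 10.0, "lactate": 25.0, "ammonium": 2.0})
        res = run_column(
            grid, [communities["SRB"]], params, sched,
            horizon_days=12.0, dt_days=0.02,
        )
        ps = res.port_series
        last = ps[(ps.port == 5) & (ps.time_d == ps.time_d.max())]
        sulfide = last[last.species == "sulfide"].value_mM.iloc[0]
        assert sulfide == pytest.approx(10.0, rel=0.05)

    def test_global_sulfur_mass_balance(self, column_network, column_truth, grid):
        sched = Schedule(
            [
                (0.0, 9.0, {"sulfate": 10.0, "lactate": 25.0, "ammonium": 1.0}),
                (3.0, 9.0, {"sulfate": 10.0, "lactate": 25.0, "ammonium": 1.0, "nitrate": 8.0}),
            ]
        )
        res = run_column(
            grid, column_network, column_truth.params, sched,
            horizon_days=6.0, dt_days=0.02,
        )
        led = res.ledger
        vp = grid.cell_pore_volume_l
        fin = {sp: float(res.final_state[:, i].sum() * vp) for sp, i in res.system.sp_index.items()}
        # species-level closure with the reaction ledger
        for sp in ("sulfate", "sulfide", "nitrate", "lactate"):
            assert abs(led.closure(fin, sp)) < 1e-6
        # element-level: total S in/out/stored closes without the reaction term
        s_in = led.influx["sulfate"] + led.influx["sulfide"]
        s_out = led.outflux["sulfate"] + led.outflux["sulfide"]
        s_0 = led.initial_storage["sulfate"] + led.initial_storage["sulfide"]
        s_f = fin["sulfate"] + fin["sulfide"]
        assert abs(s_0 + s_in - s_out - s_f) / max(s_in, 1e-12) < 1e-6

    def test_biomass_never_advects(self, column_network, column_truth, grid):
        """Transport leaves biomass untouched; only growth/decay move it."""
        sched = constant_schedule(9.0, {"sulfate": 10.0, "lactate": 25.0, "ammonium": 1.0})
        res = run_column(
            grid, column_network, column_truth.params, sched,
            horizon_days=2.0, dt_days=0.05, skip_startup=True,
        )
        sysm = res.system
        # decay-free check is indirect: rerun with zero-rate params and see
        # the biomass profile stay exactly at its initial value under flow
        frozen = {
            n: KineticParams(0.0, 1e-4, 1e-4, I=p.I, b=0.0, X0=p.X0)
            for n, p in column_truth.params.items()
        }
        res2 = run_column(
            grid, column_network, frozen, sched,
            horizon_days=2.0, dt_days=0.05, skip_startup=True,
        )
        x0 = frozen["SRB"].x0_mol_per_l
        xcols = res2.final_state[:, sysm.n_dyn :]
        assert np.allclose(xcols, x0, rtol=1e-12)

    def test_splitting_convergence(self, column_network, column_truth, grid):
        """Halving the global splitting step changes port series by < 0.5%."""
        sched = constant_schedule(9.0, {"sulfate": 10.0, "lactate": 25.0, "ammonium": 1.0, "nitrate": 5.0})
        kw = dict(horizon_days=3.0, skip_startup=True)
        a = run_column(grid, column_network, column_truth.params, sched, dt_days=0.02, **kw)
        b = run_column(grid, column_network, column_truth.params, sched, dt_days=0.01, **kw)
        pa = a.port_series.set_index(["time_d", "port", "species"]).value_mM
        pb = b.port_series.set_index(["time_d", "port", "species"]).value_mM
        joined = pd.concat([pa, pb], axis=1, keys=["a", "b"]).dropna()
        scale = joined.abs().max().max()
        assert (joined["a"] - joined["b"]).abs().max().max() / scale < 0.005


class TestInfluentEstimate:
    def _series(self, sulf, h2s):
        t = np.arange(len(sulf), dtype=float)
        rows = [(ti, 5, "sulfate", s) for ti, s in zip(t, sulf)]
        rows += [(ti, 5, "sulfide", h) for ti, h in zip(t, h2s)]
        return pd.DataFrame(rows, columns=["time_d", "port", "species", "value_mM"])

    def test_constant_split(self):
        ps = self._series([3.0] * 10, [7.0] * 10)
        assert estimate_influent_sulfate(ps, (0, 9)) == pytest.approx(10.0)

    def test_pure_sulfate(self):
        ps = self._series([4.0] * 5, [0.0] * 5)
        assert estimate_influent_sulfate(ps, (0, 4)) == pytest.approx(4.0)

    def test_noise_averages_out(self):
        rng = np.random.default_rng(42)
        n = 50
        sulf = 3.0 + 0.1 * rng.standard_normal(n)
        h2s = 7.0 + 0.1 * rng.standard_normal(n)
        est = estimate_influent_sulfate(self._series(sulf, h2s), (0, n - 1))
        sd = 0.1 * np.sqrt(2)
        assert abs(est - 10.0) < 3 * sd / np.sqrt(n)

    def test_empty_window_rejected(self):
        ps = self._series([1.0], [1.0])
        with pytest.raises(ValueError):
            estimate_influent_sulfate(ps, (5.0, 6.0))
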