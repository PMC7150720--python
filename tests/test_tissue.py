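"""Unit tests for monodomain tissue conduction, activation maps and
reentry machinery."""

import numpy as np
import pytest

from cardiolab import ionic_cell as ic
from cardiolab import protocols as pr
from cardiolab import tissue as ts
from cardiolab.exceptions import (
    ConfigurationError,
    InsufficientReentryError,
    PropagationFailure,
)


class TestGridsAndStability:
    def test_stability_preflight(self):
        grid = ts.make_cable("WT", length=0.5, D=0.01)
        with pytest.raises(ConfigurationError):
            ts.run_tissue(grid, 5.0,
                          [ts.Stimulus(0.0, ts._edge_mask(grid, 0.05))],
                          dt=0.1)

    def test_transmural_layout(self):
        grid = ts.make_cable("WT", length=1.5, cell_types="transmural")
        x = np.arange(grid.n_nodes) * grid.dx
        assert set(np.unique(grid.cell_types)) == {0, 1, 2}
        assert np.all(grid.cell_types[x < 0.2] == 0)     # endo shell
        assert np.all(grid.cell_types[x > 1.3] == 2)     # epi shell

    def test_uniform_state_stays_uniform(self):
        """Diffusion of a spatially constant state is zero (no-flux):
        a homogeneous unstimulated cable stays exactly uniform."""
        grid = ts.make_cable("WT", length=0.5, cell_types="epi")
        for _ in range(200):
            ts.step_tissue(grid)
        assert np.ptp(grid.Y[0]) == 0.0


class TestDecoupledLimit:
    def test_zero_diffusion_matches_single_cell(self):
        """With D = 0 every tissue node reproduces the single-cell
        trajectory exactly."""
        grid = ts.make_cable("E299V", length=0.1, D=0.0, cell_types="epi")
        n = grid.n_nodes
        run = ts.run_tissue(grid, 120.0,
                            [ts.Stimulus(0.0, np.ones(n, dtype=bool))],
                            rec_interval=0.5)
        state, params = ic.make_cell("epi", "E299V")
        vs = []
        for k in range(6000):
            istim = -52.0 if k * 0.02 < 1.0 else 0.0
            state = ic.step_cell(state, params, "E299V", I_stim=istim)
            if (k + 1) % 25 == 0:
                vs.append(state.V)
        diff = np.abs(run.V[1:len(vs) + 1, n // 2] - np.array(vs))
        assert diff.max() < 1e-6

    def test_zero_diffusion_no_propagation(self):
        """D = 0 with a local stimulus: the wave cannot travel."""
        grid = ts.make_cable("WT", length=1.0, D=0.0, cell_types="epi")
        run = ts.run_tissue(grid, 50.0,
                            [ts.Stimulus(0.0, ts._edge_mask(grid, 0.1),
                                         duration=2.0)], rec_interval=0.5)
        with pytest.raises(PropagationFailure):
            ts.measure_cv(run)


class TestConductionVelocity:
    def test_cv_sqrt_d_scaling(self, calibrated_D):
        """CV scales with sqrt(D): quadrupling D doubles CV within 5%
        (on a refined grid where discretization error is small)."""
        cvs = {}
        for fac in (1.0, 4.0):
            g = ts.make_cable("WT", length=2.0, dx=0.0125,
                              D=fac * calibrated_D, cell_types="epi")
            r = ts.run_tissue(g, 40.0,
                              [ts.Stimulus(0.0, ts._edge_mask(g, 0.1),
                                           duration=2.0)],
                              dt=0.01, rec_interval=0.1)
            cvs[fac] = ts.measure_cv(r)
        assert cvs[4.0] / cvs[1.0] == pytest.approx(2.0, rel=0.05)

    def test_cv_grid_convergence(self, calibrated_D):
        """Planar CV converges under dx halving (< 2% change between the
        two finest grids)."""
        cvs = {}
        for dx, dt in ((0.00625, 0.002), (0.003125, 0.002)):
            g = ts.make_cable("WT", length=1.2, dx=dx, D=calibrated_D,
                              cell_types="epi")
            r = ts.run_tissue(g, 30.0,
                              [ts.Stimulus(0.0, ts._edge_mask(g, 0.1),
                                           duration=2.0)],
                              dt=dt, rec_interval=0.1)
            cvs[dx] = ts.measure_cv(r)
        rel = abs(cvs[0.003125] - cvs[0.00625]) / cvs[0.003125]
        assert rel < 0.02


class TestActivationMaps:
    def test_synthetic_maps_exact(self):
        eat = np.array([5.0, 10.0, 20.0, 15.0])
        edt = np.array([200.0, 240.0, 260.0, 230.0])
        maps = ts.maps_from_arrays(eat, edt)
        assert maps.min_eat == 5.0
        assert maps.max_eat == 20.0
        assert maps.max_edt == 260.0
        assert maps.qrs_surrogate == 15.0
        assert maps.qt_surrogate == 255.0

    def test_edt_before_eat_rejected(self):
        with pytest.raises(ConfigurationError):
            ts.maps_from_arrays(np.array([10.0]), np.array([5.0]))

    def test_single_node_qt_equals_apd(self):
        """Degenerate one-node geometry: the QT surrogate reduces to the
        cell's own APD (threshold-to-threshold timing differences only)."""
        grid = ts.make_cable("WT_E299V", length=0.0, D=0.0,
                             cell_types="endo")
        assert grid.n_nodes == 1
        run = ts.run_tissue(grid, 400.0,
                            [ts.Stimulus(0.0, np.ones(1, dtype=bool))],
                            rec_interval=0.1)
        maps = ts.activation_maps(run)
        tr = pr.pace_to_steady_state("endo", "WT_E299V", n_beats=2,
                                     record_beats=2)
        apd = pr.measure_apd(tr, 0)
        assert maps.qt_surrogate == pytest.approx(apd, abs=3.0)

    def test_transmural_qt_ordering(self, calibrated_D):
        """Repolarization-span surrogate shortens with mutation dose on the
        same transmural cable (QT ordering WT > WT/E299V > E299V)."""
        qts = {}
        for cond in ic.CONDITIONS:
            grid = ts.make_cable(cond, length=1.5, D=calibrated_D)
            stim = ts.Stimulus(0.0, ts.endocardial_edge_mask(grid),
                               duration=2.0)
            run = ts.run_tissue(grid, 600.0, [stim], rec_interval=0.5)
            maps = ts.activation_maps(run)
            qts[cond] = maps.qt_surrogate
            assert np.all(maps.edt[~np.isnan(maps.edt)] >=
                          maps.eat[~np.isnan(maps.edt)])
        assert qts["WT"] > qts["WT_E299V"] > qts["E299V"]


class TestReentry:
    def test_late_s2_no_reentry(self, calibrated_D):
        """An S2 delivered after full repolarization everywhere launches a
        plain wave, not reentry."""
        sheet = ts.make_sheet("E299V", Lx=1.5, Ly=1.5, D=calibrated_D)
        run = ts.induce_spiral(sheet, s2_time=400.0, duration=800.0,
                               persist_ms=300.0)
        assert not run.reentrant

    def test_s2_region_confined(self, calibrated_D):
        """Right after delivery the S2 has depolarized its target quadrant
        but not the distant corner (the wavefront needs ~8 ms to get
        there at 70 cm/s)."""
        sheet = ts.make_sheet("E299V", Lx=1.5, Ly=1.5, D=calibrated_D)
        ny, nx = sheet.shape
        run = ts.induce_spiral(sheet, s2_time=400.0, duration=420.0,
                               persist_ms=300.0)
        frame = run.V[np.searchsorted(run.t, 402.0)].reshape(ny, nx)
        q_target = frame[ny // 2 + 2:, :nx // 2 - 2]
        far_corner = frame[:ny // 4, 3 * nx // 4:]
        assert q_target.max() > -40.0
        assert far_corner.max() < -60.0

    def test_ring_reentry_sustained(self, ring_runs):
        """The unidirectional ring wave persists for the whole run in all
        three conditions (wavelength < circumference)."""
        for cond, run in ring_runs.items():
            assert run.reentrant, cond

    def test_wavelength_estimators_agree(self, ring_runs):
        """Excited-arc and CV x APD wavelength estimates agree within 15%
        on a stable circulating wave."""
        for cond, run in ring_runs.items():
            wl = ts.reentry_wavelength(run)
            rel = abs(wl["arc"] - wl["cv_apd"]) / wl["cv_apd"]
            assert rel < 0.15, (cond, wl)

    def test_wavelength_requires_sustained_run(self, calibrated_D):
        grid = ts.make_cable("WT", length=0.5, D=calibrated_D)
        run = ts.run_tissue(grid, 30.0,
                            [ts.Stimulus(0.0, ts._edge_mask(grid, 0.05))],
                            rec_interval=1.0)
        with pytest.raises(InsufficientReentryError):
            ts.reentry_wavelength(run)
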