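"""Scan protocols, ultrasensitivity metrics, contours, hysteresis screen."""

import numpy as np
import pytest

import il6loop as il
from il6loop.analysis import ScanResult, ultrasensitivity
from conftest import hill_scan


class TestScanE2F1:
    def test_flat_without_induction(self, config):
        cell = il.cell_defaults("melanoma", config)
        cell = cell.replace(params=cell.params.replace(k1=0.0))
        system = il.SystemSpec(cells=(cell,), shared_medium=False)
        scan = il.scan_E2F1(system, n=7)
        assert np.ptp(scan.response) <= 1e-9 * max(scan.response.max(), 1.0)

    def test_monotone_increasing_under_defaults(self, melanoma_scan):
        r = melanoma_scan.response
        assert np.all(np.diff(r) >= -1e-9 * r.max())
        assert r[-1] > r[0]

    def test_each_point_is_an_independent_simulation(self, melanoma_system,
                                                     melanoma_scan):
        # oracle: re-run single simulations at a few grid levels directly
        for i in (0, 13, 27, 40):
            level = melanoma_scan.grid[i]
            cell = melanoma_system.cells[0].replace(E2F1=float(level))
            system = il.SystemSpec(cells=(cell,), shared_medium=False)
            traj = il.integrate(system, t_end=100.0, n_out=51)
            assert il.readout_IL6(traj, 100.0) == pytest.approx(
                melanoma_scan.response[i], rel=1e-9)

    def test_order_invariance(self, melanoma_system):
        # computing levels in shuffled order then sorting matches the scan
        scan = il.scan_E2F1(melanoma_system, lo=0.5, hi=50.0, n=7)
        rng = np.random.default_rng(0)
        order = rng.permutation(7)
        shuffled = {}
        for i in order:
            level = scan.grid[i]
            cell = melanoma_system.cells[0].replace(E2F1=float(level))
            system = il.SystemSpec(cells=(cell,), shared_medium=False)
            traj = il.integrate(system, t_end=100.0, n_out=51)
            shuffled[i] = il.readout_IL6(traj, 100.0)
        recomposed = np.array([shuffled[i] for i in range(7)])
        assert np.allclose(recomposed, scan.response, rtol=1e-12)

    def test_invalid_grid(self, melanoma_system):
        with pytest.raises(ValueError):
            il.scan_E2F1(melanoma_system, lo=1.0, hi=0.1)
        with pytest.raises(ValueError):
            il.scan_E2F1(melanoma_system, n=1)


class TestScan2D:
    def test_monotone_along_both_axes(self, scan2d):
        R = scan2d.response
        assert np.all(np.diff(R, axis=0) >= -1e-9 * R.max())
        assert np.all(np.diff(R, axis=1) >= -1e-9 * R.max())

    def test_maximum_at_high_high_corner(self, scan2d):
        assert scan2d.response[-1, -1] == scan2d.response.max()

    def test_and_gate_margins_lowest(self, config):
        # with no basal transcription (activation seeded by an exogenous
        # IL-6 trickle instead) the low-E2F1 column and low-STAT3 row are
        # the two weakest margins of the response matrix
        cell = il.cell_defaults("melanoma", config)
        cell = cell.replace(params=cell.params.replace(k0=0.0))
        system = il.SystemSpec(cells=(cell,), shared_medium=False,
                               il6_infusion=0.05)
        s2 = il.scan_E2F1_STAT3(system, n=5)
        R = s2.response
        # elementwise: no other row is weaker than the low-STAT3 row and no
        # other column weaker than the low-E2F1 column
        assert np.all(R[0][None, :] <= R + 1e-12)
        assert np.all(R[:, 0][:, None] <= R + 1e-12)

    def test_entries_match_independent_simulation(self, melanoma_system, scan2d):
        for (j, i) in ((0, 0), (12, 20), (24, 24)):
            cell = melanoma_system.cells[0].replace(
                E2F1=float(scan2d.grid_E2F1[i]), S_tot=float(scan2d.grid_STAT3[j]))
            system = il.SystemSpec(cells=(cell,), shared_medium=False)
            traj = il.integrate(system, t_end=100.0, n_out=51)
            assert il.readout_IL6(traj, 100.0) == pytest.approx(
                scan2d.response[j, i], rel=1e-9)


class TestIsoResponseContour:
    def test_minimum_level_covers_all_rows_at_lowest_e2f1(self, scan2d):
        contour = il.iso_response_contour(scan2d, float(scan2d.response.min()))
        assert len(contour) == len(scan2d.grid_STAT3)
        assert all(e == pytest.approx(scan2d.grid_E2F1[0]) for e, _ in contour)

    def test_level_above_range_rejected(self, scan2d):
        with pytest.raises(ValueError):
            il.iso_response_contour(scan2d, float(scan2d.response.max()) * 1.01)

    def test_bracketing(self, scan2d):
        # oracle: each contour point sits between the bracketing grid points
        R = scan2d.response
        level = float(R.min() + 0.5 * (R.max() - R.min()))
        contour = il.iso_response_contour(scan2d, level)
        for e2f1, s_tot in contour:
            j = int(np.argmin(np.abs(scan2d.grid_STAT3 - s_tot)))
            row = R[j]
            above = np.nonzero(row >= level)[0]
            i = int(above[0])
            if i > 0:
                assert scan2d.grid_E2F1[i - 1] <= e2f1 <= scan2d.grid_E2F1[i]
                assert row[i - 1] < level <= row[i]

    def test_trade_off_curve_nonincreasing(self, scan2d):
        R = scan2d.response
        level = float(R.min() + 0.5 * (R.max() - R.min()))
        contour = il.iso_response_contour(scan2d, level)
        e = np.array([p[0] for p in contour])
        assert np.all(np.diff(e) <= 1e-9)


class TestUltrasensitivity:
    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0])
    def test_recovers_hill_exponent(self, h):
        # closed form: EC90/EC10 = 81^(1/h) exactly for a Hill curve
        metrics = ultrasensitivity(hill_scan(h))
        assert metrics.n_H == pytest.approx(h, rel=0.05)
        assert metrics.EC10 <= metrics.EC50 <= metrics.EC90

    def test_classification_bands(self):
        assert ultrasensitivity(hill_scan(1.0)).classification == "graded"
        assert ultrasensitivity(hill_scan(2.0)).classification == "ultrasensitive"
        assert ultrasensitivity(hill_scan(5.0)).classification == "switch-like"

    def test_cd4_autocrine_response_is_ultrasensitive(self, cd4_scan):
        metrics = ultrasensitivity(cd4_scan)
        assert metrics.n_H > 1.2

    def test_flat_scan_rejected(self):
        scan = ScanResult(knob="E2F1", grid=np.geomspace(0.1, 10, 11),
                          response=np.full(11, 3.0), protocol={})
        with pytest.raises(ValueError, match="5-fold"):
            ultrasensitivity(scan)

    def test_non_monotone_scan_rejected(self):
        grid = np.geomspace(0.1, 10, 11)
        resp = np.linspace(1, 10, 11)
        resp[5] = 0.2
        scan = ScanResult(knob="E2F1", grid=grid, response=resp, protocol={})
        with pytest.raises(ValueError, match="monotone"):
            ultrasensitivity(scan)


class TestBistabilityScreen:
    def test_weak_linear_feedback_has_no_hysteresis(self, config):
        # h_E = h_S = 1 with weak phosphorylation: monostable everywhere
        cell = il.cell_defaults("melanoma", config)
        cell = cell.replace(params=cell.params.replace(h_S=1.0, k_p=0.05, k0=0.01))
        system = il.SystemSpec(cells=(cell,), shared_medium=False)
        report = il.bistability_screen(system, np.geomspace(0.1, 10, 7))
        assert report.hysteresis_window == []
        assert not report.bistable

    def test_window_brackets_two_equilibria(self, melanoma_system):
        # the default melanoma instance switches: inside a detected window an
        # independent multi-start root search finds at least two equilibria
        from scipy.optimize import root
        from il6loop.model import rhs_vector

        grid = np.geomspace(0.05, 2.0, 9)
        report = il.bistability_screen(melanoma_system, grid)
        assert report.bistable  # the shipped melanoma instance switches here
        level = report.hysteresis_window[len(report.hysteresis_window) // 2]
        cell = melanoma_system.cells[0].replace(E2F1=float(level))
        system = il.SystemSpec(cells=(cell,), shared_medium=False)
        found = []
        rng = np.random.default_rng(7)
        for _ in range(30):
            y0 = rng.uniform(0, 1, 4) * np.array([20, cell.S_tot, cell.R_tot, 40])
            sol = root(lambda y: rhs_vector(0.0, y, system), y0, method="hybr")
            if sol.success and np.all(sol.x > -1e-9):
                if not any(np.allclose(sol.x, f, rtol=1e-3, atol=1e-6) for f in found):
                    found.append(sol.x)
        assert len(found) >= 2

    def test_reports_absolute_difference_only(self, melanoma_system):
        grid = np.geomspace(0.05, 2.0, 5)
        report = il.bistability_screen(melanoma_system, grid)
        assert report.up_response.shape == grid.shape
        assert report.down_response.shape == grid.shape

    def test_invalid_grid(self, melanoma_system):
        with pytest.raises(ValueError):
            il.bistability_screen(melanoma_system, [1.0, 0.5, 2.0])
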