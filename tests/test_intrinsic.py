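"""Intrinsic-property extraction: closed-form recovery and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from neuropheno import intrinsic as intr
from neuropheno import synthetic as syn


def make_rc_sweep(fs=20000.0, rmp=-60.0, deflect=-20.0, tau_s=0.02,
                  step_start=0.2, step_dur=0.5, total=1.0):
    """Pure RC charging response, no sag, no noise."""
    n = int(total * fs)
    v = np.full(n, rmp)
    i0 = int(step_start * fs)
    n_step = int(step_dur * fs)
    t = np.arange(n_step) / fs
    v[i0:i0 + n_step] += deflect * (1 - np.exp(-t / tau_s))
    v[i0 + n_step:] += deflect * np.exp(-np.arange(n - i0 - n_step) / fs / tau_s)
    return v


class TestRmp:
    def test_constant_trace(self):
        v = np.full(20000, -60.0)
        assert intr.measure_rmp(v, 20000.0, step_start=0.5) == -60.0

    def test_noisy_baseline_clt(self, rng):
        v = -60.0 + rng.normal(0, 1.0, 20000)
        est = intr.measure_rmp(v, 20000.0, step_start=0.5, baseline_s=0.5)
        sem = 1.0 / np.sqrt(10000)
        assert abs(est + 60.0) < 3 * sem

    def test_window_before_start_rejected(self):
        v = np.zeros(1000)
        with pytest.raises(ValueError):
            intr.measure_rmp(v, 20000.0, step_start=0.001, baseline_s=0.1)


class TestInputResistance:
    @pytest.mark.parametrize("deflect, expected", [(-31.0, 310.0), (-10.0, 100.0)])
    def test_ohms_law(self, deflect, expected):
        v = make_rc_sweep(deflect=deflect)
        r = intr.input_resistance(v, 20000.0, -100.0, 0.2, 0.5)
        assert r == pytest.approx(expected, rel=1e-3)

    def test_offset_invariance(self):
        v = make_rc_sweep()
        r1 = intr.input_resistance(v, 20000.0, -100.0, 0.2, 0.5)
        r2 = intr.input_resistance(v + 17.3, 20000.0, -100.0, 0.2, 0.5)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError):
            intr.input_resistance(make_rc_sweep(), 20000.0, 0.0, 0.2, 0.5)

    def test_programmed_round_trip(self):
        t = syn.GroundTruth(cell=syn.CellParams(r_n_mohm=250.0))
        ss = syn.gen_step_sweeps(t, noise_sd=0.0)
        r = intr.input_resistance(ss.sweep_at(-100.0), ss.fs, -100.0,
                                  ss.protocol.step_start, ss.protocol.step_dur)
        assert r == pytest.approx(250.0, rel=0.01)


class TestTauFit:
    def test_closed_form_recovery(self):
        v = make_rc_sweep(tau_s=0.020)
        assert intr.fit_tau(v, 20000.0, 0.2) == pytest.approx(20.0, rel=0.01)

    def test_noisy_recovery_within_five_percent(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            v = make_rc_sweep(tau_s=0.035) + rng.normal(0, 0.5, 20000)
            errs.append(abs(intr.fit_tau(v, 20000.0, 0.2) - 35.0) / 35.0)
        assert np.max(errs) < 0.05

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            intr.fit_tau(np.full(20000, -60.0), 20000.0, 0.2)


class TestSag:
    def test_peak_minus_steady_state(self):
        # square construction: drop to −90 then relax to a −80 plateau
        fs = 20000.0
        v = np.full(int(1.0 * fs), -60.0)
        i0, i1 = int(0.2 * fs), int(0.7 * fs)
        v[i0:i1] = -80.0
        v[i0:i0 + 400] = -90.0
        sag_v, sag_pct = intr.sag_measures(v, fs, 0.2, 0.5)
        assert sag_v == pytest.approx(-10.0)
        assert sag_pct == pytest.approx(100 * 10.0 / 30.0)

    def test_no_sag_component(self):
        v = make_rc_sweep()
        sag_v, sag_pct = intr.sag_measures(v, 20000.0, 0.2, 0.5)
        assert sag_v == pytest.approx(0.0, abs=1e-9)
        assert sag_pct == pytest.approx(0.0, abs=1e-6)

    def test_depolarizing_rejected(self):
        v = make_rc_sweep(deflect=+20.0)
        with pytest.raises(ValueError):
            intr.sag_measures(v, 20000.0, 0.2, 0.5)

    def test_programmed_round_trip(self):
        t = syn.GroundTruth(cell=syn.CellParams(sag_mv=5.0))
        ss = syn.gen_step_sweeps(t, noise_sd=0.0)
        sag_v, _ = intr.sag_measures(ss.sweep_at(-100.0), ss.fs,
                                     ss.protocol.step_start, ss.protocol.step_dur)
        assert sag_v == pytest.approx(-5.0, abs=0.05)


class TestSpikes:
    def test_subthreshold_empty(self):
        assert intr.detect_spikes(make_rc_sweep(), 20000.0).size == 0

    def test_programmed_spikes_recovered(self):
        fs = 20000.0
        v = np.full(20000, -60.0)
        times = [0.1, 0.2, 0.35, 0.5, 0.8]
        for t in times:
            v[int(t * fs):int(t * fs) + 10] = 20.0
        det = intr.detect_spikes(v, fs)
        assert det.size == 5
        assert np.allclose(det, times, atol=1.0 / fs)

    def test_refractory_merges_close_crossings(self):
        fs = 20000.0
        v = np.full(4000, -60.0)
        v[1000:1005] = 20.0
        v[1020:1025] = 20.0  # 1 ms later
        det = intr.detect_spikes(v, fs, refractory_ms=2.0)
        assert det.size == 1


class TestAccommodation:
    def test_printed_formula(self):
        # ISIs 10, 20, 40 ms then 50 ms to step end: 50/10 = 5
        spikes = np.array([0.0, 0.010, 0.030, 0.070])
        assert intr.accommodation_index(spikes, 0.120) == pytest.approx(5.0)

    def test_regular_spiking_gives_one(self):
        spikes = np.arange(0.0, 0.5, 0.05)
        assert intr.accommodation_index(spikes, 0.5) == pytest.approx(1.0)

    def test_undefined_below_two_spikes(self):
        assert intr.accommodation_index(np.array([0.1]), 0.5) is None

    @given(hst.floats(0.5, 20.0))
    def test_time_dilation_invariance(self, c):
        spikes = np.array([0.01, 0.03, 0.06, 0.12])
        a1 = intr.accommodation_index(spikes, 0.5)
        a2 = intr.accommodation_index(spikes * c, 0.5 * c)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_matches_geometric_generator_model(self, truth):
        """Index equals the closed form implied by geometric ISI growth."""
        ss = syn.gen_step_sweeps(truth, noise_sd=0.0)
        p = ss.protocol
        end = p.step_start + p.step_dur
        for k, gt in enumerate(ss.spike_times):
            if gt.size < 2:
                continue
            isis = np.diff(gt)
            expected = max(isis.max(), end - gt[-1]) / isis[0]
            det = intr.detect_spikes(ss.sweeps[k], ss.fs, window=(p.step_start, end))
            got = intr.accommodation_index(det, end)
            assert got == pytest.approx(expected, rel=0.01)
            # geometric growth: max programmed ISI is isi0 * g^(k-1)
            g = truth.cell.accommodation
            assert isis.max() == pytest.approx(isis[0] * g ** (isis.size - 1),
                                               rel=1e-6)


class TestIoCurves:
    def _group(self, slope, n_cells, rng, noise=0.3):
        rows = []
        currents = np.array([0.0, 40.0, 80.0, 120.0, 160.0])
        for c in range(n_cells):
            counts = slope * currents + rng.normal(0, noise, currents.size)
            for i, cur in enumerate(currents):
                rows.append({"cell": f"c{c}", "current": cur,
                             "n_spikes": max(counts[i], 0.0)})
        return pd.DataFrame(rows)

    def test_io_curve_monotone_for_generator(self, truth):
        ss = syn.gen_step_sweeps(truth, noise_sd=0.0)
        curve = intr.io_curve(ss)
        counts = curve.set_index("current")["n_spikes"]
        supra = counts[counts.index >= truth.cell.rheobase_pa]
        assert (np.diff(supra.values) >= 0).all()
        assert counts[counts.index < 0].sum() == 0

    def test_identical_groups_no_difference(self, rng):
        g = self._group(0.05, 6, rng)
        res = intr.compare_io(g, g.copy())
        assert res.p_slope > 0.9
        assert res.f_slope == pytest.approx(0.0, abs=1e-6)

    def test_programmed_slope_ratio_detected(self, rng):
        ga = self._group(0.05, 6, rng)
        gb = self._group(0.10, 6, rng)
        res = intr.compare_io(ga, gb)
        assert res.slopes_differ
        assert res.slopes["b"] / res.slopes["a"] == pytest.approx(2.0, rel=0.15)

    def test_single_point_grid_rejected(self, rng):
        g = self._group(0.05, 3, rng)
        bad = g[g["current"] == 40.0]
        with pytest.raises(ValueError):
            intr.compare_io(bad, bad)

    def test_disjoint_grids_rejected(self, rng):
        ga = self._group(0.05, 3, rng)
        gb = self._group(0.05, 3, rng)
        gb["current"] += 1000.0
        with pytest.raises(ValueError, match="disjoint"):
            intr.compare_io(ga, gb)


class TestFullPanel:
    def test_noise_free_panel_recovers_programmed_cell(self):
        cell = syn.CellParams(rmp_mv=-62.3, r_n_mohm=195.0, tau_ms=19.0, sag_mv=4.3)
        ss = syn.gen_step_sweeps(syn.GroundTruth(cell=cell), noise_sd=0.0)
        p = intr.measure_intrinsic(ss)
        assert p.rmp == pytest.approx(cell.rmp_mv, rel=0.01)
        assert p.input_resistance == pytest.approx(cell.r_n_mohm, rel=0.01)
        assert p.tau == pytest.approx(cell.tau_ms, rel=0.01)
        assert p.sag_voltage == pytest.approx(-cell.sag_mv, rel=0.01)
        assert p.accommodation_index is not None and p.accommodation_index >= 1.0
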