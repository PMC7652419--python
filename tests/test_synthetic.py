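"""Generator contracts: determinism, zero-noise round trips, noise behaviour."""

import numpy as np
import pytest

from neuropheno import behavior as bhv
from neuropheno import flux
from neuropheno import intrinsic as intr
from neuropheno import stats as st
from neuropheno import synthetic as syn


class TestDeterminism:
    def test_same_seed_bit_identical(self, truth):
        a1 = syn.gen_isotopomer_dataset(truth, noise_cv=0.08, n=5)
        a2 = syn.gen_isotopomer_dataset(truth, noise_cv=0.08, n=5)
        for s1, s2 in zip(a1, a2):
            assert s1.enrich == s2.enrich
        s1 = syn.gen_step_sweeps(truth, noise_sd=0.5)
        s2 = syn.gen_step_sweeps(truth, noise_sd=0.5)
        assert np.array_equal(s1.sweeps, s2.sweeps)
        t1, e1 = syn.gen_psc_trace(truth, duration=110.0, fs=20000.0, noise_sd=4.0)
        t2, e2 = syn.gen_psc_trace(truth, duration=110.0, fs=20000.0, noise_sd=4.0)
        assert np.array_equal(t1, t2) and np.array_equal(e1.amplitudes, e2.amplitudes)
        tr1 = syn.gen_track(truth, duration=10.0)
        tr2 = syn.gen_track(truth, duration=10.0)
        assert np.array_equal(tr1.x, tr2.x)
        q1 = syn.gen_qpcr(truth, n_per_group=3)
        q2 = syn.gen_qpcr(truth, n_per_group=3)
        assert q1.equals(q2)

    def test_different_seeds_differ(self, truth):
        other = truth.with_seed(truth.seed + 1)
        s1 = syn.gen_step_sweeps(truth, noise_sd=0.5)
        s2 = syn.gen_step_sweeps(other, noise_sd=0.5)
        assert not np.array_equal(s1.sweeps, s2.sweeps)


class TestIsotopomerGenerator:
    def test_zero_noise_hits_targets_exactly(self, truth):
        s = syn.gen_isotopomer_dataset(truth, noise_cv=0.0)[0]
        assert flux.mr_glu(s) == pytest.approx(truth.flux.mr_glu, rel=1e-12)
        assert flux.mr_gaba(s) == pytest.approx(truth.flux.mr_gaba, rel=1e-12)
        assert flux.mr_total(s) == pytest.approx(truth.flux.mr_total, rel=1e-12)

    def test_custom_targets_round_trip(self):
        t = syn.GroundTruth(
            seed=7, flux=syn.FluxTargets(mr_glu=0.3, mr_gaba=0.1, mr_total=0.55)
        )
        s = syn.gen_isotopomer_dataset(t, noise_cv=0.0)[0]
        assert flux.mr_glu(s) == pytest.approx(0.3, rel=1e-12)

    def test_zero_targets_zero_enrichments(self):
        t = syn.GroundTruth(
            seed=1, flux=syn.FluxTargets(mr_glu=0.0, mr_gaba=0.0, mr_total=0.0)
        )
        s = syn.gen_isotopomer_dataset(t)[0]
        assert all(v == 0 for v in s.enrich.values())
        assert flux.mr_total(s) == 0.0

    def test_noisy_recovery_unbiased(self):
        t = syn.GroundTruth(seed=11, flux=syn.FluxTargets(
            mr_glu=0.3, mr_gaba=0.117156, mr_total=0.55))
        samples = syn.gen_isotopomer_dataset(t, noise_cv=0.05, n=100)
        vals = np.array([flux.mr_glu(s) for s in samples])
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.3) < 2 * sem + 1e-12

    def test_rejects_bad_inputs(self, truth):
        with pytest.raises(ValueError, match="all-zero"):
            syn.gen_isotopomer_dataset(
                truth, template={p: 0.0 for p in flux.ENRICH_POSITIONS})
        with pytest.raises(ValueError):
            syn.FluxTargets(mr_glu=-0.1)
        with pytest.raises(ValueError, match="infeasible"):
            # total below the floor implied by the component rates
            bad = syn.GroundTruth(flux=syn.FluxTargets(
                mr_glu=0.3476, mr_gaba=0.1172, mr_total=0.2))
            syn.gen_isotopomer_dataset(bad)


class TestSweepGenerator:
    def test_ohms_law_steady_state(self):
        """310 MΩ at −100 pA gives a −31 mV steady-state deflection."""
        t = syn.GroundTruth(seed=0, cell=syn.CellParams(
            r_n_mohm=310.0, sag_mv=0.0))
        ss = syn.gen_step_sweeps(t, noise_sd=0.0)
        p = ss.protocol
        hyp = ss.sweep_at(-100.0)
        rmp = intr.measure_rmp(hyp, ss.fs, p.step_start)
        i = slice(int((p.step_start + 0.8 * p.step_dur) * ss.fs),
                  int((p.step_start + p.step_dur) * ss.fs))
        assert np.mean(hyp[i]) - rmp == pytest.approx(-31.0, abs=0.05)

    def test_tau_recovery_noise_free(self):
        t = syn.GroundTruth(seed=0, cell=syn.CellParams(tau_ms=20.0))
        ss = syn.gen_step_sweeps(t, noise_sd=0.0)
        tau = intr.fit_tau(ss.sweep_at(-100.0), ss.fs, ss.protocol.step_start)
        assert tau == pytest.approx(20.0, rel=0.01)

    def test_zero_sag_measures_zero(self):
        t = syn.GroundTruth(seed=0, cell=syn.CellParams(sag_mv=0.0))
        ss = syn.gen_step_sweeps(t, noise_sd=0.0)
        sag_v, sag_pct = intr.sag_measures(
            ss.sweep_at(-100.0), ss.fs, ss.protocol.step_start, ss.protocol.step_dur)
        assert sag_v == pytest.approx(0.0, abs=1e-6)
        assert sag_pct == pytest.approx(0.0, abs=1e-4)

    def test_ground_truth_spikes_detected(self, truth):
        ss = syn.gen_step_sweeps(truth, noise_sd=0.0)
        p = ss.protocol
        for k, current in enumerate(p.currents):
            det = intr.detect_spikes(ss.sweeps[k], ss.fs,
                                     window=(p.step_start, p.step_start + p.step_dur))
            gt = ss.spike_times[k]
            assert det.size == gt.size
            if gt.size:
                assert np.max(np.abs(det - gt)) <= 1.5 / ss.fs

    def test_rejects_bad_protocol(self, truth):
        with pytest.raises(ValueError):
            syn.gen_step_sweeps(truth, noise_sd=-1.0)
        with pytest.raises(ValueError):
            intr.StepProtocol(step_dur=0.0)


class TestPscGenerator:
    def test_event_count_near_poisson_mean(self, truth):
        _, gt = syn.gen_psc_trace(truth, duration=150.0, fs=10000.0, noise_sd=0.0)
        # rate 2 Hz, 150 s: 300 expected, allow 4 sigma
        assert abs(len(gt) - 300) < 4 * np.sqrt(300)

    def test_tail_mass_binomial(self):
        t = syn.GroundTruth(seed=5, events=syn.EventParams(
            rate_hz=20.0, tail_frac=0.05))
        _, gt = syn.gen_psc_trace(t, duration=250.0, fs=10000.0, noise_sd=0.0)
        n = len(gt)
        assert n > 4000
        frac = np.mean(gt.amplitudes > t.events.tail_cutoff_pa)
        margin = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < margin + 0.005

    def test_rejects_unresolvable_kernel(self, truth):
        with pytest.raises(ValueError, match="rise"):
            syn.gen_psc_trace(truth, duration=150.0, fs=1000.0)
        with pytest.raises(ValueError):
            syn.EventParams(rise_ms=6.0, decay_ms=5.0)

    def test_short_recording_warns(self, truth):
        with pytest.warns(UserWarning, match="200"):
            syn.gen_psc_trace(truth, duration=10.0, fs=10000.0)


class TestStartleGenerator:
    def test_zero_cv_exact_attenuation(self, truth):
        trials = syn.gen_startle_trials(truth, cv=0.0)
        for lvl, att in truth.ppi.attenuation.items():
            assert bhv.ppi_percent(trials, lvl) == pytest.approx(100 * att)

    def test_zero_attenuation_zero_ppi(self):
        t = syn.GroundTruth(ppi=syn.PpiParams(attenuation={8: 0.0}))
        trials = syn.gen_startle_trials(t, cv=0.0)
        assert bhv.ppi_percent(trials, 8) == pytest.approx(0.0)

    def test_noisy_ppi_unbiased(self):
        t0 = syn.GroundTruth(ppi=syn.PpiParams(attenuation={16: 0.4}))
        vals = [
            bhv.ppi_percent(
                syn.gen_startle_trials(t0.with_seed(s), n_tone=10, n_prepulse=5,
                                       cv=0.2), 16)
            for s in range(400)
        ]
        vals = np.asarray(vals)
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        # ratio-of-means estimator carries O(cv^2/n) bias; allow it on top
        assert abs(vals.mean() - 40.0) < 2 * sem + 0.5

    def test_rejects_negative_basal(self):
        with pytest.raises(ValueError):
            syn.PpiParams(basal=-1.0)


class TestTrackGenerator:
    def test_positions_stay_inside(self, truth):
        tr = syn.gen_track(truth, duration=20.0)
        assert tr.arena.contains(tr.x, tr.y).all()

    def test_huge_avoidance_empties_center(self):
        t = syn.GroundTruth(seed=2, track=syn.TrackParams(
            step_scale_cm=1.0, persistence=0.0, avoidance_weight=1e9))
        tr = syn.gen_track(t, duration=60.0)
        assert bhv.zone_metrics(tr, "center")["pct_time_in_zone"] == 0.0

    def test_zero_area_arena_rejected(self):
        import shapely.geometry as geo
        with pytest.raises(ValueError):
            bhv.Arena("degenerate", geo.Polygon())


class TestQpcrGenerator:
    def test_noise_free_exact_folds(self):
        q = syn.QpcrParams(log2_fc={"a": 1.0, "b": 0.0, "c": -1.0},
                           ct_sd=0.0, subject_sd=0.25)
        tab = syn.gen_qpcr(syn.GroundTruth(seed=0, qpcr=q), n_per_group=5)
        res = st.ddct_fold_change(tab, "vehicle").set_index("gene")
        assert res.loc["a", "fold_change"] == pytest.approx(2.0)
        assert res.loc["b", "fold_change"] == pytest.approx(1.0)
        assert res.loc["c", "fold_change"] == pytest.approx(0.5)

    def test_unit_folds_give_zero_ddct(self):
        q = syn.QpcrParams(log2_fc={"a": 0.0, "b": 0.0}, ct_sd=0.0, subject_sd=0.0)
        tab = syn.gen_qpcr(syn.GroundTruth(qpcr=q), n_per_group=3)
        res = st.ddct_fold_change(tab, "vehicle")
        assert np.allclose(res["ddct"], 0.0)

    def test_noisy_recovery_unbiased(self):
        q = syn.QpcrParams(log2_fc={"a": 1.0}, ct_sd=0.2, subject_sd=0.0)
        folds = []
        for s in range(300):
            tab = syn.gen_qpcr(syn.GroundTruth(seed=s, qpcr=q), n_per_group=11)
            folds.append(
                st.ddct_fold_change(tab, "vehicle")["fold_change"].iloc[0])
        # ddct is unbiased in log space: compare log2 means
        logs = np.log2(folds)
        sem = logs.std(ddof=1) / np.sqrt(logs.size)
        assert abs(logs.mean() - 1.0) < 2 * sem

    def test_housekeeping_required(self, truth):
        with pytest.raises(ValueError):
            syn.QpcrParams(log2_fc={"Gapdh": 1.0})
        tab = syn.gen_qpcr(truth, n_per_group=2)
        import neuropheno.stats as st2
        with pytest.raises(ValueError, match="housekeeping"):
            st2.ddct_fold_change(tab[tab["gene"] != "Gapdh"], "vehicle")
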