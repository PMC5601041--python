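
import numpy as np
import pandas as pd
import pytest

import restcm as rc
from restcm.erp_pipeline import StageWindows, concatenate_epochs, stage_table
from restcm.referencing import ScalpRecording


def make_rec(cap63, data, sfreq=500.0):
    return ScalpRecording(data, cap63.labels, sfreq)


class TestPreprocess:
    def test_dc_preserved_and_decimation(self, cap63):
        rec = make_rec(cap63, np.full((63, 1000), 5.0))
        out = rc.preprocess(rec)
        assert out.sfreq == 250.0
        assert out.n_samples == 500
        assert np.allclose(out.data, 5.0, atol=1e-9)

    def test_20hz_strongly_attenuated(self, cap63):
        t = np.arange(2000) / 500.0
        rec = make_rec(cap63, np.tile(np.sin(2 * np.pi * 20 * t), (63, 1)))
        out = rc.preprocess(rec)
        core = out.data[:, 100:-100]           # avoid filter edges
        assert np.abs(core).max() < 0.01       # < 1% of unit input

    def test_6hz_passband_edge(self, cap63):
        t = np.arange(4000) / 500.0
        rec = make_rec(cap63, np.tile(np.sin(2 * np.pi * 1.0 * t), (63, 1)))
        out = rc.preprocess(rec)
        core = out.data[0, 200:-200]
        assert np.abs(core).max() > 0.98       # 1 Hz passes essentially intact

    def test_cutoff_above_nyquist_rejected(self, cap63):
        rec = make_rec(cap63, np.zeros((63, 100)), sfreq=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            rc.preprocess(rec, cutoff=6.0)


class TestEpochs:
    @pytest.fixture()
    def events(self):
        return pd.DataFrame({"onset_s": [1.0, 2.0, 3.0],
                             "condition": ["target", "standard", "target"]})

    def test_epoch_geometry_and_baseline(self, cap63, events, rng):
        rec = make_rec(cap63, rng.normal(size=(63, 250 * 5)) + 3.0, sfreq=250.0)
        ep = rc.make_epochs(rec, events, reject_uv=None)
        assert ep.data.shape == (3, 63, 250)
        pre = ep.data[:, :, :50]               # [-200, 0) ms at 250 Hz
        assert np.abs(pre.mean(axis=2)).max() < 1e-10
        assert list(ep.conditions) == ["target", "standard", "target"]

    def test_rejection_boundary(self, cap63, events):
        """|v| > 75 uV rejects; exactly 75 uV is retained."""
        data = np.zeros((63, 250 * 5))
        i_cz = cap63.index("Cz")
        data[i_cz, int(1.1 * 250)] = 76.0      # in epoch 1 (post-baseline)
        data[i_cz, int(2.1 * 250)] = 75.0      # in epoch 2
        rec = make_rec(cap63, data, sfreq=250.0)
        ep = rc.make_epochs(rec, events)
        assert list(ep.rejected) == [True, False, False]
        assert "amplitude" in ep.reject_reason[0]

    def test_rejection_ignores_non_analysis_channels(self, cap63, events):
        data = np.zeros((63, 250 * 5))
        data[cap63.index("VEOG"), int(1.1 * 250)] = 500.0
        rec = make_rec(cap63, data, sfreq=250.0)
        ep = rc.make_epochs(rec, events)
        assert not ep.rejected.any()

    def test_edge_events_skipped(self, cap63, rng):
        rec = make_rec(cap63, rng.normal(size=(63, 500)), sfreq=250.0)
        ev = pd.DataFrame({"onset_s": [0.05, 0.5], "condition": ["t", "t"]})
        ep = rc.make_epochs(rec, ev, reject_uv=None)
        assert len(ep.data) == 1
        assert len(ep.skipped_events) == 1

    def test_average_linearity_and_counts(self, cap63, events, rng):
        rec = make_rec(cap63, rng.normal(size=(63, 250 * 5)), sfreq=250.0)
        ep = rc.make_epochs(rec, events, reject_uv=None)
        avg = rc.average_erp(ep, "target")
        assert avg.meta["n_averaged"] == 2
        expect = ep.data[[0, 2]].mean(axis=0)
        assert np.allclose(avg.data, expect, atol=1e-12)
        with pytest.raises(ValueError):
            rc.average_erp(ep, "nope")

    def test_identical_epochs_average(self, cap63):
        data = np.zeros((63, 250 * 5))
        t = np.arange(250 * 5) / 250.0
        data[5] = np.sin(2 * np.pi * 3 * t)    # 1 s periodic: epochs identical
        rec = make_rec(cap63, data, sfreq=250.0)
        ev = pd.DataFrame({"onset_s": [1.0, 2.0], "condition": ["t", "t"]})
        ep = rc.make_epochs(rec, ev, reject_uv=None)
        avg = rc.average_erp(ep, "t")
        assert np.allclose(avg.data, ep.data[0], atol=1e-12)

    def test_reref_commutes_with_averaging(self, cap63, events, rng):
        """AR of the average equals the average of AR epochs."""
        rec = make_rec(cap63, rng.normal(size=(63, 250 * 5)), sfreq=250.0)
        ep = rc.make_epochs(rec, events, reject_uv=None)
        avg_then_ar = rc.apply_common_reference(rc.average_erp(ep, "target"),
                                                "AR")
        ar_rec = rc.apply_common_reference(rec, "AR")
        ar_then_avg = rc.average_erp(
            rc.make_epochs(ar_rec, events, reject_uv=None), "target")
        assert np.allclose(avg_then_ar.data, ar_then_avg.data, atol=1e-10)


class TestP300Measures:
    def make_erp(self, cap63, data, sfreq=250.0):
        return ScalpRecording(data, cap63.labels, sfreq, tmin=-0.2)

    def test_three_electrode_mean(self, cap63):
        data = np.zeros((63, 250))
        i = int((0.36 + 0.2) * 250)
        for lab, amp in (("Cz", 8.0), ("CPz", 10.0), ("Pz", 12.0)):
            data[cap63.index(lab), i] = amp
        meas = rc.p300_measures(self.make_erp(cap63, data))
        assert meas.p300_amplitude == pytest.approx(10.0)
        assert meas.p300_latency == pytest.approx(0.36, abs=1e-9)

    def test_flat_signal_latency_undefined(self, cap63):
        meas = rc.p300_measures(self.make_erp(cap63, np.zeros((63, 250))))
        assert meas.p300_amplitude == 0.0
        assert meas.p300_latency is None

    def test_recovers_generator_component(self, default_cohort):
        """A noiseless ERP built from the cohort's parietal P300 component
        (10 uV at Pz, 360 ms) measures 10 +/- 1 uV and 360 +/- 12 ms."""
        cfg = default_cohort.cfg
        comp = next(c for c in cfg.components if c.name == "P300")
        ci = cfg.components.index(comp)
        gmap = default_cohort._comp_maps[:-1, ci]      # montage channels
        amp = comp.amplitude_uv["target"]
        wave = comp.waveform(1.0 / 250, 250)   # post-stimulus second at 250 Hz
        erp = ScalpRecording(np.outer(amp * gmap, wave),
                             default_cohort.montage.labels, 250.0, tmin=0.0)
        meas = rc.p300_measures(erp)
        assert abs(meas.p300_amplitude - amp) <= 1.0
        assert abs(meas.p300_latency - comp.peak_s) <= 0.012


class TestStageStatistics:
    def test_window_defaults(self):
        s = StageWindows()
        assert s.S1 == (0.210, 0.350)
        assert s.S2 == (0.350, 0.480)
        assert s.S3 == (0.480, 0.740)
        with pytest.raises(ValueError):
            StageWindows(S1=(0.3, 0.2))
        with pytest.raises(ValueError):
            StageWindows(S1=(0.2, 0.4), S2=(0.35, 0.5))

    @pytest.fixture()
    def samples(self, rng):
        rows = []
        times = 0.2 + np.arange(150) / 250.0
        for sub in range(6):
            # exactly representable values -> stage means are bit-identical
            # across references
            base = rng.integers(-64, 64, size=len(times)) / 16.0
            for ref in ("REST", "AR", "LM"):
                for cond in ("target", "standard"):
                    rows.append(pd.DataFrame({
                        "subject": sub, "reference": ref, "condition": cond,
                        "time": times, "X": 0.0, "Y": base,
                        "speed": np.abs(base),
                    }))
        return pd.concat(rows, ignore_index=True)

    def test_identical_references_null(self, samples):
        out = rc.stage_statistics(samples)
        for stage in ("S1", "S2", "S3"):
            t = out["tests"][stage]["mean_y"]
            assert t["anova"].F == pytest.approx(0.0, abs=1e-18)
            assert t["anova"].p == 1.0
            assert np.allclose(t["tukey"].p_adjusted, 1.0)

    def test_table_shape(self, samples):
        tab = stage_table(samples)
        assert len(tab) == 6 * 3 * 2 * 3       # subjects x refs x conds x stages

    def test_detects_reference_shift(self, samples):
        shifted = samples.copy()
        mask = shifted.reference == "LM"
        shifted.loc[mask, "Y"] += 0.4
        out = rc.stage_statistics(shifted)
        t = out["tests"]["S2"]["mean_y"]
        assert t["anova"].p < 0.001
        assert t["tukey"].p_for("LM", "REST") < 0.01


class TestDefaultCohortReferenceEffect:
    def test_s2_separates_lm_from_rest(self, oddball_results):
        """On the default cohort the linked-mastoids reference shifts the S2
        (P300-stage) CM location relative to REST (Tukey p < 0.05), echoing
        the reference effect the analysis is designed to expose."""
        st = rc.stage_statistics(oddball_results["samples"])
        s2 = st["tests"]["S2"]["mean_y"]
        assert s2["anova"].p < 0.05
        assert s2["tukey"].p_for("LM", "REST") < 0.05


class TestConditionCorrelation:
    def test_identical_curves(self):
        times = 0.2 + np.arange(150) / 250.0
        rng = np.random.default_rng(3)
        v = np.abs(rng.normal(size=150)) + 0.5
        out = rc.condition_correlation(v, v, times)
        # S2/S3 pair identical windows: R = 1, slope = 1
        for stage in ("S2", "S3"):
            assert out[stage].r == pytest.approx(1.0)
            assert out[stage].slope == pytest.approx(1.0)

    def test_negated_curves(self):
        times = 0.2 + np.arange(150) / 250.0
        v = np.sin(np.linspace(0, 9, 150)) + 2.0
        out = rc.condition_correlation(v, -v, times)
        assert out["S2"].r == pytest.approx(-1.0)

    def test_s1_window_sample_count(self):
        """S1 pairs 26 samples at 250 Hz (inclusive endpoints, 40 ms lag)."""
        times = 0.2 + np.arange(150) / 250.0
        v = np.sin(np.linspace(0, 9, 150)) + 2.0
        out = rc.condition_correlation(v, 0.5 * v + 0.1, times)
        assert out["S1"].n == 26

    def test_lag_alignment(self):
        """A 40 ms lagged copy correlates perfectly in S1."""
        times = 0.2 + np.arange(150) / 250.0
        rng = np.random.default_rng(5)
        std = np.abs(rng.normal(size=150)) + 1.0
        tgt = np.roll(std, 10)                 # 10 samples = 40 ms delay
        out = rc.condition_correlation(tgt, std, times)
        assert out["S1"].r == pytest.approx(1.0)
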