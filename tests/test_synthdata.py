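import numpy as np
import pytest
from scipy import signal as sps

from eegsonify import synthdata as sd
from eegsonify.evaluation import fleiss_kappa, ratings_from_labels


def _cfg(**kw):
    base = dict(duration=120.0, n_channels=2, seed=42)
    base.update(kw)
    return sd.SynthConfig(**base)


class TestGenRecord:
    def test_determinism(self):
        cfg = _cfg(events=[sd.SeizureEventSpec(onset=30, duration=20)],
                   ecg=sd.EcgSpec())
        r1, _ = sd.gen_record(cfg)
        r2, _ = sd.gen_record(cfg)
        assert np.array_equal(r1.samples, r2.samples)

    def test_background_rms_matches_config(self):
        rec, _ = sd.gen_record(_cfg(background_rms=30.0))
        rms = np.sqrt(np.mean(rec.samples ** 2, axis=1))
        assert np.all(np.abs(rms - 30.0) / 30.0 < 0.10)

    @pytest.mark.parametrize("target_rms", [67.8, 18.6])
    def test_event_window_rms(self, target_rms):
        ev = sd.SeizureEventSpec(onset=30, duration=40, rms=target_rms,
                                 channels=(0,))
        cfg = _cfg(events=[ev], background_rms=0.001)
        rec, _ = sd.gen_record(cfg)
        window = rec.samples[0, int(30 * 256):int(70 * 256)]
        realized = np.sqrt(np.mean(window ** 2))
        assert abs(realized - target_rms) / target_rms < 0.10

    def test_low_amplitude_event_is_sub_unit_snr(self):
        """18.6 µV event on 30 µV background: the generator's hard case."""
        ev = sd.SeizureEventSpec(onset=30, duration=40, rms=18.6, channels=(0,))
        cfg = _cfg(events=[ev], background_rms=30.0)
        parts = sd.gen_components(cfg)
        w = slice(int(30 * 256), int(70 * 256))
        snr = np.mean(parts["events"][0, w] ** 2) / np.mean(
            parts["background"][0, w] ** 2)
        assert snr < 1.0

    def test_event_outside_record_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _cfg(events=[sd.SeizureEventSpec(onset=115, duration=20)])

    def test_overlapping_events_rejected(self):
        evs = [sd.SeizureEventSpec(onset=30, duration=20),
               sd.SeizureEventSpec(onset=40, duration=20)]
        with pytest.raises(ValueError, match="overlap"):
            _cfg(events=evs)

    def test_short_event_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            sd.SeizureEventSpec(onset=0, duration=5)

    def test_sweep_tracked_by_stft_peak(self):
        """Dominant STFT frequency follows the configured linear sweep."""
        ev = sd.SeizureEventSpec(onset=10, duration=60, f_start=4.0,
                                 f_end=1.0, rms=50.0, channels=(0,))
        cfg = _cfg(events=[ev], background_rms=0.001, seed=3)
        rec, _ = sd.gen_record(cfg)
        rate = 256
        nper = 8 * rate  # 0.125 Hz bins
        f, t, Z = sps.stft(rec.samples[0], fs=rate, nperseg=nper,
                           noverlap=nper // 2)
        for i, tc in enumerate(t):
            if not (10 + 6 < tc < 70 - 6):
                continue
            dominant = f[np.argmax(np.abs(Z[:, i]))]
            expected = 4.0 + (1.0 - 4.0) * (tc - 10) / 60
            assert abs(dominant - expected) <= f[1] - f[0] + 1e-9

    def test_ecg_track_beat_rate(self):
        cfg = _cfg(ecg=sd.EcgSpec(heart_rate=140, amplitude=25),
                   background_rms=30.0)
        parts = sd.gen_components(cfg)
        track = parts["ecg"][0]
        peaks, _ = sps.find_peaks(track, height=0.5 * track.max(),
                                  distance=int(0.3 * 256))
        bpm = 60.0 * peaks.size / cfg.duration
        assert abs(bpm - 140) / 140 < 0.08


class TestSimulateAnnotators:
    def _models(self, p_keep):
        # bias set so the logistic yields exactly p_keep at the probe event
        bias = np.log(p_keep / (1 - p_keep)) if 0 < p_keep < 1 else \
            (60.0 if p_keep >= 1 else -60.0)
        return [sd.AnnotatorModel(f"A{i}", bias=bias, w_rms=0.0, w_dur=0.0)
                for i in range(3)]

    def test_perfect_detection_perfect_agreement(self):
        truth_yes = sd.SeizureAnnotation("r1", "t", [(10.0, 30.0)])
        truth_no = sd.SeizureAnnotation("r2", "t", [])
        models = self._models(1.0)
        labels = []
        for truth in [truth_yes, truth_no] * 10:
            anns = sd.simulate_annotators(truth, models, seed=1)
            labels.append([int(a.has_seizure) for a in anns])
        ratings = ratings_from_labels(np.array(labels))
        assert fleiss_kappa(ratings).kappa == pytest.approx(1.0)

    def test_zero_detection_no_events(self):
        truth = sd.SeizureAnnotation("r1", "t", [(10.0, 30.0)])
        anns = sd.simulate_annotators(truth, self._models(0.0), seed=2)
        assert all(not a.has_seizure for a in anns)

    def test_requires_two_models(self):
        truth = sd.SeizureAnnotation("r1", "t", [])
        with pytest.raises(ValueError):
            sd.simulate_annotators(truth, [sd.AnnotatorModel("A")])

    def test_empirical_kappa_matches_bernoulli_expectation(self):
        """Fleiss kappa over 500 simulated records agrees with the
        closed-form expectation of the Bernoulli annotator model."""
        q = 0.8          # per-annotator detection probability
        prevalence = 0.5
        n_records, n_raters = 500, 3
        models = self._models(q)
        truth_event = [(10.0, 60.0)]

        labels = []
        for r in range(n_records):
            has = r < int(prevalence * n_records)
            truth = sd.SeizureAnnotation(f"r{r}", "t",
                                         truth_event if has else [])
            anns = sd.simulate_annotators(truth, models, seed=1000 + r)
            labels.append([int(a.has_seizure) for a in anns])
        res = fleiss_kappa(ratings_from_labels(np.array(labels)))

        # oracle: E[p] from per-subject pairwise agreement, p_e from the
        # expected category marginals. Seizure records vote 1 iid Bern(q);
        # clean records always vote 0.
        agree_seizure = q * q + (1 - q) * (1 - q)
        E_p = prevalence * agree_seizure + (1 - prevalence) * 1.0
        marginal_1 = prevalence * q
        E_pe = marginal_1 ** 2 + (1 - marginal_1) ** 2
        kappa_expected = (E_p - E_pe) / (1 - E_pe)

        half_width = res.z * res.sd / np.sqrt(res.n)
        assert abs(res.kappa - kappa_expected) < half_width
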