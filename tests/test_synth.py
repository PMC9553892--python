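"""Generator contracts: counts, determinism, PSD shaping, planted structure."""

import numpy as np
import pytest
from scipy import signal as sps

from brainprint import features as F
from brainprint import synth
from brainprint.montage import DEFAULT_REGIONS


class TestSynthesizeChannel:
    def test_flat_psd_matches_variance(self, rng):
        """Parseval: flat density S over the band gives variance S * bandwidth."""
        fs, n, level = 500.0, 200000, 0.2
        nf = n // 2 + 1
        x = synth.synthesize_channel(np.full(nf, level), n, fs, rng)
        assert x.var() == pytest.approx(level * fs / 2, rel=0.02)

    def test_single_bin_gives_narrowband_tone(self, rng):
        fs, n = 500.0, 50000
        freqs = np.fft.rfftfreq(n, 1 / fs)
        psd = np.zeros(freqs.size)
        psd[np.argmin(np.abs(freqs - 10.0))] = 3.0
        x = synth.synthesize_channel(psd, n, fs, rng)
        f, p = sps.periodogram(x, fs=fs)
        outside = p[(f < 9) | (f > 11)].sum()
        assert outside / p.sum() < 1e-6

    def test_zero_psd_gives_zero_series(self, rng):
        x = synth.synthesize_channel(np.zeros(501), 1000, 500.0, rng)
        assert np.allclose(x, 0.0)

    def test_negative_psd_rejected(self, rng):
        psd = np.zeros(501)
        psd[3] = -1.0
        with pytest.raises(ValueError):
            synth.synthesize_channel(psd, 1000, 500.0, rng)

    def test_realized_periodogram_converges_to_target(self, rng):
        """Segment-averaged periodogram approaches the shaped target PSD."""
        fs, n = 500.0, 1000
        freqs = np.fft.rfftfreq(n, 1 / fs)
        target = 1.0 / (1.0 + freqs)
        acc = np.zeros_like(freqs)
        n_seg = 400
        for _ in range(n_seg):
            x = synth.synthesize_channel(target, n, fs, rng)
            _, p = sps.periodogram(x, fs=fs)
            acc += p
        acc /= n_seg
        band = (freqs > 1) & (freqs < 200)
        assert np.corrcoef(np.log(acc[band]), np.log(target[band]))[0, 1] > 0.99
        assert np.median(acc[band] / target[band]) == pytest.approx(1.0, abs=0.1)


class TestCohortGeneration:
    def test_minimal_cohort_counts(self):
        cfg = synth.CohortConfig(n_pairs=1, weeks=1, tasks=("rce",), seed=0)
        recs, gt = synth.generate_cohort(cfg)
        assert len(recs) == 2
        assert sorted(r.subject_id for r in recs) == [1, 2]
        assert all(r.data.shape == (32, 32500) for r in recs)

    def test_recording_grid_counts(self, small_config, small_cohort):
        recs, _ = small_cohort
        cfg = small_config
        assert len(recs) == cfg.n_subjects * cfg.weeks * len(cfg.tasks)
        keys = {(r.subject_id, r.week, r.task) for r in recs}
        assert len(keys) == len(recs)

    def test_same_seed_is_bit_identical(self):
        cfg = synth.CohortConfig(n_pairs=1, weeks=1, tasks=("rce", "mbi"), seed=42)
        a, _ = synth.generate_cohort(cfg)
        b, _ = synth.generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_streaming_matches_materialized(self):
        cfg = synth.CohortConfig(n_pairs=1, weeks=1, tasks=("rce",), seed=9)
        listed, _ = synth.generate_cohort(cfg)
        streamed = list(synth.iter_cohort(cfg))
        assert np.array_equal(listed[0].data, streamed[0].data)

    def test_missing_cells_are_skipped(self):
        cfg = synth.CohortConfig(
            n_pairs=1, weeks=1, tasks=("rce", "roe"), missing=((1, 1, "rce"),), seed=0
        )
        recs = list(synth.iter_cohort(cfg))
        assert len(recs) == 3
        assert (1, 1, "rce") not in {(r.subject_id, r.week, r.task) for r in recs}

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="window"):
            synth.CohortConfig(task_duration=1.0)

    def test_bad_montage_rejected(self):
        with pytest.raises(ValueError, match="montage"):
            synth.CohortConfig(channels=("FP1", "NOPE"))


class TestGroundTruth:
    def test_profiles_strictly_positive(self, small_cohort):
        _, gt = small_cohort
        for prof in gt.base_profiles.values():
            assert np.all(prof > 0)

    def test_within_pair_closer_than_between(self):
        cfg = synth.CohortConfig(n_pairs=4, weeks=1, tasks=("rce",), seed=2)
        gt = synth.make_ground_truth(cfg)
        logp = {s: np.log(p) for s, p in gt.base_profiles.items()}
        for p in range(1, cfg.n_pairs + 1):
            a, b = 2 * p - 1, 2 * p
            within = np.linalg.norm(logp[a] - logp[b])
            others = [
                np.linalg.norm(logp[a] - logp[s])
                for s in cfg.subjects
                if s not in (a, b)
            ]
            assert within < min(others)

    def test_frontal_divergence_exceeds_occipital(self):
        cfg = synth.CohortConfig(n_pairs=6, weeks=1, tasks=("rce",), seed=3)
        gt = synth.make_ground_truth(cfg)
        scalp = list(gt.scalp_channels)
        fro = [scalp.index(c) for c in DEFAULT_REGIONS["frontal"]]
        occ = [scalp.index(c) for c in DEFAULT_REGIONS["occipital"]]
        fro_d, occ_d = [], []
        for p in range(1, cfg.n_pairs + 1):
            d = np.log(gt.base_profiles[2 * p - 1]) - np.log(gt.base_profiles[2 * p])
            fro_d.append(np.sqrt(np.mean(d[fro] ** 2)))
            occ_d.append(np.sqrt(np.mean(d[occ] ** 2)))
        # frontal deviations are 5x occipital in the region map, diluted by
        # the channel-shared divergence component
        assert np.mean(fro_d) > 1.5 * np.mean(occ_d)

    def test_base_signal_invariant_across_task_and_week(self):
        """Averaged PSDs of week-1 rce and last-week mbi both point to the
        subject's own base profile, not any non-sibling's."""
        cfg = synth.CohortConfig(
            n_pairs=2, weeks=4, tasks=("rce", "mbi"), blink_rate=0.0, seed=7
        )
        gt = synth.make_ground_truth(cfg)
        scheme = F.SegmentationScheme()
        for subject in cfg.subjects:
            sib = subject + 1 if subject % 2 else subject - 1
            for week, task in [(1, "rce"), (4, "mbi")]:
                rec = synth.generate_recording(cfg, gt, subject, week, task)
                segs = F.segment_signal(rec, scheme)
                psd = np.mean(
                    [F.compute_psd(s, cfg.sampling_rate)[1] for s in segs], axis=0
                )[: len(gt.scalp_channels)]
                band = np.fft.rfftfreq(1000, 1 / 500.0)
                keep = (band >= 2) & (band <= 40)

                def match(cand):
                    prof = np.vstack(
                        [np.interp(band, gt.freqs, row) for row in cand]
                    )
                    return np.corrcoef(
                        np.log(psd[:, keep]).ravel(), np.log(prof[:, keep]).ravel()
                    )[0, 1]

                own = match(gt.base_profiles[subject])
                rivals = [
                    match(gt.base_profiles[s])
                    for s in cfg.subjects
                    if s not in (subject, sib)
                ]
                assert own > max(rivals)


class TestBlinks:
    @pytest.fixture
    def quiet_recording(self):
        cfg = synth.CohortConfig(
            n_pairs=1, weeks=1, tasks=("rce",), task_duration=60.0,
            blink_rate=0.0, seed=21,
        )
        gt = synth.make_ground_truth(cfg)
        return synth.generate_recording(cfg, gt, 1, 1, "rce")

    def test_rate_zero_is_identity(self, quiet_recording, rng):
        out = synth.inject_blinks(quiet_recording, 0.0, 0.4, rng)
        assert np.array_equal(out.data, quiet_recording.data)

    def test_event_count_and_frontal_coupling(self, quiet_recording, rng):
        rec = quiet_recording
        out = synth.inject_blinks(rec, 12.0, 0.4, rng)
        added = out.get_data(["VEO"])[0] - rec.get_data(["VEO"])[0]
        peaks, _ = sps.find_peaks(added, height=30.0, distance=50)
        assert 4 <= peaks.size <= 25  # Poisson(12) on a 60-s recording

        def corr(r):
            return np.corrcoef(r.get_data(["FP1"])[0], r.get_data(["VEO"])[0])[0, 1]

        assert corr(out) > corr(rec) + 0.1
        # posterior channels stay blink-free
        assert np.array_equal(out.get_data(["O1", "OZ", "O2"]),
                              rec.get_data(["O1", "OZ", "O2"]))

    def test_zero_frontal_gain_leaves_scalp_untouched(self, quiet_recording, rng):
        rec = quiet_recording
        out = synth.inject_blinks(rec, 12.0, 0.0, rng)
        assert np.array_equal(out.get_data(rec.scalp_names),
                              rec.get_data(rec.scalp_names))
        assert not np.array_equal(out.get_data(["VEO"]), rec.get_data(["VEO"]))

    def test_missing_eog_rejected(self, quiet_recording, rng):
        scalp_only = quiet_recording.copy(
            data=quiet_recording.get_data(quiet_recording.scalp_names),
            channel_names=quiet_recording.scalp_names,
        )
        with pytest.raises(ValueError, match="EOG"):
            synth.inject_blinks(scalp_only, 12.0, 0.4, rng)
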