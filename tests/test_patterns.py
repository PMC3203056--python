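"""Pattern-generator statistics: schedules, latencies, and the six models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stdplearn as sl
from stdplearn.patterns import GroupSpec, resolve_bimodal


def _rate_spec(model, n=20, m=10, sigma=1.0, p=1.0, **kw):
    return sl.PatternSpec(
        model_kind=model, n_total=n, n_pattern=m, pattern_duration=50.0,
        presentation_rate=1.5, background_rate=20.0,
        occurrence_prob=p, jitter_width=sigma, **kw,
    )


class TestSchedule:
    def test_degenerate_window_empty(self):
        assert len(sl.make_schedule(0.0, 1.5, 50.0, seed=1)) == 0

    def test_mean_onset_rate_matches_rejection_oracle(self):
        """Delivered onset rate stays nu despite non-overlap thinning.

        Oracle: independent rejection sampler that draws Poisson(nu) candidate
        sets until one is non-overlapping (exact for small windows).
        """
        T, nu, delta = 10_000_000.0, 1.5, 50.0
        counts = [len(sl.make_schedule(T, nu, delta, seed=s)) for s in range(10)]
        expected = nu * T / 1000.0
        sd = np.sqrt(expected)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(len(counts))
        # tiny-window oracle: exact enumeration of the acceptance probability
        rng = np.random.default_rng(0)
        T2 = 130.0  # at most two non-overlapping presentations fit
        oracle = []
        lam = (nu / 1000.0) / (1.0 - nu * delta / 1000.0)
        for _ in range(4000):
            n = rng.poisson(lam * (T2 - delta))
            cand = np.sort(rng.random(n) * (T2 - delta))
            kept = 0
            last = -np.inf
            for t in cand:
                if t - last >= delta:
                    kept += 1
                    last = t
            oracle.append(kept)
        ours = [len(sl.make_schedule(T2, nu, delta, seed=s)) for s in range(4000)]
        assert abs(np.mean(ours) - np.mean(oracle)) < 0.03

    def test_non_overlap_invariant(self):
        sched = sl.make_schedule(1_000_000.0, 1.5, 50.0, seed=3)
        assert np.all(np.diff(sched.onsets) >= 50.0)


class TestLatencies:
    def test_zero_duration_empty(self):
        assert sl.make_latencies(0.0, 20.0, seed=1).size == 0

    def test_poisson_mean_count(self):
        counts = [sl.make_latencies(50.0, 20.0, seed=s).size for s in range(10_000)]
        # Poisson(r0 * Delta) with r0*Delta = 1
        assert abs(np.mean(counts) - 1.0) < 3 * 1.0 / np.sqrt(10_000)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_support(self, seed):
        lat = sl.make_latencies(50.0, 20.0, seed=seed)
        assert np.all((lat >= 0) & (lat < 50.0))


class TestSpikeModels:
    def test_reliable_pattern_identical_across_presentations(self, short_schedule):
        spec = _rate_spec("S").with_random_latencies(5)
        ts = sl.gen_spike_pattern(spec, short_schedule, seed=9)
        # spike times relative to onsets repeat exactly for pattern afferents
        i = next(k for k in range(10) if spec.latencies[k].size)
        rel = []
        for o in short_schedule.onsets[:40]:
            seg = ts.trains[i][(ts.trains[i] >= o) & (ts.trains[i] < o + 50.0)]
            rel.append(np.sort(seg - o))
        ref = rel[0]
        for r in rel[1:]:
            assert r.size == ref.size
            assert np.allclose(r, ref, atol=1e-9)

    def test_long_run_rate_homogeneity(self, short_schedule):
        for model, p, sig in (("S", 1.0, 0.0), ("SD", 0.5, 0.0), ("SJ", 1.0, 5.0)):
            spec = _rate_spec(model, p=p, sigma=sig).with_random_latencies(5)
            ts = sl.gen_spike_pattern(spec, short_schedule, seed=9)
            assert np.all(np.abs(ts.rates() - 20.0) < 2.5), model

    def test_jitter_with_deletion_rejected(self):
        with pytest.raises(ValueError):
            _rate_spec("SJ", p=0.5, sigma=2.0)

    def test_deleted_pattern_is_poisson_like(self, short_schedule):
        spec = _rate_spec("SD", p=0.0).with_random_latencies(5)
        ts = sl.gen_spike_pattern(spec, short_schedule, seed=9)
        fanos = [
            sl.fano_empirical(ts, short_schedule, i)
            for i in range(10)
            if ts.trains[i].size
        ]
        assert abs(np.mean(fanos) - 1.0) < 0.15

    def test_determinism(self, short_schedule):
        spec = _rate_spec("SJ", sigma=2.0).with_random_latencies(5)
        a = sl.gen_spike_pattern(spec, short_schedule, seed=4)
        b = sl.gen_spike_pattern(spec, short_schedule, seed=4)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta, tb)


class TestRateModel:
    def test_counts_vary_across_presentations(self, short_schedule):
        spec = _rate_spec("R").with_random_latencies(5)
        ts, _ = sl.gen_rate_pattern(spec, short_schedule, seed=9)
        i = next(k for k in range(10) if spec.latencies[k].size)
        counts = sl.correlograms.presentation_counts(ts.trains[i], short_schedule)
        assert counts.std() > 0

    def test_expected_spikes_per_presentation(self, short_schedule):
        """Unit-area peaks: mean count = amplitude x number of latencies."""
        spec = _rate_spec("R", sigma=2.0).with_random_latencies(5)
        ts, _ = sl.gen_rate_pattern(spec, short_schedule, seed=9)
        for i in range(10):
            n_lat = spec.latencies[i].size
            if n_lat == 0:
                continue
            counts = sl.correlograms.presentation_counts(ts.trains[i], short_schedule)
            # background contributes ~0 inside presentations for pattern afferents
            se = 3 * np.sqrt(n_lat / len(short_schedule))
            assert abs(counts.mean() - n_lat) < se + 0.15

    def test_fano_near_one(self, short_schedule):
        spec = _rate_spec("R").with_random_latencies(5)
        ts, _ = sl.gen_rate_pattern(spec, short_schedule, seed=9)
        f = [sl.fano_empirical(ts, short_schedule, i) for i in range(10) if ts.trains[i].size]
        assert abs(np.mean(f) - 1.0) < 0.2

    def test_rate_functions_mean_near_background(self, short_schedule):
        spec = _rate_spec("R", sigma=2.0).with_random_latencies(5)
        _, rates = sl.gen_rate_pattern(spec, short_schedule, seed=9)
        grid, lam = rates.sample(0, 0.0, 20_000.0)
        assert abs(lam.mean() - 20.0) < 6.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            _rate_spec("R", amplitude=-1.0)


class TestBimodal:
    def _spec(self, kind, m1=50, m2=50, t1=10.0, t2=30.0, w1=2.0, w2=2.0):
        return sl.PatternSpec(
            model_kind=kind, n_total=200, n_pattern=100, pattern_duration=50.0,
            presentation_rate=1.5, background_rate=20.0,
            group_spec=(GroupSpec(m1, t1, w1), GroupSpec(m2, t2, w2)),
        )

    def test_group_correlogram_peak_location(self, short_schedule):
        spec = self._spec("SB")
        ts = sl.gen_bimodal_pattern(spec, short_schedule, seed=3)
        corr = sl.group_correlogram(ts, range(50), range(50, 100))
        peak = corr.lags[np.argmax(corr.values)]
        assert abs(peak - 20.0) < 3.0  # T2 - T1

    def test_label_swap_reflects_correlogram(self, short_schedule):
        spec = self._spec("SB")
        ts = sl.gen_bimodal_pattern(spec, short_schedule, seed=3)
        c12 = sl.group_correlogram(ts, range(50), range(50, 100))
        c21 = sl.group_correlogram(ts, range(50, 100), range(50))
        assert np.allclose(c12.values, c21.values[::-1], atol=1e-9)

    def test_sb_rb_share_population_correlogram(self, short_schedule):
        sb = sl.gen_bimodal_pattern(self._spec("SB"), short_schedule, seed=3)
        rb = sl.gen_bimodal_pattern(self._spec("RB"), short_schedule, seed=3)
        csb = sl.group_correlogram(sb, range(50), range(50, 100))
        crb = sl.group_correlogram(rb, range(50), range(50, 100))
        pred = sl.predicted_group_correlogram(self._spec("SB"))
        for c in (csb, crb):
            resid = np.abs(c.values - pred.values)
            assert resid.max() < 0.35 * pred.values.max()

    def test_oversized_groups_rejected(self):
        with pytest.raises(ValueError):
            self._spec("SB", m1=80, m2=80)


class TestEnvelope:
    def _spec(self):
        return sl.PatternSpec(
            model_kind="R_envelope", n_total=10, n_pattern=5,
            pattern_duration=100.0, presentation_rate=1.5,
            background_rate=20.0, jitter_width=2.0,
        ).with_random_latencies(11)

    def test_population_histogram_tracks_intensity(self):
        spec = self._spec()
        sched = sl.make_schedule(100_000.0, 1.5, 100.0, seed=2)
        ts, rates = sl.gen_envelope_pattern(spec, sched, seed=3)
        grid = np.arange(0.0, 5000.0, 10.0)
        lam = np.mean([rates.intensity(i, grid) for i in range(10)], axis=0)
        allsp = np.sort(np.concatenate([t[t < 5000.0] for t in ts.trains]))
        hist = np.histogram(allsp, bins=np.arange(0.0, 5010.0, 10.0))[0] / 10 / 10 * 1000.0
        # correlation between smoothed histogram and mean intensity
        k = np.ones(5) / 5
        hs = np.convolve(hist, k, mode="same")
        ls = np.convolve(lam, k, mode="same")
        r = np.corrcoef(hs, ls)[0, 1]
        assert r > 0.5

    def test_pattern_intensity_repeats_across_presentations(self):
        spec = self._spec()
        sched = sl.make_schedule(60_000.0, 1.5, 100.0, seed=2)
        _, rates = sl.gen_envelope_pattern(spec, sched, seed=3)
        i = next(k for k in range(5) if spec.latencies[k].size)
        o1, o2 = sched.onsets[:2]
        rel = np.arange(5.0, 95.0, 1.0)
        l1 = rates.intensity(i, o1 + rel) * rates.envelope(o1 + rel) ** 0
        # compare the modulated profiles
        m1 = rates.intensity(i, o1 + rel)
        m2 = rates.intensity(i, o2 + rel)
        assert np.corrcoef(m1, m2)[0, 1] > 0.95

    def test_rate_homogeneity_long_run(self):
        spec = self._spec()
        sched = sl.make_schedule(200_000.0, 1.5, 100.0, seed=2)
        ts, _ = sl.gen_envelope_pattern(spec, sched, seed=3)
        assert abs(np.mean(ts.rates()) - 20.0) < 3.0


class TestIO:
    def test_spike_file_roundtrip_byte_identical(self, tmp_path, short_schedule):
        spec = _rate_spec("S").with_random_latencies(5)
        ts = sl.gen_spike_pattern(spec, short_schedule, seed=4)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        sl.patterns.write_spikes(ts, p1)
        ts2 = sl.gen_spike_pattern(spec, short_schedule, seed=4)
        sl.patterns.write_spikes(ts2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = sl.patterns.read_spikes(p1, n_afferents=20, total_duration=ts.total_duration)
        for a, b in zip(ts.trains, back.trains):
            assert np.allclose(a, b, atol=1e-6)

    def test_schedule_roundtrip(self, tmp_path, short_schedule):
        p = tmp_path / "sched.tsv"
        sl.patterns.write_schedule(short_schedule, p)
        back = sl.patterns.read_schedule(p, short_schedule.total_duration, 50.0)
        assert np.allclose(back.onsets, short_schedule.onsets, atol=1e-6)
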