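import itertools

import numpy as np
import pytest

from spinefate import synthetic, traces
from spinefate.events import (
    DeconvolutionParams,
    EventTrain,
    deconvolve_oasis,
    estimate_g,
    estimate_noise_sd,
    event_rate,
    peak_amplitudes,
)


def ar1_from_spikes(spikes: dict[int, float], g: float, n: int) -> np.ndarray:
    c = np.zeros(n)
    for t in range(n):
        c[t] = (g * c[t - 1] if t else 0.0) + spikes.get(t, 0.0)
    return c


def brute_force_feasible(y, g, s_min, max_events=3):
    """Exhaustive minimum-SSE search over event placements whose jointly
    fitted amplitudes are all >= s_min (infeasible placements discarded).
    Independent oracle for the pooled solver on small problems."""
    T = len(y)
    best = (np.inf, None, None)
    for k in range(max_events + 1):
        for E in itertools.combinations(range(1, T), k):
            cols = [g ** np.arange(T, dtype=float)]
            for e in E:
                col = np.zeros(T)
                col[e:] = g ** np.arange(T - e, dtype=float)
                cols.append(col)
            A = np.array(cols).T
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            if sol[0] < -1e-9 or np.any(sol[1:] < s_min - 1e-9):
                continue
            resid = y - A @ sol
            sse = float(resid @ resid)
            if sse < best[0] - 1e-12:
                best = (sse, E, sol[1:])
    return best


class TestEstimateG:
    def test_pure_ar1_recovered(self, rng):
        g = 0.9
        n = 10000
        x = np.zeros(n)
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = g * x[t - 1] + eps[t]
        assert abs(estimate_g(x) - g) < 0.03

    def test_white_noise_declared_memoryless(self, rng):
        assert estimate_g(rng.normal(size=5000)) < 0.1

    def test_clipping_contract(self, rng):
        for _ in range(20):
            x = rng.normal(size=200).cumsum() + rng.normal(size=200)
            assert 0.0 <= estimate_g(x) <= 0.999

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_g(np.arange(10.0))


class TestNoiseSd:
    def test_white_noise_calibrated(self, rng):
        ests = [estimate_noise_sd(rng.normal(0, 0.1, 1200)) for _ in range(50)]
        assert abs(np.mean(ests) - 0.1) < 0.01


class TestDeconvolve:
    def test_zero_trace_no_events(self):
        c, ev = deconvolve_oasis(
            np.zeros(100), DeconvolutionParams(g=0.9, sn=None, s_min=2.5)
        )
        assert len(ev) == 0
        assert np.allclose(c, 0.0)

    def test_exact_recovery_of_planted_spikes(self):
        g = 0.95
        y = ar1_from_spikes({100: 5.0, 400: 4.0}, g, 600)
        c, ev = deconvolve_oasis(
            y, DeconvolutionParams(g=g, sn=None, s_min=2.5, optimize_g=0), 20.0
        )
        assert np.array_equal((ev.times * 20).round(), [100, 400])
        assert np.allclose(np.sort(ev.amplitudes), [4.0, 5.0], atol=1e-6)
        assert np.max(np.abs(c - y)) < 1e-9

    def test_subthreshold_spike_suppressed(self):
        g = 0.95
        y = ar1_from_spikes({100: 5.0, 250: 1.0, 400: 4.0}, g, 600)
        _, ev = deconvolve_oasis(
            y, DeconvolutionParams(g=g, sn=None, s_min=2.5, optimize_g=0), 20.0
        )
        assert np.array_equal((ev.times * 20).round(), [100, 400])

    @pytest.mark.parametrize("spikes", [
        {3: 5.0, 10: 4.0},
        {3: 5.0, 7: 1.0, 14: 3.0},
        {2: 2.6, 3: 2.6},
        {5: 1.0},
        {1: 8.0, 2: 3.0, 15: 2.5},
        {},
    ])
    def test_toy_traces_match_brute_force(self, spikes):
        g, s_min = 0.9, 2.5
        y = ar1_from_spikes(spikes, g, 20)
        sse, frames, amps = brute_force_feasible(y, g, s_min)
        c, ev = deconvolve_oasis(
            y, DeconvolutionParams(g=g, sn=None, s_min=s_min, optimize_g=0), 20.0
        )
        ours = tuple(int(round(t * 20)) for t in ev.times)
        assert ours == frames
        assert np.allclose(np.sort(amps), np.sort(ev.amplitudes), atol=1e-5)
        assert abs(float(np.sum((y - c) ** 2)) - sse) < 1e-6

    def test_random_toy_traces_match_brute_force(self, rng):
        """Oracle equivalence on random noiseless placements whose planted
        amplitudes are clearly above or clearly below threshold (the
        greedy solver is not guaranteed optimal in the narrow ambiguous
        band around s_min; see methods note)."""
        g, s_min, T = 0.9, 2.5, 20
        for _ in range(30):
            k = rng.integers(0, 4)
            frames = np.sort(rng.choice(np.arange(1, T), size=k, replace=False))
            spikes = {
                int(f): (rng.uniform(0.4, 1.1) if rng.random() < 0.4
                         else rng.uniform(3.0, 6.0))
                for f in frames
            }
            y = ar1_from_spikes(spikes, g, T)
            sse, bf_frames, bf_amps = brute_force_feasible(y, g, s_min)
            c, ev = deconvolve_oasis(
                y, DeconvolutionParams(g=g, sn=None, s_min=s_min, optimize_g=0),
                20.0,
            )
            ours = tuple(int(round(t * 20)) for t in ev.times)
            assert ours == bf_frames
            assert np.allclose(np.sort(bf_amps), np.sort(ev.amplitudes), atol=1e-5)
            assert abs(float(np.sum((y - c) ** 2)) - sse) < 1e-6

    def test_all_events_at_or_above_threshold(self, rng):
        z = rng.normal(size=600) + ar1_from_spikes({100: 6.0, 300: 5.0}, 0.9, 600)
        _, ev = deconvolve_oasis(
            z, DeconvolutionParams(g=0.9, sn=None, s_min=2.5, optimize_g=0), 20.0
        )
        assert np.all(ev.amplitudes >= 2.5 - 1e-9)

    def test_rate_monotone_nonincreasing_in_s_min(self, rng):
        z = rng.normal(size=400) + ar1_from_spikes(
            {50: 6.0, 150: 4.0, 250: 3.0, 350: 2.0}, 0.9, 400
        )
        counts = []
        for s_min in (0.5, 1.0, 2.0, 3.0, 4.0):
            _, ev = deconvolve_oasis(
                z, DeconvolutionParams(g=0.9, sn=None, s_min=s_min, optimize_g=0),
                20.0,
            )
            counts.append(len(ev))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_residual_monotone_in_s_min(self, rng):
        """Relaxing s_min can only improve (never worsen) the fit."""
        z = rng.normal(size=200) + ar1_from_spikes({40: 5.0, 120: 3.0}, 0.9, 200)
        rss = []
        for s_min in (4.0, 3.0, 2.0, 1.0, 0.5):
            c, _ = deconvolve_oasis(
                z, DeconvolutionParams(g=0.9, sn=None, s_min=s_min, optimize_g=0),
                20.0,
            )
            rss.append(float(np.sum((z - c) ** 2)))
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_oasis(np.zeros(50), DeconvolutionParams(g=1.5, s_min=1.0))


class TestEventRate:
    def test_simple_rate(self):
        ev = EventTrain(np.linspace(1, 59, 12), np.ones(12), 60.0)
        assert event_rate(ev) == pytest.approx(0.2)

    def test_mean_over_repeats(self):
        r1 = EventTrain(np.linspace(1, 50, 6), np.ones(6), 60.0)
        r2 = EventTrain(np.linspace(1, 50, 18), np.ones(18), 60.0)
        assert event_rate(r1, 60.0, repeats=[r1, r2]) == pytest.approx(0.2)

    def test_empty_repeats_rejected(self):
        ev = EventTrain(np.array([1.0]), np.array([1.0]), 60.0)
        with pytest.raises(ValueError):
            event_rate(ev, repeats=[])


class TestPeakAmplitudes:
    def test_no_events_empty(self):
        ev = EventTrain(np.array([]), np.array([]), 60.0)
        assert peak_amplitudes(np.zeros(1200), ev).size == 0

    def test_single_transient_amplitude(self):
        kern = synthetic.KERNELS["6s-like"]
        train = EventTrain(np.array([30.0]), np.array([1.0]), 60.0,
                           source="ground_truth")
        raw = synthetic.render_trace(train, kern, noise_sd=0.0,
                                     frame_rate_hz=20.0, duration_s=60.0, f0=100.0)
        dff = (raw - 100.0) / 100.0
        amps = peak_amplitudes(dff, train, window_s=1.0, frame_rate_hz=20.0)
        assert amps.size == 1
        assert abs(amps[0] - kern.amplitude_dff) < 0.02 * kern.amplitude_dff

    def test_kernel_amplitude_ratio_recovered(self, rng):
        """jGCaMP7b-like events are configured 1.5x brighter than
        GCaMP6s-like; the measured mean peak ratio recovers that factor."""
        means = {}
        for name in ("6s-like", "7b-like"):
            kern = synthetic.KERNELS[name]
            amps = []
            while len(amps) < 500:
                train = synthetic.simulate_event_train(0.1, 60, rng)
                if len(train) == 0:
                    continue
                f0 = 100.0
                raw = synthetic.render_trace(
                    train, kern, noise_sd=0.05, frame_rate_hz=10.0,
                    duration_s=60.0, f0=f0, rng=rng,
                )
                dff = (raw - f0) / f0
                amps.extend(peak_amplitudes(dff, train, frame_rate_hz=10.0))
            means[name] = np.mean(amps)
        ratio = means["7b-like"] / means["6s-like"]
        assert 1.35 <= ratio <= 1.65

    def test_event_past_trace_end_rejected(self):
        ev = EventTrain(np.array([59.9]), np.array([1.0]), 60.0)
        with pytest.raises(ValueError):
            peak_amplitudes(np.zeros(100), ev, frame_rate_hz=20.0)
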