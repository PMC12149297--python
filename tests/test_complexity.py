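import numpy as np
import pytest

from eegrc.complexity import (box_counting_fd, higuchi_fd, higuchi_k_grid,
                              kmax_scan, windowed_hfd)
from eegrc.synth import SignalSpec, gen_signal

from conftest import make_epoch


def naive_higuchi(x, ks):
    """Direct-summation Higuchi estimator (independent oracle)."""
    n = len(x)
    logs = []
    for k in ks:
        lm = []
        for m in range(1, k + 1):
            n_mk = (n - m) // k
            if n_mk < 1:
                continue
            idx = m - 1 + np.arange(n_mk + 1) * k
            length = np.sum(np.abs(np.diff(x[idx])))
            lm.append(length * (n - 1) / (n_mk * k) / k)
        logs.append(np.log(np.mean(lm)))
    slope = np.polyfit(-np.log(ks), logs, 1)[0]
    return slope


def naive_box_count(x, n_boxes):
    """Brute-force grid count: walk every interpolated segment."""
    y = (x - x.min()) / (x.max() - x.min())
    t = np.linspace(0.0, 1.0, len(x))
    eps = 1.0 / n_boxes
    boxes = set()
    for i in range(len(x) - 1):
        # sample the segment densely relative to the grid
        f = np.linspace(0.0, 1.0, 50)
        tt = t[i] + f * (t[i + 1] - t[i])
        yy = y[i] + f * (y[i + 1] - y[i])
        for a, b in zip(tt, yy):
            boxes.add((min(int(a / eps), n_boxes - 1),
                       min(int(b / eps), n_boxes - 1)))
    return len(boxes)


class TestBoxCounting:
    def test_straight_line_is_one_dimensional(self):
        line = np.linspace(-3.0, 7.0, 4096)
        assert box_counting_fd(line) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_nearly_plane_filling(self):
        vals = [box_counting_fd(gen_signal(SignalSpec("white", seed=s)))
                for s in range(20)]
        assert 1.85 <= np.mean(vals) <= 2.0

    def test_fbm_half_matches_two_minus_hurst(self):
        vals = [box_counting_fd(gen_signal(
            SignalSpec("fbm", seed=s, hurst=0.5))) for s in range(20)]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_counts_match_brute_force_grid(self):
        x = gen_signal(SignalSpec("fbm", fs=500, duration_s=1.024, seed=4,
                                  hurst=0.5))  # 512 samples
        _, (eps, counts) = box_counting_fd(x, return_counts=True)
        for e, c in zip(eps, counts):
            assert c == naive_box_count(x, int(round(1 / e)))

    def test_constant_signal_degenerate(self):
        assert box_counting_fd(np.ones(512)) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            box_counting_fd(np.arange(100.0))

    def test_amplitude_invariance(self):
        x = gen_signal(SignalSpec("fbm", seed=8, hurst=0.4))
        assert box_counting_fd(x) == pytest.approx(box_counting_fd(250 * x),
                                                   abs=1e-12)


class TestHiguchi:
    def test_straight_line(self):
        assert higuchi_fd(np.linspace(0, 1, 2000), 32) == pytest.approx(
            1.0, abs=0.01)

    def test_white_noise_limit(self):
        vals = [higuchi_fd(gen_signal(SignalSpec("white", seed=s)), 126)
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.05)

    def test_fbm_tracks_two_minus_hurst(self):
        vals = [higuchi_fd(gen_signal(SignalSpec("fbm", seed=s, hurst=0.7)),
                           126) for s in range(20)]
        assert np.mean(vals) == pytest.approx(1.3, abs=0.1)

    @pytest.mark.parametrize("kmax", [8, 32])
    def test_matches_direct_summation_oracle(self, kmax):
        x = gen_signal(SignalSpec("fbm", fs=500, duration_s=4, seed=3,
                                  hurst=0.5))
        ks = higuchi_k_grid(kmax)
        assert higuchi_fd(x, kmax) == pytest.approx(naive_higuchi(x, ks),
                                                    abs=1e-10)

    def test_amplitude_invariance(self):
        x = gen_signal(SignalSpec("white", seed=2))
        assert higuchi_fd(3.7 * x, 64) == pytest.approx(higuchi_fd(x, 64),
                                                        abs=1e-12)

    def test_kmax_bounds_enforced(self):
        x = np.arange(100.0)
        with pytest.raises(ValueError):
            higuchi_fd(x, 1)
        with pytest.raises(ValueError):
            higuchi_fd(x, 51)
        higuchi_fd(x, 50)  # boundary accepted

    def test_hurst_sweep_recovery_slope(self):
        hs = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
        means = []
        for h in hs:
            vals = [higuchi_fd(gen_signal(
                SignalSpec("fbm", seed=200 + s, hurst=h)), 126)
                for s in range(10)]
            means.append(np.mean(vals))
        slope = np.polyfit(2 - hs, means, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.2)

    def test_complexity_ordering(self):
        # FD(white) > FD(fbm, H=0.5) > FD(sinusoid), near-always per triple
        t = np.arange(7500) / 500.0
        wins = 0
        for s in range(20):
            w = higuchi_fd(gen_signal(SignalSpec("white", seed=s)), 64)
            b = higuchi_fd(gen_signal(SignalSpec("fbm", seed=s, hurst=0.5)),
                           64)
            tone = higuchi_fd(np.sin(2 * np.pi * (3 + s % 5) * t), 64)
            wins += (w > b > tone)
        assert wins >= 19


class TestWindowedHfd:
    def test_window_count_and_truncation(self):
        ep = make_epoch(gen_signal(SignalSpec("white", seed=0))[None])
        t = windowed_hfd(ep, kmax=126)
        assert t.params["n_windows"] == 15
        ep_long = make_epoch(gen_signal(
            SignalSpec("white", seed=0, duration_s=15.5))[None])
        assert windowed_hfd(ep_long, kmax=126).params["n_windows"] == 15

    def test_stationary_signal_windowed_close_to_whole_epoch(self):
        x = gen_signal(SignalSpec("white", seed=5))
        ep = make_epoch(x[None])
        whole = higuchi_fd(x, 126)
        assert abs(windowed_hfd(ep, kmax=126).values.iloc[0] - whole) < 0.05

    def test_default_kmax_follows_sampling_rate(self):
        ep500 = make_epoch(gen_signal(SignalSpec("white", seed=1))[None])
        assert windowed_hfd(ep500).params["kmax"] == 126
        ep128 = make_epoch(gen_signal(
            SignalSpec("white", fs=128, duration_s=8, seed=1))[None], fs=128.0)
        assert windowed_hfd(ep128).params["kmax"] == 32

    def test_window_too_short_for_kmax(self):
        ep = make_epoch(gen_signal(SignalSpec("white", seed=1))[None])
        with pytest.raises(ValueError, match="too short"):
            windowed_hfd(ep, kmax=300, window_s=1.0)


class TestKmaxScan:
    @staticmethod
    def _cohort(n=4):
        eps = []
        for s in range(n):
            ep = make_epoch(gen_signal(
                SignalSpec("fbm", seed=30 + s, hurst=0.4, duration_s=5))[None])
            ep.subject_id = f"s{s}"
            ep.group = "control" if s % 2 else "AD"
            eps.append(ep)
        return eps

    def test_single_kmax_selected_trivially(self):
        scan = kmax_scan(self._cohort(), [16])
        assert scan.selected_kmax == 16

    def test_selection_is_closest_to_curve_median(self):
        scan = kmax_scan(self._cohort(), [4, 8, 16, 32, 64])
        curve = scan.subject_means.mean(axis=1)
        expect = curve.index[np.argmin(np.abs(
            curve.to_numpy() - np.median(curve.to_numpy())))]
        assert scan.selected_kmax == expect
        # monotone curve: the middle element of an odd-length list wins
        diffs = np.diff(curve.to_numpy())
        if np.all(diffs < 0) or np.all(diffs > 0):
            assert scan.selected_kmax == curve.index[len(curve) // 2]

    def test_group_curves_shape(self):
        scan = kmax_scan(self._cohort(), [4, 8, 16])
        assert list(scan.group_means.index) == [4, 8, 16]
        assert set(scan.group_means.columns) == {"AD", "control"}
        assert scan.to_frame().shape == (6, 4)

    def test_empty_kmax_list_rejected(self):
        with pytest.raises(ValueError):
            kmax_scan(self._cohort(), [])

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            kmax_scan(self._cohort()[:1], [8])
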