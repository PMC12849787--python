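"""Montage selection, filtering, segmentation, labeling, balancing, z-scoring."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seizformer as sz
from conftest import make_record
from seizformer.errors import (BalancingError, MontageError, ParameterError,
                               SegmentationError)
from seizformer.preprocess import (CHB_MIT_16, TUH_20, zscore_apply,
                                   zscore_fit, load_windowset_npz,
                                   save_windowset_npz)


class TestMontage:
    def test_identity_and_reversal(self):
        rec = make_record(np.arange(12.0).reshape(3, 4))
        same = sz.select_montage(rec, rec.channel_labels)
        assert np.array_equal(same.data, rec.data)
        rev = sz.select_montage(rec, rec.channel_labels[::-1])
        assert np.array_equal(rev.data, rec.data[::-1])

    def test_case_and_whitespace_insensitive(self):
        rec = sz.EEGRecord(data=np.zeros((2, 10)), fs=10,
                           channel_labels=["FP1-F7", "F7-T7"])
        out = sz.select_montage(rec, ["fp 1- f 7"])
        assert out.channel_labels == ["FP1-F7"]

    def test_missing_channel_named_in_error(self):
        rec = make_record(np.zeros((2, 10)))
        with pytest.raises(MontageError, match="XX-YY"):
            sz.select_montage(rec, ["XX-YY"])

    def test_presets_cover_paper_channel_sets(self):
        rec16 = sz.make_subject(sz.SimConfig(duration_s=5, seizure_rate=0, seed=0))
        out = sz.select_montage(rec16, "chb-mit-16")
        assert out.n_channels == 16
        assert out.channel_labels == CHB_MIT_16
        assert len(TUH_20) == 20 and len(set(TUH_20)) == 20


class TestBandpass:
    fs = 256.0

    def _tone(self, freq):
        """Smooth-onset tone (Tukey window) so the measurement reflects the
        filter's frequency response, not the onset discontinuity."""
        from scipy.signal.windows import tukey
        t = np.arange(0, 10, 1 / self.fs)
        x = np.sin(2 * np.pi * freq * t) * tukey(t.size, 0.2)
        return make_record(x[None, :], fs=self.fs)

    def test_stopband_tone_suppressed(self):
        rec = self._tone(60.0)
        out = sz.bandpass(rec, 0.5, 48.0)
        assert np.sqrt((out.data**2).mean()) < 0.05 * np.sqrt((rec.data**2).mean())

    def test_passband_tone_preserved(self):
        rec = self._tone(10.0)
        out = sz.bandpass(rec, 0.5, 48.0)
        ratio = np.sqrt((out.data**2).mean()) / np.sqrt((rec.data**2).mean())
        assert abs(ratio - 1.0) < 0.10

    def test_zeros_map_to_zeros(self):
        out = sz.bandpass(make_record(np.zeros((2, 2560))), 0.5, 48.0)
        assert np.allclose(out.data, 0.0)

    def test_band_outside_nyquist_rejected(self):
        rec = self._tone(10.0)
        with pytest.raises(ParameterError):
            sz.bandpass(rec, 0.5, 200.0)
        with pytest.raises(ParameterError):
            sz.bandpass(rec, 50.0, 40.0)


class TestSegmentation:
    def test_sixty_seconds_gives_119_windows(self):
        rec = make_record(np.zeros((2, 60 * 256)))
        assert len(sz.segment_windows(rec, 1.0, 0.5)) == 119

    def test_record_equal_to_window_gives_one(self):
        rec = make_record(np.zeros((2, 256)))
        ws = sz.segment_windows(rec, 1.0, 0.5)
        assert len(ws) == 1

    def test_two_seconds_gives_three(self):
        rec = make_record(np.zeros((2, 512)))
        ws = sz.segment_windows(rec, 1.0, 0.5)
        assert len(ws) == 3
        assert np.allclose(ws.starts, [0.0, 0.5, 1.0])

    def test_too_short_record_raises(self):
        rec = make_record(np.zeros((2, 100)))
        with pytest.raises(SegmentationError):
            sz.segment_windows(rec, 1.0, 0.5)

    @given(
        n_samples=st.integers(min_value=16, max_value=400),
        window_idx=st.sampled_from([4, 8, 16]),
        overlap=st.sampled_from([Fraction(0), Fraction(1, 4),
                                 Fraction(1, 2), Fraction(3, 4)]),
    )
    def test_window_count_matches_exact_enumeration(self, n_samples,
                                                    window_idx, overlap):
        """K = floor((T - w)/step) + 1 vs brute-force start enumeration."""
        fs = 8
        T = Fraction(n_samples, fs)
        w = Fraction(window_idx, fs)
        if T < w:
            return
        step = w * (1 - overlap)
        count, k = 0, 0
        while k * step + w <= T:
            count += 1
            k += 1
        rec = make_record(np.zeros((2, n_samples)), fs=float(fs))
        ws = sz.segment_windows(rec, float(w), float(overlap))
        assert len(ws) == count


class TestLabeling:
    def _ws(self):
        rec = make_record(np.zeros((1, 4 * 16)), fs=16.0)
        return sz.segment_windows(rec, 1.0, 0.0)   # windows at 0,1,2,3 s

    def test_full_overlap_and_no_overlap(self):
        ws = sz.label_windows(self._ws(), [(1.0, 2.0)])
        assert ws.labels.tolist() == [0, 1, 0, 0]

    def test_partial_overlap_below_half_is_negative(self):
        # window [1, 2) vs interval [1.6, 10): 0.4 overlap < 0.5
        ws = sz.label_windows(self._ws(), [(1.6, 10.0)])
        assert ws.labels[1] == 0

    def test_tie_at_exactly_half_is_positive(self):
        ws = sz.label_windows(self._ws(), [(1.5, 10.0)])
        assert ws.labels[1] == 1

    def test_interval_order_irrelevant(self):
        ivs = [(2.2, 3.4), (0.0, 0.9)]
        a = sz.label_windows(self._ws(), ivs)
        b = sz.label_windows(self._ws(), ivs[::-1])
        assert a.labels.tolist() == b.labels.tolist()


class TestBalancing:
    def _ws(self, n_neg, n_pos):
        wins = [sz.Window(data=np.full((1, 4), float(i)), label=int(i < n_pos),
                          start_s=float(i)) for i in range(n_neg + n_pos)]
        return sz.WindowSet(windows=wins, fs=4.0, channel_labels=["A-B"])

    def test_counts_equalized(self):
        out = sz.balance_1to1(self._ws(100, 40), seed=0)
        y = out.labels
        assert (y == 1).sum() == 100 and (y == 0).sum() == 100

    def test_already_balanced_untouched(self):
        ws = self._ws(10, 10)
        assert sz.balance_1to1(ws, seed=0) is ws

    def test_oversampled_windows_are_copies(self):
        ws = self._ws(20, 5)
        out = sz.balance_1to1(ws, seed=1)
        originals = {w.data.tobytes() for w in ws.windows if w.label == 1}
        extras = out.windows[len(ws.windows):]
        assert all(w.label == 1 and w.data.tobytes() in originals for w in extras)

    def test_deterministic_given_seed(self):
        ws = self._ws(30, 7)
        a = sz.balance_1to1(ws, seed=5)
        b = sz.balance_1to1(ws, seed=5)
        assert [w.start_s for w in a.windows] == [w.start_s for w in b.windows]

    def test_single_class_rejected(self):
        wins = [sz.Window(data=np.zeros((1, 4)), label=0, start_s=0.0)]
        ws = sz.WindowSet(windows=wins, fs=4.0, channel_labels=["A-B"])
        with pytest.raises(BalancingError):
            sz.balance_1to1(ws, seed=0)


class TestZScore:
    def test_fit_apply_standardizes(self, labeled_windows):
        stats = zscore_fit(labeled_windows)
        out = zscore_apply(labeled_windows, stats)
        x = out.stacked()
        assert np.allclose(x.mean(axis=(0, 2)), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=(0, 2)), 1.0, atol=1e-6)

    def test_constant_channel_floored_to_zero(self):
        wins = [sz.Window(data=np.full((2, 4), 3.0), label=0, start_s=0.0)]
        ws = sz.WindowSet(windows=wins, fs=4.0, channel_labels=["A-B", "C-D"])
        out = zscore_apply(ws, zscore_fit(ws))
        assert np.allclose(out.windows[0].data, 0.0)

    def test_train_stats_leave_test_uncentered(self, labeled_windows):
        n = len(labeled_windows) // 2
        train = sz.WindowSet(windows=labeled_windows.windows[:n],
                             fs=labeled_windows.fs,
                             channel_labels=labeled_windows.channel_labels)
        test = sz.WindowSet(windows=labeled_windows.windows[n:],
                            fs=labeled_windows.fs,
                            channel_labels=labeled_windows.channel_labels)
        out = zscore_apply(test, zscore_fit(train))
        assert np.abs(out.stacked().mean(axis=(0, 2))).max() > 1e-4


def test_windowset_npz_roundtrip(labeled_windows, tmp_path):
    p = tmp_path / "ws.npz"
    save_windowset_npz(labeled_windows, p)
    back = load_windowset_npz(p)
    assert len(back) == len(labeled_windows)
    assert np.array_equal(back.stacked(), labeled_windows.stacked())
    assert np.array_equal(back.labels, labeled_windows.labels)
    assert back.channel_labels == labeled_windows.channel_labels
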