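"""Filtering, segmentation and recording I/O."""

import numpy as np
import pytest
import yaml

from oracles import sine_amplitude
from ulameeg.preprocess import (
    EEGRecording,
    LoadError,
    butterworth_lowpass,
    clean_recording,
    load_recording,
    notch_filter,
    segment_recording,
)


def sine(f, fs, dur):
    t = np.arange(int(fs * dur)) / fs
    return np.sin(2 * np.pi * f * t)


class TestNotch:
    def test_zeros_stay_zeros(self):
        assert np.allclose(notch_filter(np.zeros(512), 128), 0)

    def test_attenuates_50hz_passes_10hz(self):
        fs = 128
        y50 = notch_filter(sine(50, fs, 8), fs)
        y10 = notch_filter(sine(10, fs, 8), fs)
        assert sine_amplitude(y50, fs, 50) < 0.1
        assert abs(sine_amplitude(y10, fs, 10) - 1.0) < 0.05

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            notch_filter(np.zeros(512), fs=90.0, f0=50.0)

    def test_zero_phase(self):
        """Cross-correlation peak between input and output sits at lag 0."""
        fs = 128
        x = np.random.default_rng(9).standard_normal(8 * fs)
        y = notch_filter(x, fs)
        lags = np.arange(-64, 65)
        xc = [np.dot(x[64:-64], y[64 + l : len(y) - 64 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(512, 3.7)
        assert np.allclose(butterworth_lowpass(x, 256), x, rtol=1e-6)

    def test_passband_and_stopband(self):
        fs = 256
        y10 = butterworth_lowpass(sine(10, fs, 8), fs)
        y100 = butterworth_lowpass(sine(100, fs, 8), fs)
        assert abs(sine_amplitude(y10, fs, 10) - 1.0) < 0.02
        assert sine_amplitude(y100, fs, 100) < 0.15

    def test_cutoff_clamped_at_nyquist_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            y = butterworth_lowpass(sine(10, 100, 4), fs=100, cutoff=60)
        assert np.all(np.isfinite(y))

    def test_rejects_nonfinite(self):
        x = np.zeros(128)
        x[5] = np.nan
        with pytest.raises(ValueError):
            butterworth_lowpass(x, 128)

    def test_filter_order_commutes(self):
        """Notch-then-lowpass equals lowpass-then-notch on linear signals.

        The reflect-padding of the zero-phase pass is not time-invariant at
        the boundaries, so commutation is asserted on the interior samples.
        """
        fs = 128
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2048)
        a = butterworth_lowpass(notch_filter(x, fs), fs)
        b = notch_filter(butterworth_lowpass(x, fs), fs)
        assert np.sqrt(np.mean((a - b)[256:-256] ** 2)) < 1e-6


class TestSegmentation:
    @pytest.mark.parametrize("samples,expected", [(2048, 4), (2047, 3), (511, 0), (512, 1)])
    def test_floor_rule(self, samples, expected):
        rec = EEGRecording(
            data=np.zeros((2, samples)), fs=128, channel_names=["a", "b"],
            label="normal", subject_id="s",
        )
        segs = segment_recording(rec, 512)
        assert len(segs) == expected
        for i, s in enumerate(segs):
            assert s.data.shape == (2, 512)
            assert s.label == "normal" and s.index == i

    def test_segments_tile_the_recording_in_order(self):
        data = np.arange(2 * 1300).reshape(2, 1300).astype(float)
        rec = EEGRecording(data=data, fs=128, channel_names=["a", "b"],
                           label="ADHD", subject_id="s")
        segs = segment_recording(rec, 512)
        rebuilt = np.concatenate([s.data for s in segs], axis=1)
        assert np.array_equal(rebuilt, data[:, : 2 * 512])


class TestLoad:
    def _write(self, tmp_path, data, meta, name="rec.csv"):
        p = tmp_path / name
        np.savetxt(p, data, delimiter=",")
        with open(p.with_suffix(".csv.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)
        return p

    def test_roundtrip_channels_major(self, tmp_path):
        data = np.random.default_rng(0).standard_normal((19, 1024))
        p = self._write(tmp_path, data, {"fs": 128, "label": "ADHD"})
        rec = load_recording(p)
        assert rec.data.shape == (19, 1024) and rec.fs == 128
        assert np.allclose(rec.data, data, atol=1e-5)

    def test_orientation_flag_transposes(self, tmp_path):
        data = np.random.default_rng(1).standard_normal((1024, 19))
        p = self._write(tmp_path, data,
                        {"fs": 128, "label": "normal",
                         "orientation": "samples_x_channels"})
        rec = load_recording(p)
        assert rec.data.shape == (19, 1024)

    def test_nan_cell_names_location(self, tmp_path):
        data = np.zeros((3, 8))
        data[1, 5] = np.nan
        p = self._write(tmp_path, data, {"fs": 128, "label": "ADHD"})
        with pytest.raises(LoadError, match="row 1, column 5"):
            load_recording(p)

    def test_missing_fs_is_an_error(self, tmp_path):
        p = self._write(tmp_path, np.zeros((2, 8)), {"label": "ADHD"})
        with pytest.raises(LoadError, match="fs"):
            load_recording(p)

    def test_unreadable_edf_is_a_load_error(self, tmp_path):
        p = tmp_path / "bogus.edf"
        p.write_bytes(b"not an edf file")
        with pytest.raises(LoadError):
            load_recording(p, label="ADHD")


def test_clean_recording_preserves_shape_and_label():
    rng = np.random.default_rng(3)
    rec = EEGRecording(data=rng.standard_normal((4, 1024)), fs=128,
                       channel_names=list("abcd"), label="ADHD", subject_id="x")
    out = clean_recording(rec)
    assert out.data.shape == rec.data.shape
    assert out.label == "ADHD" and out.subject_id == "x"
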