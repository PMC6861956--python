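"""Segmentation, Z-score normalization, synthetic records, WFDB ingest."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owfb import (
    ECGRecord,
    Epoch,
    ZeroVarianceError,
    read_wfdb,
    segment,
    synthesize_record,
    write_wfdb,
    zscore,
)

HOLTER_DURATION_S = 2 * 3600 + 10 * 60 + 12  # 2 h 10 min 12 s


def _record(n, fs=128.0, channels=3, **kw):
    rng = np.random.default_rng(0)
    chans = {f"CH{i + 1}": rng.standard_normal(n) for i in range(channels)}
    return ECGRecord(channels=chans, fs=fs, subject_id="t", **kw)


class TestSegment:
    def test_holter_duration_gives_26_epochs_per_channel(self):
        n = round(HOLTER_DURATION_S * 128)  # 999,936 samples
        assert n == 999_936
        epochs = segment(_record(n))
        assert len(epochs) == 26 * 3
        assert all(len(e.samples) == 38_400 for e in epochs)

    def test_windows_are_consecutive_and_non_overlapping(self):
        rec = _record(3 * 38_400 + 100, channels=1)
        epochs = segment(rec)
        assert len(epochs) == 3
        joined = np.concatenate([e.samples for e in epochs])
        np.testing.assert_array_equal(joined, rec.channels["CH1"][:3 * 38_400])

    def test_short_record_yields_empty_list(self, caplog):
        assert segment(_record(100)) == []

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(duration=st.floats(min_value=10.0, max_value=20_000.0))
    def test_epoch_count_matches_brute_force_windowing(self, duration):
        fs = 128.0
        n = round(duration * fs)
        window = round(300.0 * fs)
        rec = ECGRecord(
            channels={"CH1": np.zeros(n)}, fs=fs, subject_id="x"
        )
        got = len(segment(rec))
        brute = 0
        start = 0
        while start + window <= n:
            brute += 1
            start += window
        assert got == brute


class TestZscore:
    def test_three_point_example(self):
        ep = Epoch(np.array([1.0, 2.0, 3.0]), 128.0, "s", "CH1", "LRHT")
        z = zscore(ep)
        root = np.sqrt(1.5)
        np.testing.assert_allclose(z.samples, [-root, 0.0, root], atol=1e-12)

    def test_population_convention(self):
        ep = Epoch(np.random.default_rng(1).standard_normal(500) * 7 + 3,
                   128.0, "s", "CH1", "LRHT")
        z = zscore(ep)
        assert z.samples.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.samples.std() == pytest.approx(1.0, abs=1e-9)  # ddof=0

    def test_idempotent(self):
        ep = Epoch(np.random.default_rng(2).standard_normal(100),
                   128.0, "s", "CH1", "LRHT")
        z1 = zscore(ep)
        z2 = zscore(z1)
        np.testing.assert_allclose(z1.samples, z2.samples, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        ep = Epoch(x, 128.0, "s", "CH1", "LRHT")
        scaled = Epoch(a * x + b, 128.0, "s", "CH1", "LRHT")
        np.testing.assert_allclose(
            zscore(ep).samples, zscore(scaled).samples, atol=1e-10
        )

    def test_flatline_raises_with_epoch_id(self):
        ep = Epoch(np.full(10, 4.2), 128.0, "subj9", "CH2", "LRHT",
                   epoch_index=3)
        with pytest.raises(ZeroVarianceError, match="subj9/CH2/3"):
            zscore(ep)


class TestSynthesize:
    def test_deterministic_for_fixed_seed(self):
        r1 = synthesize_record(duration_s=300, seed=7)
        r2 = synthesize_record(duration_s=300, seed=7)
        for c in r1.channels:
            np.testing.assert_array_equal(r1.channels[c], r2.channels[c])

    def test_holter_duration_segments_into_26_epochs(self):
        rec = synthesize_record(duration_s=HOLTER_DURATION_S, noise_sd=0.0)
        assert len(segment(rec)) == 26 * 3

    def test_noiseless_60_bpm_is_periodic_with_period_128(self):
        rec = synthesize_record(duration_s=300, heart_rate_bpm=60.0,
                                noise_sd=0.0, seed=1)
        for sig in rec.channels.values():
            assert np.abs(sig[:-128] - sig[128:]).max() == 0.0

    def test_three_channels_at_128_hz(self):
        rec = synthesize_record(duration_s=300)
        assert list(rec.channels) == ["CH1", "CH2", "CH3"]
        assert rec.fs == 128.0

    @pytest.mark.parametrize(
        "kw", [dict(duration_s=100), dict(heart_rate_bpm=0),
               dict(noise_sd=-1), dict(class_label="XYZ")]
    )
    def test_invalid_profiles_rejected(self, kw):
        with pytest.raises(ValueError):
            synthesize_record(**kw)


class TestWFDB:
    @pytest.mark.parametrize("fmt", [16, 80])
    def test_round_trip(self, tmp_path, fmt):
        rec = synthesize_record(duration_s=300, noise_sd=0.05, seed=3)
        gain = 1000.0 if fmt == 16 else 80.0
        header = write_wfdb(rec, tmp_path, "rt", fmt=fmt, gain=gain)
        back = read_wfdb(header)
        assert list(back.channels) == ["CH1", "CH2", "CH3"]
        assert back.fs == 128.0
        for c in rec.channels:
            # exact to the quantization step of the chosen format
            assert np.abs(back.channels[c] - rec.channels[c]).max() <= 0.5 / gain

    def test_path_without_suffix(self, tmp_path):
        rec = synthesize_record(duration_s=300, seed=1)
        write_wfdb(rec, tmp_path, "nosuf")
        back = read_wfdb(tmp_path / "nosuf")
        assert back.n_samples == rec.n_samples

    def test_single_channel_record(self, tmp_path):
        rec = ECGRecord(channels={"V5": np.sin(np.arange(500) / 5.0)},
                        fs=250.0, subject_id="one")
        back = read_wfdb(write_wfdb(rec, tmp_path, "one", gain=2000))
        assert list(back.channels) == ["V5"]
        np.testing.assert_allclose(
            back.channels["V5"], rec.channels["V5"], atol=1e-3
        )

    def test_missing_header_raises_with_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nothere"):
            read_wfdb(tmp_path / "nothere.hea")

    def test_unsupported_format_rejected(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad 1 128 100\nbad.dat 212 200 12 0 0 0 0 X\n")
        (tmp_path / "bad.dat").write_bytes(b"\x00" * 150)
        with pytest.raises(ValueError, match="format"):
            read_wfdb(tmp_path / "bad.hea")
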