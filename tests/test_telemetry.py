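"""Codec, ADC transfer and baseline-normalization behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fixmon import telemetry as tel
from fixmon.errors import BlockSizeError, CountRangeError, InsufficientDataError


def make_frames(counts_rows, t0=0, dt=100):
    return [
        tel.SampleFrame(timestamp_ms=t0 + i * dt, counts=tuple(row))
        for i, row in enumerate(counts_rows)
    ]


counts_strategy = st.lists(
    st.tuples(*[st.integers(tel.INT16_MIN, tel.INT16_MAX)] * 4),
    min_size=10, max_size=10,
)


class TestCodec:
    def test_block_is_exactly_150_bytes(self, config):
        frames = make_frames([(0, 0, 0, 0)] * 10)
        block = tel.encode_block(frames, config)
        assert len(block) == 150
        assert len(tel.encode_stream(frames[:1], config)) == 15

    def test_zero_frames_have_zero_payload_outside_sync_and_timestamp(self, config):
        frames = make_frames([(0, 0, 0, 0)] * 10)
        block = tel.encode_block(frames, config)
        for k in range(10):
            frame = block[k * 15 : (k + 1) * 15]
            assert frame[:3] == config.sync_mark
            assert frame[3:11] == b"\x00" * 8  # count payload
        # first frame: timestamp zero too
        assert block[11:15] == b"\x00" * 4

    def test_wrong_frame_count_rejected(self, config):
        with pytest.raises(BlockSizeError):
            tel.encode_block(make_frames([(0, 0, 0, 0)] * 9), config)

    def test_count_overflow_rejected(self):
        with pytest.raises(CountRangeError):
            tel.SampleFrame(timestamp_ms=0, counts=(2**15, 0, 0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(counts=counts_strategy, t0=st.integers(0, 2**31))
    def test_round_trip_identity(self, counts, t0):
        config = tel.AcquisitionConfig()
        frames = make_frames(counts, t0=t0)
        decoded, report = tel.decode_stream(tel.encode_block(frames, config), config)
        assert decoded == frames
        assert report.events == [] and report.frames_lost_estimate == 0


class TestResync:
    def _frames(self, n=30):
        rng = np.random.default_rng(7)
        counts = rng.integers(-30000, 30000, size=(n, 4))
        return make_frames(counts.tolist())

    def test_clean_stream_no_resync(self, config):
        frames = self._frames()
        decoded, report = tel.decode_stream(tel.encode_stream(frames, config), config)
        assert decoded == frames and report.bytes_skipped == 0

    def test_seven_byte_deletion_loses_one_frame(self, config):
        """A mid-block deletion costs the damaged frame only, one resync."""
        frames = self._frames(10)
        data = tel.encode_stream(frames, config)
        k = 4  # corrupt frame 4 starting at its sync mark
        corrupted = data[: k * 15] + data[k * 15 + 7 :]
        decoded, report = tel.decode_stream(corrupted, config)
        assert decoded == frames[:k] + frames[k + 1 :]
        assert len(report.events) == 1
        assert report.frames_decoded + report.frames_lost_estimate == len(frames)

    @settings(derandomize=True, max_examples=60)
    @given(
        start=st.integers(0, 30 * 15 - 1),
        length=st.integers(1, 14),
    )
    def test_single_deletion_loses_at_most_two_frames(self, start, length):
        """Contiguous corruption: <=2 frames lost, later frames recovered exactly."""
        config = tel.AcquisitionConfig()
        frames = self._frames(30)
        data = tel.encode_stream(frames, config)
        corrupted = data[:start] + data[start + length :]
        decoded, _ = tel.decode_stream(corrupted, config)
        originals = [f for f in decoded if f in frames]
        missing = [f for f in frames if f not in decoded]
        assert len(missing) <= 2
        # every frame strictly after the damaged byte range is recovered
        first_safe = -(-(start + length) // 15)  # first frame fully beyond the cut
        for f in frames[first_safe + 1 :]:
            assert f in originals

    def test_random_bytes_without_sync_yield_nothing(self, config):
        rng = np.random.default_rng(11)
        junk = bytes(b for b in rng.integers(0, 170, 500).tolist())  # never 0xAA
        decoded, report = tel.decode_stream(junk, config)
        assert decoded == [] and report.frames_decoded == 0

    def test_empty_stream(self, config):
        decoded, report = tel.decode_stream(b"", config)
        assert decoded == [] and report.events == []


class TestAdcTransfer:
    def test_zero_count_zero_offset_is_zero_newtons(self, config):
        frame = tel.SampleFrame(0, (0, 0, 0, 0))
        assert np.allclose(tel.counts_to_force(frame, config), 0.0)

    def test_linear_map_with_scale(self):
        config = tel.AcquisitionConfig(per_cell_scale=(0.01,) * 4)
        frame = tel.SampleFrame(0, (-5000, 0, 1000, -5000))
        np.testing.assert_allclose(
            tel.counts_to_force(frame, config), [-50.0, 0.0, 10.0, -50.0]
        )

    def test_full_scale_counts_stay_within_sensor_range(self, config):
        """Extreme counts map inside the 0-1 kN per-cell sensor range."""
        hi = tel.counts_to_force(tel.SampleFrame(0, (tel.INT16_MAX,) * 4), config)
        lo = tel.counts_to_force(tel.SampleFrame(0, (tel.INT16_MIN,) * 4), config)
        assert np.all(np.abs(hi) <= 1000.0 + 1e-9)
        assert np.all(np.abs(lo) <= 1000.0 * (2**15) / (2**15 - 1) + 1e-9)

    def test_force_count_inversion(self, config):
        forces = np.array([[12.3, -450.0, 0.0, 999.0]])
        counts = tel.force_to_counts(forces, config)
        back = counts * np.asarray(config.per_cell_scale)
        np.testing.assert_allclose(back, forces, atol=config.per_cell_scale[0])


class TestBaseline:
    def _rest(self, forces, config):
        counts = tel.force_to_counts(np.asarray(forces), config)
        return make_frames(counts.tolist())

    def test_constant_load_mean(self, config):
        frames = self._rest([[3.0] * 4] * 50, config)
        base = tel.compute_baseline(frames, config)
        np.testing.assert_allclose(base.per_cell_mean, 3.0, atol=0.02)

    def test_alternating_load_mean_zero(self, config):
        frames = self._rest([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]] * 25, config)
        base = tel.compute_baseline(frames, config)
        assert abs(base.per_cell_mean[0]) < 0.02

    def test_linear_drift_mean_is_midpoint(self, config):
        """Mean of a linear ramp s*t over [0, T] is s*T/2."""
        slope, T, n = 0.4, 100.0, 1001  # N per s
        t = np.linspace(0, T, n)
        forces = np.tile((slope * t)[:, None], (1, 4))
        frames = self._rest(forces, config)
        base = tel.compute_baseline(frames, config)
        np.testing.assert_allclose(base.per_cell_mean, slope * T / 2, atol=0.05)

    def test_empty_window_rejected(self, config):
        with pytest.raises(InsufficientDataError):
            tel.compute_baseline([], config)

    def test_normalized_rest_window_has_zero_baseline(self, config):
        rng = np.random.default_rng(3)
        forces = rng.normal(5.0, 0.2, size=(200, 4))
        frames = self._rest(forces, config)
        base = tel.compute_baseline(frames, config)
        _, normalized = tel.apply_baseline(frames, base, config)
        assert np.allclose(normalized.mean(axis=0), 0.0, atol=1e-9)

    def test_step_height_preserved_after_normalization(self, config):
        rest = np.full((100, 4), 2.5)
        loaded = rest + 10.0
        frames = self._rest(np.vstack([rest, loaded]), config)
        base = tel.compute_baseline(frames[:100], config)
        _, normalized = tel.apply_baseline(frames, base, config)
        step = normalized[100:].mean(axis=0) - normalized[:100].mean(axis=0)
        np.testing.assert_allclose(step, 10.0, atol=0.05)

    def test_normalization_is_pure_shift_variance_unchanged(self, config):
        rng = np.random.default_rng(4)
        forces = rng.normal(0.0, 1.0, size=(300, 4))
        frames = self._rest(forces, config)
        _, raw = tel.frames_to_forces(frames, config)
        base = tel.compute_baseline(frames, config)
        _, normalized = tel.apply_baseline(frames, base, config)
        np.testing.assert_allclose(
            raw.var(axis=0), normalized.var(axis=0), rtol=1e-12
        )


class TestExternalFormats:
    def test_csv_columns_and_sum(self, config, tmp_path):
        frames = make_frames([(100, 200, 300, 400)] * 5)
        path = tmp_path / "trace.csv"
        tel.export_csv(path, frames, config)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == tel.CSV_COLUMNS
        np.testing.assert_allclose(
            df["sum_N"], df[tel.CSV_COLUMNS[1:5]].sum(axis=1)
        )

    def test_metadata_sidecar_round_trip(self, config, tmp_path):
        path = tmp_path / "meta.json"
        tel.write_metadata(path, config, session_start="2024-03-01T08:00:00Z")
        meta = tel.read_metadata(path)
        assert meta["session_start"] == "2024-03-01T08:00:00Z"
        assert bytes.fromhex(meta["config"]["sync_mark"]) == config.sync_mark
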