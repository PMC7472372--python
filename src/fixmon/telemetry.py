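"""Framed load-cell telemetry: binary codec, ADC conversion, baseline normalization.

The acquisition firmware streams four-channel load-cell samples in fixed-size
frames so a receiver can resynchronize after data loss.  Wire format of one
frame (15 bytes, little-endian):

====== ======= ==========================================================
bytes  field   content
====== ======= ==========================================================
0-2    sync    3-byte synchronization mark (default ``AA 55 A5``)
3-10   counts  four signed 16-bit ADC counts, one per load cell
11-14  time    unsigned 32-bit timestamp, milliseconds since session start
====== ======= ==========================================================

Ten frames form a 150-byte block, the transmission unit of the acquisition
loop.  The hardware publishes only the mark width and the block size, so the
field order and endianness here are this package's own convention; they are
documented byte-exact above and frozen by the round-trip tests.

Wall-clock anchoring of a session lives in the JSON metadata sidecar (see
:func:`write_metadata`), not in individual frames.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BlockSizeError, CountRangeError, InsufficientDataError

FRAME_SIZE = 15
BLOCK_FRAMES = 10
BLOCK_SIZE = FRAME_SIZE * BLOCK_FRAMES  # 150 bytes
DEFAULT_SYNC_MARK = b"\xaa\x55\xa5"
N_CELLS = 4
INT16_MIN, INT16_MAX = -(2**15), 2**15 - 1
#: per-cell sensor range of the load cells, newtons
FULL_SCALE_N = 1000.0
#: default rest window used to estimate the static baseline, seconds
DEFAULT_BASELINE_WINDOW_S = 10.0

_FRAME_STRUCT = struct.Struct("<3s4hI")
assert _FRAME_STRUCT.size == FRAME_SIZE


@dataclass(frozen=True)
class AcquisitionConfig:
    """Static acquisition parameters shared by encoder and decoder.

    The ADC transfer is affine per cell: ``force = count * scale + offset``.
    The default scale maps the full signed 16-bit range onto the +-1 kN
    sensor range; compression is negative, traction positive.
    """

    sample_rate: float = 10.0  # Hz, hardware supports 5-50
    adc_bits: int = 16
    reference_voltage: float = 2.5  # V, Wheatstone bridge excitation
    per_cell_scale: tuple[float, float, float, float] = (
        FULL_SCALE_N / INT16_MAX,
    ) * N_CELLS  # N per count
    per_cell_offset: tuple[float, float, float, float] = (0.0,) * N_CELLS  # N
    sync_mark: bytes = DEFAULT_SYNC_MARK

    def __post_init__(self) -> None:
        if not 5.0 <= self.sample_rate <= 50.0:
            raise ValueError(f"sample_rate must lie in [5, 50] Hz, got {self.sample_rate}")
        if len(self.per_cell_scale) != N_CELLS or len(self.per_cell_offset) != N_CELLS:
            raise ValueError("per_cell_scale/offset must each hold 4 values")
        if any(s <= 0 for s in self.per_cell_scale):
            raise ValueError("per_cell_scale entries must be positive")
        if len(self.sync_mark) != 3:
            raise ValueError("sync_mark must be exactly 3 bytes")


@dataclass(frozen=True)
class SampleFrame:
    """One sync-marked acquisition instant: a timestamp plus 4 ADC counts."""

    timestamp_ms: int
    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CELLS:
            raise ValueError("a frame carries exactly 4 load-cell counts")
        if not 0 <= self.timestamp_ms < 2**32:
            raise ValueError("timestamp_ms must fit an unsigned 32-bit field")
        for c in self.counts:
            if not INT16_MIN <= c <= INT16_MAX:
                raise CountRangeError(f"ADC count {c} outside signed 16-bit range")


@dataclass(frozen=True)
class BaselineOffsets:
    """Static-rest normalization offsets, one mean force per load cell (N)."""

    per_cell_mean: tuple[float, float, float, float]
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.n_samples_used < 1:
            raise InsufficientDataError("baseline needs at least one rest sample")
        if len(self.per_cell_mean) != N_CELLS:
            raise ValueError("per_cell_mean must hold 4 values")


@dataclass(frozen=True)
class ResyncEvent:
    """One receiver resynchronization: where it happened and what was skipped."""

    offset: int  # byte offset where scanning resumed on a valid frame
    bytes_skipped: int


@dataclass
class ResyncReport:
    """Accounting of a decode pass; guarantees no silent data loss."""

    events: list[ResyncEvent] = field(default_factory=list)
    frames_decoded: int = 0
    bytes_consumed: int = 0
    bytes_skipped: int = 0
    bytes_trailing: int = 0  # incomplete tail, shorter than one frame

    @property
    def frames_lost_estimate(self) -> int:
        """Upper-bound estimate of frames lost to corruption (15 B apiece)."""
        lost = self.bytes_skipped + self.bytes_trailing
        return -(-lost // FRAME_SIZE)  # ceil division


def encode_frame(frame: SampleFrame, config: AcquisitionConfig) -> bytes:
    return _FRAME_STRUCT.pack(config.sync_mark, *frame.counts, frame.timestamp_ms)


def encode_block(frames: Sequence[SampleFrame], config: AcquisitionConfig) -> bytes:
    """Serialize exactly 10 frames into one 150-byte transmission block."""
    if len(frames) != BLOCK_FRAMES:
        raise BlockSizeError(f"a block holds exactly {BLOCK_FRAMES} frames, got {len(frames)}")
    out = b"".join(encode_frame(f, config) for f in frames)
    assert len(out) == BLOCK_SIZE
    return out


def encode_stream(frames: Sequence[SampleFrame], config: AcquisitionConfig) -> bytes:
    """Serialize an arbitrary number of frames (frames are self-delimiting)."""
    return b"".join(encode_frame(f, config) for f in frames)


def _parse_frame(buf: bytes, offset: int) -> SampleFrame:
    _, c1, c2, c3, c4, ts = _FRAME_STRUCT.unpack_from(buf, offset)
    return SampleFrame(timestamp_ms=ts, counts=(c1, c2, c3, c4))


def decode_stream(
    data: bytes, config: AcquisitionConfig
) -> tuple[list[SampleFrame], ResyncReport]:
    """Recover frames from a possibly corrupted byte stream.

    Decoding walks frame by frame while the sync mark appears at the expected
    offset.  On a mismatch it scans forward for the mark; a candidate found
    off-grid is accepted only if the following 15-byte slot again starts with
    the mark (or the stream ends there), which makes an accidental payload
    match vanishingly unlikely.  Corruption never raises: damaged spans are
    skipped and reported as :class:`ResyncEvent` entries.
    """
    sync = config.sync_mark
    frames: list[SampleFrame] = []
    report = ResyncReport()
    i = 0
    aligned = True  # expecting a frame right here
    skip_start = 0
    n = len(data)
    while i + FRAME_SIZE <= n:
        if data[i : i + 3] == sync:
            accept = True
            if not aligned:
                nxt = i + FRAME_SIZE
                if nxt + 3 <= n:
                    accept = data[nxt : nxt + 3] == sync
                # else: tail frame, nothing left to cross-check — accept
            if accept:
                if not aligned:
                    report.events.append(
                        ResyncEvent(offset=i, bytes_skipped=i - skip_start)
                    )
                    report.bytes_skipped += i - skip_start
                    aligned = True
                frames.append(_parse_frame(data, i))
                report.frames_decoded += 1
                report.bytes_consumed += FRAME_SIZE
                i += FRAME_SIZE
                continue
        if aligned:
            aligned = False
            skip_start = i
        i += 1
    if aligned:
        report.bytes_trailing = n - i
    else:
        report.bytes_skipped += i - skip_start
        report.bytes_trailing = n - i
        if i > skip_start:
            report.events.append(ResyncEvent(offset=i, bytes_skipped=i - skip_start))
    return frames, report


# ---------------------------------------------------------------------------
# ADC transfer and baseline normalization
# ---------------------------------------------------------------------------

def counts_to_force(frame: SampleFrame, config: AcquisitionConfig) -> np.ndarray:
    """Affine ADC transfer for one frame -> 4 forces in N (compression < 0)."""
    counts = np.asarray(frame.counts, dtype=float)
    return counts * np.asarray(config.per_cell_scale) + np.asarray(config.per_cell_offset)


def force_to_counts(forces: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    """Inverse ADC transfer (used by the synthetic bench); clips to int16."""
    forces = np.asarray(forces, dtype=float)
    counts = (forces - np.asarray(config.per_cell_offset)) / np.asarray(config.per_cell_scale)
    return np.clip(np.rint(counts), INT16_MIN, INT16_MAX).astype(np.int64)


def frames_to_forces(
    frames: Sequence[SampleFrame], config: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize a frame sequence into ``(time_s, forces)`` arrays.

    ``forces`` has shape ``(n, 4)`` with one column per load cell.
    """
    if not frames:
        return np.empty(0), np.empty((0, N_CELLS))
    t = np.array([f.timestamp_ms for f in frames], dtype=float) / 1000.0
    counts = np.array([f.counts for f in frames], dtype=float)
    forces = counts * np.asarray(config.per_cell_scale) + np.asarray(config.per_cell_offset)
    return t, forces


def compute_baseline(
    rest_frames: Sequence[SampleFrame], config: AcquisitionConfig
) -> BaselineOffsets:
    """Arithmetic per-cell mean force over a static rest window.

    Taken before the experimental measurement starts, with the limb at rest;
    subtracting it removes sensor drift, thermal offsets and any constant
    preload carried by the fixator frame.
    """
    if len(rest_frames) == 0:
        raise InsufficientDataError("baseline window is empty")
    _, forces = frames_to_forces(rest_frames, config)
    mean = forces.mean(axis=0)
    return BaselineOffsets(per_cell_mean=tuple(mean), n_samples_used=len(rest_frames))


def apply_baseline(
    frames: Sequence[SampleFrame], offsets: BaselineOffsets, config: AcquisitionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(time_s, normalized forces)`` with the rest baseline removed.

    A pure per-cell shift: variances and all force differences are preserved.
    """
    t, forces = frames_to_forces(frames, config)
    return t, forces - np.asarray(offsets.per_cell_mean)


def normalize_forces(forces: np.ndarray, offsets: BaselineOffsets) -> np.ndarray:
    """Baseline shift for force arrays already converted from counts."""
    return np.asarray(forces, dtype=float) - np.asarray(offsets.per_cell_mean)


# ---------------------------------------------------------------------------
# CSV / JSON external interfaces
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["time_s", "cell1_N", "cell2_N", "cell3_N", "cell4_N", "sum_N"]


def frames_to_dataframe(
    frames: Sequence[SampleFrame],
    config: AcquisitionConfig,
    baseline: BaselineOffsets | None = None,
) -> pd.DataFrame:
    if baseline is not None:
        t, forces = apply_baseline(frames, baseline, config)
    else:
        t, forces = frames_to_forces(frames, config)
    df = pd.DataFrame(forces, columns=CSV_COLUMNS[1:5])
    df.insert(0, "time_s", t)
    df["sum_N"] = forces.sum(axis=1)
    return df


def export_csv(
    path,
    frames: Sequence[SampleFrame],
    config: AcquisitionConfig,
    baseline: BaselineOffsets | None = None,
) -> None:
    frames_to_dataframe(frames, config, baseline).to_csv(path, index=False)


def write_metadata(
    path,
    config: AcquisitionConfig,
    baseline: BaselineOffsets | None = None,
    session_start: str = "1970-01-01T00:00:00Z",
    extra: dict | None = None,
) -> None:
    """JSON sidecar: acquisition config, baseline, wall-clock session anchor."""
    meta = {
        "session_start": session_start,
        "config": {
            "sample_rate": config.sample_rate,
            "adc_bits": config.adc_bits,
            "reference_voltage": config.reference_voltage,
            "per_cell_scale": list(config.per_cell_scale),
            "per_cell_offset": list(config.per_cell_offset),
            "sync_mark": config.sync_mark.hex(),
        },
        "baseline": None
        if baseline is None
        else {
            "per_cell_mean": list(baseline.per_cell_mean),
            "n_samples_used": baseline.n_samples_used,
        },
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def make_frames(
    forces: np.ndarray,
    config: AcquisitionConfig,
    t0_ms: int = 0,
) -> list[SampleFrame]:
    """Quantize an ``(n, 4)`` force array into frames at the configured rate."""
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    counts = force_to_counts(forces, config)
    dt_ms = 1000.0 / config.sample_rate
    return [
        SampleFrame(
            timestamp_ms=int(t0_ms + round(i * dt_ms)),
            counts=tuple(int(c) for c in row),
        )
        for i, row in enumerate(counts)
    ]
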