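"""Session I/O and pseudo-online block streaming.

An ECoG session is a pair of files: an EDF recording (64 channels at
586 Hz by default) and a behaviour CSV with one row per 59-sample block
carrying the desired action (idle/walk) and the binary satisfaction label.
Sessions are streamed as consecutive non-overlapping 59-sample blocks, the
granularity at which the whole pipeline operates; a trailing partial block
is dropped.

EDF reading goes through MNE.  Writing uses a small single-purpose EDF
encoder (16-bit, one signal per channel) because the installed MNE build
has no EDF export; the encoder is exercised against MNE read-back in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = ["SessionRecord", "LabelStream", "Block", "read_session",
           "read_behavior", "preprocess", "iter_blocks", "write_predictions",
           "write_edf", "ACTIONS"]

ACTIONS = ("idle", "walk")
BLOCK_LEN = 59


@dataclass
class SessionRecord:
    """One session's ECoG samples (microvolts) plus acquisition metadata."""

    samples: np.ndarray          # (n_samples, n_channels)
    sample_rate: float = 586.0
    channel_ids: Sequence[str] = None
    session_id: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D [n_samples x n_channels]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"E{i + 1:02d}"
                                for i in range(self.samples.shape[1])]
        elif len(self.channel_ids) != self.samples.shape[1]:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.n_samples // BLOCK_LEN


@dataclass
class LabelStream:
    """Per-block behaviour labels aligned with a session record."""

    action_desired: np.ndarray   # array of "idle"/"walk" strings
    satis: np.ndarray            # array of 0/1 ints

    def __post_init__(self):
        self.action_desired = np.asarray(self.action_desired, dtype=object)
        self.satis = np.asarray(self.satis, dtype=int)
        if self.action_desired.shape != self.satis.shape:
            raise ValueError("label arrays must have equal length")
        bad = set(self.action_desired) - set(ACTIONS)
        if bad:
            raise ValueError(f"unknown action token(s): {sorted(bad)}")
        if not np.isin(self.satis, (0, 1)).all():
            raise ValueError("satis labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.satis)


@dataclass
class Block:
    """One streamed 59-sample block with its labels."""

    data: np.ndarray             # (59, n_channels)
    block_index: int
    action_desired: str
    satis: int


def read_behavior(behavior_path: str | Path) -> LabelStream:
    """Behaviour CSV with header ``block,action,satis``."""
    path = Path(behavior_path)
    if not path.exists():
        raise FileNotFoundError(f"behaviour file not found: {path}")
    df = pd.read_csv(path)
    for col in ("action", "satis"):
        if col not in df.columns:
            raise ValueError(f"behaviour file lacks column {col!r}")
    return LabelStream(df["action"].to_numpy(dtype=object),
                       df["satis"].to_numpy())


def read_session(edf_path: str | Path, behavior_path: str | Path
                 ) -> tuple:
    """Read an aligned (SessionRecord, LabelStream) session pair.

    The behaviour file must contain exactly one row per complete 59-sample
    block of the recording.
    """
    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise FileNotFoundError(f"EDF file not found: {edf_path}")
    import mne
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    samples = raw.get_data().T * 1e6        # volts -> microvolts
    record = SessionRecord(samples=samples,
                           sample_rate=float(raw.info["sfreq"]),
                           channel_ids=list(raw.ch_names))
    labels = read_behavior(behavior_path)
    if len(labels) != record.n_blocks:
        raise ValueError(
            f"label/block misalignment: behaviour file has {len(labels)} "
            f"rows but the recording holds {record.n_blocks} complete "
            f"blocks")
    return record, labels


def preprocess(record: SessionRecord, low_hz: float = 0.5,
               high_hz: float = 300.0, order: int = 4) -> SessionRecord:
    """Zero-phase Butterworth band-pass copy of a session.

    The band is clamped to [0.5, 0.95 * Nyquist] so the acquisition default
    of 300 Hz remains valid at 586 Hz sampling.  Zero-phase filtering
    (forward-backward) keeps the block alignment intact.
    """
    if not (0 < low_hz < high_hz):
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] Hz")
    nyq = record.sample_rate / 2.0
    low = max(low_hz, 0.5)
    high = min(high_hz, 0.95 * nyq)
    if not low < high:
        raise ValueError(f"band [{low_hz}, {high_hz}] Hz collapses after "
                         f"clamping to Nyquist {nyq:g} Hz")
    sos = sp_signal.butter(order, [low, high], btype="bandpass",
                           fs=record.sample_rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, record.samples, axis=0)
    if not np.all(np.isfinite(filtered)):
        raise FloatingPointError("filtering produced non-finite samples")
    return SessionRecord(samples=filtered, sample_rate=record.sample_rate,
                         channel_ids=list(record.channel_ids),
                         session_id=record.session_id)


def iter_blocks(record: SessionRecord, labels: LabelStream | None = None
                ) -> Iterator[Block]:
    """Yield consecutive non-overlapping 59-sample blocks in order.

    Block k covers samples [59k, 59k+59); trailing samples that do not fill
    a block are dropped.  With ``labels`` given, block k carries labels[k].
    """
    n_blocks = record.n_blocks
    if labels is not None and len(labels) != n_blocks:
        raise ValueError(f"label/block misalignment: {len(labels)} labels "
                         f"vs {n_blocks} blocks")
    for k in range(n_blocks):
        data = record.samples[k * BLOCK_LEN:(k + 1) * BLOCK_LEN]
        if labels is None:
            yield Block(data, k, None, None)
        else:
            yield Block(data, k, labels.action_desired[k],
                        int(labels.satis[k]))


def write_predictions(results, csv_path: str | Path) -> None:
    """Write per-block predictions as CSV (one row per block).

    ``results`` is a sequence of decoder BlockResult objects; an empty
    sequence is an error rather than an empty file.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty prediction file")
    rows = []
    has_feedback = any(getattr(r, "feedback_applied", False)
                       for r in results)
    for r in results:
        row = {
            "block_index": r.block_index,
            "action_desired": r.action_desired,
            "action_predicted": r.action_predicted,
            "satis_label": r.satis_label,
            "satis_predicted": r.satis_predicted,
            "y_mcd": r.y_mcd,
            "y_nrd": r.y_nrd,
            "mcd_error": r.mcd_error,
            "nrd_error": r.nrd_error,
        }
        if has_feedback:
            row["action_after_feedback"] = r.action_after_feedback
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# EDF writing

def _pad_field(value, width: int) -> bytes:
    text = str(value).encode("ascii")
    if len(text) > width:
        raise ValueError(f"EDF header field too long: {value!r}")
    return text + b" " * (width - len(text))


def write_edf(path: str | Path, samples_uv: np.ndarray, sample_rate: float,
              channel_ids: Sequence[str], record_dur_s: float = 0.5) -> int:
    """Write a plain EDF file (16-bit) and return the samples written.

    The recording is trimmed to a whole number of data records
    (``record_dur_s`` seconds each); the physical range is taken from the
    data so quantisation error is at most half a digital step.
    """
    samples_uv = np.asarray(samples_uv, dtype=float)
    n_samples, n_ch = samples_uv.shape
    spr = sample_rate * record_dur_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record duration must hold an integer number of "
                         "samples")
    spr = int(round(spr))
    n_rec = n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record")
    data = samples_uv[:n_rec * spr]
    pmin = float(np.floor(data.min() - 1.0))
    pmax = float(np.ceil(data.max() + 1.0))
    dmin, dmax = -32768, 32767
    digital = np.round((data - pmin) * (dmax - dmin) / (pmax - pmin)
                       + dmin).astype("<i2")
    header = b"".join([
        _pad_field("0", 8),
        _pad_field("X X X X", 80),
        _pad_field("Startdate X X X X", 80),
        _pad_field("01.01.00", 8),
        _pad_field("00.00.00", 8),
        _pad_field(256 * (1 + n_ch), 8),
        _pad_field("", 44),
        _pad_field(n_rec, 8),
        _pad_field(f"{record_dur_s:g}", 8),
        _pad_field(n_ch, 4),
    ])
    fields = [
        (lambda c: c, 16),               # label
        (lambda c: "ECoG", 80),          # transducer
        (lambda c: "uV", 8),             # physical dimension
        (lambda c: f"{pmin:g}", 8),
        (lambda c: f"{pmax:g}", 8),
        (lambda c: dmin, 8),
        (lambda c: dmax, 8),
        (lambda c: "", 80),              # prefiltering
        (lambda c: spr, 8),
        (lambda c: "", 32),              # reserved
    ]
    for fn, width in fields:
        for ch in channel_ids:
            header += _pad_field(fn(ch), width)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[r * spr:(r + 1) * spr].T.tobytes())
    return n_rec * spr
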