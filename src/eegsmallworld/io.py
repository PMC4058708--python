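"""Reading, referencing, filtering and epoching of multichannel scalp EEG.

The analysis consumes 19-channel 10-20 recordings sampled at 256 Hz in
microvolts.  Ingestion maps vendor channel labels onto the canonical montage
(including T7/T8/P7/P8 aliases), resamples if the source rate differs, and
raises a :class:`MontageError` naming any missing analysis channel.

A small EDF writer is included so that synthetic recordings can round-trip
through the same file format as clinical exports; reading goes through MNE.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .montage import CHANNELS_1020, N_CHANNELS, normalize_label

TARGET_SFREQ = 256.0
EPOCH_SECONDS = 300.0
#: hourly epochs through 48 h after arrest, then one every 2 h
TWO_HOURLY_AFTER = 48.0


class MontageError(ValueError):
    """An analysis channel required by the 10-20 montage is missing."""


class FormatError(ValueError):
    """The input file could not be parsed as EDF."""


@dataclass
class EEGRecording:
    """A 19-channel scalp EEG segment in microvolts.

    ``t0_offset_hours`` is the time of the first sample relative to the
    cardiac arrest; the epoch schedule is anchored to the arrest, not to the
    start of the recording.
    """

    channel_labels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    t0_offset_hours: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples)")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sfreq


@dataclass
class Epoch:
    """A 300-s analysis interval cut from a recording."""

    data: np.ndarray  # (19, 76800) microvolts
    start_hour: float  # hours since arrest
    included: bool = True
    sfreq: float = TARGET_SFREQ

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_recording(path: str | Path, t0_offset_hours: float = 0.0) -> EEGRecording:
    """Read an EDF/EDF+ file and return the 19 analysis channels at 256 Hz.

    Extra electrodes (reference, ground, EOG/ECG, midline spares) are
    dropped; a missing analysis channel raises :class:`MontageError` naming
    it.  Signals are returned in microvolts, resampled to 256 Hz when the
    source rate differs.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    by_canon: dict[str, int] = {}
    for idx, name in enumerate(raw.ch_names):
        canon = normalize_label(name)
        if canon in CHANNELS_1020 and canon not in by_canon:
            by_canon[canon] = idx
    missing = [ch for ch in CHANNELS_1020 if ch not in by_canon]
    if missing:
        raise MontageError(f"missing required channel(s): {', '.join(missing)}")

    data_v = raw.get_data()  # volts
    order = [by_canon[ch] for ch in CHANNELS_1020]
    data = data_v[order] * 1e6
    sfreq = float(raw.info["sfreq"])
    if sfreq != TARGET_SFREQ:
        data = _resample(data, sfreq, TARGET_SFREQ)
        sfreq = TARGET_SFREQ
    return EEGRecording(CHANNELS_1020, sfreq, data, t0_offset_hours)


def _resample(data: np.ndarray, src: float, dst: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(dst / src).limit_denominator(1000)
    return _sig.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def preprocess(
    rec: EEGRecording,
    reference: str = "average",
    band: tuple[float, float] = (1.0, 100.0),
    order: int = 4,
) -> EEGRecording:
    """Apply the recording conventions: average reference, 1-100 Hz band-pass.

    The instantaneous mean over the 19 channels is subtracted from every
    sample (``reference="average"``; pass ``"none"`` for data that is
    already referenced), then a zero-phase Butterworth band-pass of the
    given order is applied forward-backward.
    """
    if rec.data.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {rec.data.shape[0]}")
    data = rec.data
    if reference == "average":
        data = data - data.mean(axis=0, keepdims=True)
    elif reference != "none":
        raise ValueError(f"unknown reference scheme {reference!r}")
    if band is not None:
        lo, hi = band
        nyq = rec.sfreq / 2.0
        sos = _sig.butter(order, [lo / nyq, min(hi / nyq, 0.999)], btype="band", output="sos")
        data = _sig.sosfiltfilt(sos, data, axis=1)
    return replace(rec, data=np.ascontiguousarray(data))


def read_artifact_table(path: str | Path) -> pd.DataFrame:
    """Read an epoch-level artifact annotation table.

    Plain-text delimited file with columns ``start_hour`` and ``include``
    (boolean / 0-1).  Epochs whose start hour appears with ``include`` false
    are flagged excluded by :func:`schedule_epochs`.
    """
    df = pd.read_csv(path)
    if not {"start_hour", "include"}.issubset(df.columns):
        raise FormatError("artifact table needs columns start_hour, include")
    df["include"] = df["include"].astype(bool)
    return df


def _slot_hours(start_h: float, end_h: float) -> list[float]:
    """Epoch slot start hours intersecting [start_h, end_h]."""
    hours: list[float] = [float(h) for h in range(0, int(TWO_HOURLY_AFTER))]
    h = TWO_HOURLY_AFTER
    while h <= end_h:
        hours.append(float(h))
        h += 2.0
    return [h for h in hours if h + 1.0 > start_h and h < end_h]


def schedule_epochs(
    rec: EEGRecording, artifacts: pd.DataFrame | None = None
) -> list[Epoch]:
    """Cut a recording into the study's epoch schedule.

    One 300-s interval per hour of registration through 48 h after arrest,
    then one per 2 h.  Within each slot the epoch is placed at the earliest
    covered time.  Epochs listed in the artifact table with ``include``
    false are returned with ``included=False``; a recording shorter than one
    epoch yields an empty schedule.
    """
    n_epoch = int(EPOCH_SECONDS * rec.sfreq)
    start_h = rec.t0_offset_hours
    end_h = start_h + rec.duration / 3600.0
    excluded: set[float] = set()
    if artifacts is not None:
        excluded = set(artifacts.loc[~artifacts["include"], "start_hour"].astype(float))

    epochs: list[Epoch] = []
    for slot in _slot_hours(start_h, end_h):
        t_start_h = max(slot, start_h)
        i0 = int(round((t_start_h - start_h) * 3600.0 * rec.sfreq))
        if i0 + n_epoch > rec.data.shape[1]:
            continue
        data = rec.data[:, i0 : i0 + n_epoch]
        epochs.append(
            Epoch(data=data, start_hour=t_start_h, included=slot not in excluded)
        )
    return epochs


# ---------------------------------------------------------------------------
# minimal EDF export (16-bit, 1-second records)

def _edf_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording as a plain 16-bit EDF file with 1-s data records.

    Channel labels are written as ``EEG <name>`` with physical dimension uV.
    The number of whole seconds present is written; a trailing partial
    second is dropped.
    """
    sfreq = int(round(rec.sfreq))
    n_ch = len(rec.channel_labels)
    n_rec = rec.data.shape[1] // sfreq
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : n_rec * sfreq]

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    flat = pmax - pmin < 1e-6
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (n_ch + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig_fields = [
        [f"EEG {ch}" for ch in rec.channel_labels],  # label, 16
        ["AgAgCl electrode"] * n_ch,  # transducer, 80
        ["uV"] * n_ch,  # physical dimension, 8
        [f"{v:g}"[:8] for v in pmin],  # physical min, 8
        [f"{v:g}"[:8] for v in pmax],  # physical max, 8
        [str(dmin)] * n_ch,  # digital min, 8
        [str(dmax)] * n_ch,  # digital max, 8
        [""] * n_ch,  # prefiltering, 80
        [str(sfreq)] * n_ch,  # samples per record, 8
        [""] * n_ch,  # reserved, 32
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    for vals, width in zip(sig_fields, widths):
        header += b"".join(_edf_field(v, width) for v in vals)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * sfreq : (r + 1) * sfreq]
            fh.write(block.tobytes())
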