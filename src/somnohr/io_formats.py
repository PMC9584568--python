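"""Readers and writers for the physiological formats used by the pipeline.

ECG comes in as WFDB (``.hea`` + ``.dat``/``.mat``) or EDF/EDF+; hypnograms
travel as a small CSV dialect (``epoch_index,onset_s,stage``), quality-control
reports as JSON.  All epoch bookkeeping is 0-based with half-open 30-s
intervals ``[start + 30*i, start + 30*(i+1))`` and integer-second onset
arithmetic, so joins across modules never accumulate float drift.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical AASM 5-class stage tokens.
STAGES_5 = ("W", "N1", "N2", "N3", "R")

#: Synonyms normalized on read.  Only wake/REM spellings are folded; the
#: obsolete "N4"/"S4" scoring is rejected rather than silently remapped.
_STAGE_SYNONYMS = {"WAKE": "W", "REM": "R"}

EPOCH_LEN_S = 30


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class ChannelNotFoundError(KeyError):
    """The requested channel is absent from the recording."""


class HypnogramParseError(FormatError):
    """A hypnogram CSV contains an invalid row; the message names it."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EcgRecord:
    """Single-channel ECG: samples in millivolt at a fixed sampling rate.

    ``start_time`` is an absolute timestamp in UTC seconds (epoch-zero when
    the source header carries none).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    channel_label: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("EcgRecord requires at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class Hypnogram:
    """A night of 30-s AASM epochs over {W, N1, N2, N3, R}."""

    labels: tuple
    start_time: float = 0.0
    subject_id: str = ""
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        bad = [l for l in self.labels if l not in STAGES_5]
        if bad:
            raise ValueError(f"labels outside the 5-class set: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def epoch_onsets_s(self) -> np.ndarray:
        """Onset of each epoch relative to ``start_time`` (integer seconds)."""
        return np.arange(len(self.labels), dtype=np.int64) * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Label of the epoch whose half-open interval contains absolute ``t_s``."""
        i = int((t_s - self.start_time) // self.epoch_len_s)
        if not 0 <= i < len(self.labels):
            raise IndexError(f"time {t_s} outside hypnogram span")
        return self.labels[i]


@dataclass
class EpochGrid:
    """The 30-s scoring grid shared by QC, features and evaluation."""

    n_epochs: int
    start_time: float = 0.0
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        if self.n_epochs <= 0:
            raise ValueError("grid must contain at least one epoch")

    @property
    def onsets_s(self) -> np.ndarray:
        return np.arange(self.n_epochs, dtype=np.int64) * self.epoch_len_s

    @classmethod
    def for_duration(cls, duration_s: float, start_time: float = 0.0) -> "EpochGrid":
        return cls(n_epochs=max(1, int(duration_s // EPOCH_LEN_S)), start_time=start_time)


# ---------------------------------------------------------------------------
# ECG readers
# ---------------------------------------------------------------------------

def read_ecg(path, format: str | None = None, channel=0) -> EcgRecord:
    """Read one ECG channel from a WFDB or EDF file.

    Parameters
    ----------
    path
        Path to the ``.hea`` (WFDB) or ``.edf`` file.
    format
        ``"wfdb"`` or ``"edf"``; inferred from the extension when omitted.
    channel
        Channel name (matched case-insensitively against signal labels) or
        integer index.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {"hea": "wfdb", ".hea": "wfdb", ".dat": "wfdb", ".mat": "wfdb",
                  ".edf": "edf"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension {ext!r}")
    if format == "wfdb":
        return _read_wfdb(path, channel)
    if format == "edf":
        return _read_edf(path, channel)
    raise FormatError(f"unknown format {format!r}")


def _pick_channel(labels: Sequence[str], channel) -> int:
    if isinstance(channel, int):
        if not 0 <= channel < len(labels):
            raise ChannelNotFoundError(
                f"channel index {channel} out of range (have {len(labels)})")
        return channel
    wanted = str(channel).strip().lower()
    for i, lab in enumerate(labels):
        if lab.strip().lower() == wanted:
            return i
    raise ChannelNotFoundError(
        f"channel {channel!r} not found; available: {list(labels)}")


_MV_PER_UNIT = {"mv": 1.0, "v": 1000.0, "uv": 1e-3, "µv": 1e-3, "nv": 1e-6}


def _read_wfdb(path: Path, channel) -> EcgRecord:
    """Minimal WFDB reader: text header plus format-16 ``.dat`` or a MATLAB
    ``.mat`` signal matrix (the layout used by the CinC distribution)."""
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing WFDB header {hea}")
    lines = [l.strip() for l in hea.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header {hea}")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
    except ValueError as exc:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}") from exc
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise FormatError("WFDB header declares more signals than it describes")

    names, files, gains, baselines, units = [], [], [], [], []
    for ln in sig_lines:
        toks = ln.split()
        if len(toks) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        files.append(toks[0])
        # gain spec looks like  200, 200(0), or 200(0)/mV
        gain, baseline, unit = 200.0, 0.0, "mV"
        if len(toks) >= 3:
            m = re.match(r"^([-\d.eE+]+)(?:\(([-\d.eE+]+)\))?(?:/(\S+))?$", toks[2])
            if m:
                gain = float(m.group(1)) or 200.0
                if m.group(2) is not None:
                    baseline = float(m.group(2))
                if m.group(3) is not None:
                    unit = m.group(3)
        gains.append(gain)
        baselines.append(baseline)
        units.append(unit)
        names.append(toks[-1])
    idx = _pick_channel(names, channel)

    sig_file = path.parent / files[idx]
    if sig_file.suffix == ".mat":
        from scipy.io import loadmat

        mat = loadmat(sig_file)
        arrays = [v for k, v in mat.items() if not k.startswith("__")]
        if not arrays:
            raise FormatError(f"no signal matrix in {sig_file}")
        data = np.atleast_2d(arrays[0])
        if data.shape[0] != n_sig and data.shape[1] == n_sig:
            data = data.T
        raw = data[idx].astype(float)
    else:
        flat = np.fromfile(sig_file, dtype="<i2")
        n = flat.size // n_sig
        raw = flat[: n * n_sig].reshape(n, n_sig)[:, idx].astype(float)

    mv = (raw - baselines[idx]) / gains[idx]
    scale = _MV_PER_UNIT.get(units[idx].lower())
    if scale is None:
        logger.warning("WFDB unit %r unrecognized; passing values through", units[idx])
        scale = 1.0
    return EcgRecord(samples=mv * scale, fs=fs, start_time=0.0,
                     channel_label=names[idx])


def _read_edf(path: Path, channel) -> EcgRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt headers
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    idx = _pick_channel(raw.ch_names, channel)
    name = raw.ch_names[idx]
    orig_unit = getattr(raw, "_orig_units", {}).get(name, "n/a")
    data = raw.get_data(picks=[idx])[0]
    key = str(orig_unit).strip().lower()
    if key in _MV_PER_UNIT:
        # mne rescales recognized voltage units to volts internally
        samples = data * 1000.0
    else:
        if key not in ("n/a", ""):
            logger.warning("EDF unit %r unrecognized; passing values through", orig_unit)
        samples = data
    meas = raw.info.get("meas_date")
    start = meas.timestamp() if meas is not None else 0.0
    return EcgRecord(samples=samples, fs=float(raw.info["sfreq"]),
                     start_time=start, channel_label=name)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

_HYPNO_HEADER = ["epoch_index", "onset_s", "stage"]


def write_hypnogram(h: Hypnogram, path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_HYPNO_HEADER)
        for i, (onset, lab) in enumerate(zip(h.epoch_onsets_s, h.labels)):
            w.writerow([i, int(onset), lab])


def read_hypnogram(path, start_time: float = 0.0, subject_id: str = "") -> Hypnogram:
    labels = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != _HYPNO_HEADER:
            raise HypnogramParseError(
                f"{path}: expected header {','.join(_HYPNO_HEADER)!r}, got {header}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise HypnogramParseError(f"{path}: row {row_no} malformed: {row}")
            tok = row[2].strip()
            stage = _STAGE_SYNONYMS.get(tok.upper(), tok)
            if stage not in STAGES_5:
                raise HypnogramParseError(
                    f"{path}: row {row_no}: unknown stage token {tok!r}")
            labels.append(stage)
    return Hypnogram(labels=tuple(labels), start_time=start_time,
                     subject_id=subject_id)


# ---------------------------------------------------------------------------
# QC report / config JSON
# ---------------------------------------------------------------------------

def write_qc_report(report, path) -> None:
    """Serialize a :class:`somnohr.signal_quality.QualityReport` to JSON."""
    from dataclasses import asdict

    payload = {
        "epoch_rejected": [bool(b) for b in report.epoch_rejected],
        "fraction_rejected": float(report.fraction_rejected),
        "recording_excluded": bool(report.recording_excluded),
        "config": asdict(report.config),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def read_qc_report(path):
    from .signal_quality import QcConfig, QualityReport

    with open(path) as f:
        payload = json.load(f)
    cfg_d = payload["config"]
    cfg_d["signal_band_hz"] = tuple(cfg_d["signal_band_hz"])
    return QualityReport(
        epoch_rejected=np.asarray(payload["epoch_rejected"], dtype=bool),
        fraction_rejected=float(payload["fraction_rejected"]),
        recording_excluded=bool(payload["recording_excluded"]),
        config=QcConfig(**cfg_d),
    )


def load_config(path) -> dict:
    with open(path) as f:
        return json.load(f)
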