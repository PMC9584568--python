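"""Wavelet SNR signal-quality index and epoch/recording rejection rules.

The quality contract: ECG is split into a signal component and a background
component; per-sample SNR is

    SNR[i] = 20 * log10( A_signal[i] / A_noise[i] )  dB

where ``A_signal`` is a sliding 3-s maximum filter of the absolute signal
component and ``A_noise`` is sqrt(2) times the sliding 10-s RMS of the
background, both windows advanced one sample at a time.  A 30-s epoch is
rejected when 50% or more of its samples fall strictly below 5 dB; a
recording is excluded when 10% or more of its epochs are rejected.  Both
percentage boundaries are inclusive; the dB threshold is strict.  Retained
recordings keep every epoch for downstream scoring, including rejected ones.

The signal/background separation here is a stationary wavelet transform
(default ``sym4``) reconstruction of the detail levels whose passbands
intersect the QRS energy band (default 5-32 Hz), with background defined as
the residual.  The decomposition is a pluggable hook so the SNR and
rejection machinery can be tested independently of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .io_formats import EcgRecord, EpochGrid

logger = logging.getLogger(__name__)

SNR_DB_MIN = -40.0
SNR_DB_MAX = 80.0


@dataclass
class QcConfig:
    signal_window_s: float = 3.0
    noise_window_s: float = 10.0
    snr_threshold_db: float = 5.0
    epoch_reject_fraction: float = 0.5
    recording_exclude_fraction: float = 0.1
    wavelet_name: str = "sym4"
    signal_band_hz: tuple = (5.0, 32.0)

    def __post_init__(self) -> None:
        if self.signal_window_s <= 0 or self.noise_window_s <= 0:
            raise ValueError("window lengths must be positive")
        for frac in (self.epoch_reject_fraction, self.recording_exclude_fraction):
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"fraction {frac} outside (0, 1]")


@dataclass
class SnrSeries:
    snr_db: np.ndarray
    fs: float
    a_signal: np.ndarray
    a_noise: np.ndarray


@dataclass
class QualityReport:
    epoch_rejected: np.ndarray
    fraction_rejected: float
    recording_excluded: bool
    config: QcConfig


# ---------------------------------------------------------------------------
# Decomposition hook
# ---------------------------------------------------------------------------

def swt_decomposition(x: np.ndarray, fs: float, cfg: QcConfig):
    """Split ``x`` into (signal, background) with a stationary wavelet
    transform: keep the detail levels whose dyadic passbands
    [fs/2^(j+1), fs/2^j] intersect ``cfg.signal_band_hz``; background is
    the residual.  Linear, so SNR is invariant to overall signal scale."""
    lo, hi = cfg.signal_band_hz
    levels = [j for j in range(1, 12)
              if fs / 2 ** (j + 1) < hi and fs / 2 ** j > lo]
    if not levels:
        raise ValueError(f"no wavelet level overlaps band {cfg.signal_band_hz} "
                         f"at fs={fs}")
    max_level = max(levels)
    n = x.size
    block = 2 ** max_level
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x
    coeffs = pywt.swt(xp, cfg.wavelet_name, level=max_level, norm=True)
    # coeffs[k] = (cA, cD) at level (max_level - k)
    kept = []
    for k, (ca, cd) in enumerate(coeffs):
        level = max_level - k
        kept.append((np.zeros_like(ca),
                     cd if level in levels else np.zeros_like(cd)))
    sig = pywt.iswt(kept, cfg.wavelet_name, norm=True)[:n]
    return sig, x - sig


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_snr(e: EcgRecord, cfg: QcConfig | None = None,
                decomposition: Callable | None = None) -> SnrSeries:
    """Per-sample SNR of an ECG record.

    ``decomposition(x, fs) -> (signal, background)`` overrides the wavelet
    split (used to test the ratio machinery in isolation).
    """
    cfg = cfg or QcConfig()
    if e.duration_s < cfg.noise_window_s:
        raise ValueError(
            f"record of {e.duration_s:.1f} s shorter than the "
            f"{cfg.noise_window_s} s noise window")
    x = e.samples
    if decomposition is None:
        sig, bg = swt_decomposition(x, e.fs, cfg)
    else:
        sig, bg = decomposition(x, e.fs)

    w_sig = max(1, int(round(cfg.signal_window_s * e.fs)))
    w_noise = max(1, int(round(cfg.noise_window_s * e.fs)))
    a_signal = maximum_filter1d(np.abs(sig), size=w_sig, mode="reflect")
    rms = np.sqrt(uniform_filter1d(bg.astype(float) ** 2, size=w_noise,
                                   mode="reflect"))
    a_noise = np.sqrt(2.0) * rms
    floor = np.finfo(float).eps * max(1.0, float(np.max(a_signal, initial=0.0)))
    snr = 20.0 * np.log10(np.maximum(a_signal, floor)
                          / np.maximum(a_noise, floor))
    snr = np.clip(snr, SNR_DB_MIN, SNR_DB_MAX)
    return SnrSeries(snr_db=snr, fs=e.fs, a_signal=a_signal, a_noise=a_noise)


def classify_epochs(s: SnrSeries, grid: EpochGrid,
                    cfg: QcConfig | None = None) -> QualityReport:
    """Apply the epoch rejection rule on the 30-s grid.

    An epoch is rejected when the fraction of its samples with SNR strictly
    below ``snr_threshold_db`` reaches ``epoch_reject_fraction`` (inclusive).
    """
    cfg = cfg or QcConfig()
    if grid.n_epochs == 0:
        raise ValueError("empty epoch grid")
    spe = int(round(grid.epoch_len_s * s.fs))
    rejected = np.zeros(grid.n_epochs, dtype=bool)
    for i in range(grid.n_epochs):
        seg = s.snr_db[i * spe:(i + 1) * spe]
        if seg.size == 0:
            raise ValueError(f"epoch {i} not covered by the SNR series")
        frac_bad = np.mean(seg < cfg.snr_threshold_db)
        rejected[i] = frac_bad >= cfg.epoch_reject_fraction
    report = QualityReport(
        epoch_rejected=rejected,
        fraction_rejected=float(np.mean(rejected)),
        recording_excluded=False,
        config=cfg,
    )
    return assess_recording(report, cfg)


def assess_recording(q: QualityReport, cfg: QcConfig | None = None) -> QualityReport:
    """Set the recording-level verdict: excluded when the rejected-epoch
    fraction reaches ``recording_exclude_fraction`` (inclusive).  Retained
    recordings are scored over all epochs, rejected ones included."""
    cfg = cfg or q.config
    q.recording_excluded = bool(
        q.fraction_rejected >= cfg.recording_exclude_fraction)
    return q
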