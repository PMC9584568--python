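"""Per-epoch model inputs: HR, HRV, derived respiration, in-bed score.

Time-domain features come from the 30-s epoch window of the 4 Hz tachogram;
spectral features (LF 0.04-0.15 Hz, HF 0.15-0.40 Hz) from a Welch estimate
over a 5-min window centered on the epoch — the shortest conventional
window for LF estimation.  Respiration is derived from respiratory sinus
arrhythmia: the dominant HF-band frequency of the tachogram, because the
pipeline is morphology-insensitive and R-amplitude modulation is off the
table.  Epochs outside the tachogram span carry NaN features, never
fabricated values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import EpochGrid
from .rr_processing import Tachogram

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
SPECTRAL_WINDOW_S = 300.0

POSITIONS = ("supine", "lateral_left", "lateral_right", "prone", "upright")

SCALAR_FEATURES = ("mean_hr", "sdnn", "rmssd", "lf_power", "hf_power",
                   "lf_hf_ratio", "resp_rate")

#: Fixed physiological scales used to standardize channels for the model.
_FEATURE_SCALE = {
    "mean_hr": (60.0, 20.0),       # bpm
    "sdnn": (40.0, 30.0),          # ms
    "rmssd": (30.0, 25.0),         # ms
    "lf_power": (600.0, 600.0),    # ms^2
    "hf_power": (500.0, 500.0),    # ms^2
    "lf_hf_ratio": (2.0, 2.0),
    "resp_rate": (0.25, 0.08),     # Hz
}


@dataclass
class EpochFeatures:
    """One row per epoch of the grid; NaN marks undefined entries."""

    mean_hr: np.ndarray
    sdnn: np.ndarray
    rmssd: np.ndarray
    lf_power: np.ndarray
    hf_power: np.ndarray
    lf_hf_ratio: np.ndarray
    resp_rate: np.ndarray
    in_bed: np.ndarray
    grid: EpochGrid

    def __len__(self) -> int:
        return self.grid.n_epochs


@dataclass
class FeatureTensor:
    """Model input: (n_epochs, channels, samples_per_window).

    Channel 0 is the standardized tachogram window, channel 1 a validity
    mask (1 inside the tachogram span, 0 on zero-padding), followed by the
    scalar features broadcast along time.
    """

    data: np.ndarray
    mask: np.ndarray
    context_epochs: int
    rate_hz: float
    channel_names: tuple

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class PositionSeries:
    """Categorical body-position trace sampled at arbitrary times."""

    times_s: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U16")
        bad = set(self.labels) - set(POSITIONS)
        if bad:
            raise ValueError(f"unknown position categories: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def _welch_psd(seg: np.ndarray, fs: float):
    seg = seg - np.mean(seg)
    nper = min(seg.size, int(fs * 120))
    return sps.welch(seg, fs=fs, nperseg=nper)


def _band_power(f: np.ndarray, p: np.ndarray, band) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if not np.any(m):
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def compute_epoch_features(t: Tachogram, grid: EpochGrid,
                           position: PositionSeries | None = None) -> EpochFeatures:
    """Derive the full per-epoch feature table on the scoring grid."""
    n = grid.n_epochs
    cols = {name: np.full(n, np.nan) for name in SCALAR_FEATURES}
    fs = t.rate_hz
    for i in range(n):
        onset = grid.start_time + i * grid.epoch_len_s - t.origin_s
        lo = int(round(onset * fs))
        hi = int(round((onset + grid.epoch_len_s) * fs))
        lo_c, hi_c = max(0, lo), min(t.rr_ms.size, hi)
        if hi_c - lo_c <= 1:
            continue  # epoch outside the tachogram span: stays undefined
        seg = t.rr_ms[lo_c:hi_c]
        cols["mean_hr"][i] = 60000.0 / float(np.mean(seg))
        cols["sdnn"][i] = float(np.std(seg))
        cols["rmssd"][i] = float(np.sqrt(np.mean(np.diff(seg) ** 2)))
        # spectral window: 5 min centered on the epoch, clipped to the record
        c = (lo + hi) / 2.0
        half = SPECTRAL_WINDOW_S * fs / 2.0
        slo = int(max(0, round(c - half)))
        shi = int(min(t.rr_ms.size, round(c + half)))
        if shi - slo >= int(60 * fs):
            f, p = _welch_psd(t.rr_ms[slo:shi], fs)
            lf = _band_power(f, p, LF_BAND)
            hf = _band_power(f, p, HF_BAND)
            cols["lf_power"][i] = lf
            cols["hf_power"][i] = hf
            cols["lf_hf_ratio"][i] = lf / hf if hf > 1e-12 else np.nan
    resp = derive_respiration(t, grid)
    in_bed = in_bed_score(position, grid)
    return EpochFeatures(grid=grid, resp_rate=resp, in_bed=in_bed,
                         **{k: cols[k] for k in
                            ("mean_hr", "sdnn", "rmssd", "lf_power",
                             "hf_power", "lf_hf_ratio")})


def derive_respiration(t: Tachogram, grid: EpochGrid,
                       power_floor: float = 1.0) -> np.ndarray:
    """Respiratory rate per epoch from RSA: the dominant frequency of the
    HF band (0.15-0.40 Hz) of the tachogram over a 5-min centered window.
    NaN where the band holds no energy above ``power_floor`` (ms^2)."""
    n = grid.n_epochs
    fs = t.rate_hz
    out = np.full(n, np.nan)
    for i in range(n):
        onset = grid.start_time + i * grid.epoch_len_s - t.origin_s
        c = (onset + grid.epoch_len_s / 2.0) * fs
        half = SPECTRAL_WINDOW_S * fs / 2.0
        lo = int(max(0, round(c - half)))
        hi = int(min(t.rr_ms.size, round(c + half)))
        if hi - lo < int(60 * fs):
            continue
        f, p = _welch_psd(t.rr_ms[lo:hi], fs)
        m = (f >= HF_BAND[0]) & (f <= HF_BAND[1])
        if not np.any(m) or _band_power(f, p, HF_BAND) < power_floor:
            continue
        out[i] = float(f[m][np.argmax(p[m])])
    return out


def in_bed_score(position: PositionSeries | None, grid: EpochGrid) -> np.ndarray:
    """True unless the modal position within the epoch is ``upright``.

    With no position channel every epoch is in-bed (logged warning)."""
    if position is None:
        logger.warning("no position channel: assuming in-bed for all epochs")
        return np.ones(grid.n_epochs, dtype=bool)
    out = np.ones(grid.n_epochs, dtype=bool)
    rel = position.times_s - grid.start_time
    for i in range(grid.n_epochs):
        m = (rel >= i * grid.epoch_len_s) & (rel < (i + 1) * grid.epoch_len_s)
        if not np.any(m):
            continue
        labs, counts = np.unique(position.labels[m], return_counts=True)
        out[i] = labs[np.argmax(counts)] != "upright"
    return out


# ---------------------------------------------------------------------------
# Tensor assembly
# ---------------------------------------------------------------------------

def assemble_inputs(t: Tachogram, f: EpochFeatures,
                    context_epochs: int = 0) -> FeatureTensor:
    """Package per-epoch tachogram windows plus broadcast scalar features.

    Each epoch's window spans (1 + 2*context_epochs) epochs centered on it;
    out-of-span samples are zero-padded and zeroed in the mask channel.
    Channels are standardized with fixed physiological scales so the model
    sees O(1) inputs.
    """
    if context_epochs < 0:
        raise ValueError("context_epochs must be >= 0")
    grid = f.grid
    fs = t.rate_hz
    spe = int(round(grid.epoch_len_s * fs))
    win = (1 + 2 * context_epochs) * spe
    n = grid.n_epochs
    names = ("tachogram", "mask") + SCALAR_FEATURES
    data = np.zeros((n, len(names), win))
    rr_std = (t.rr_ms - 1000.0) / 250.0
    for i in range(n):
        onset = grid.start_time + (i - context_epochs) * grid.epoch_len_s - t.origin_s
        lo = int(round(onset * fs))
        hi = lo + win
        lo_c, hi_c = max(0, lo), min(t.rr_ms.size, hi)
        if hi_c > lo_c:
            data[i, 0, lo_c - lo:hi_c - lo] = rr_std[lo_c:hi_c]
            data[i, 1, lo_c - lo:hi_c - lo] = 1.0
        for j, name in enumerate(SCALAR_FEATURES, start=2):
            v = getattr(f, name)[i]
            mu, sd = _FEATURE_SCALE[name]
            data[i, j, :] = 0.0 if np.isnan(v) else (v - mu) / sd
    return FeatureTensor(data=data, mask=data[:, 1, :].astype(bool),
                         context_epochs=context_epochs, rate_hz=fs,
                         channel_names=names)
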