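"""Dual-device epoch alignment.

Two simultaneously recorded devices (e.g., a wearable ECG patch and PSG)
are placed on one common 30-s epoch grid anchored at the earlier lights-off
time.  The shorter recording is extended to match the longer one by
assuming wake for missing epochs; padded epochs are flagged.  Sub-epoch
offsets are snapped to the nearest epoch boundary and the residual logged.
Interior dropouts are also W-filled and flagged, as a documented extension
of the end-padding rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EPOCH_LEN_S

logger = logging.getLogger(__name__)


@dataclass
class RecordingWindow:
    device_id: str
    start_time: float                 # UTC seconds
    labels: tuple                     # one label per 30-s epoch
    lights_off_time: float | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if self.lights_off_time is None:
            self.lights_off_time = self.start_time
        if self.lights_off_time < self.start_time:
            raise ValueError("lights_off_time precedes start_time")

    @property
    def end_time(self) -> float:
        return self.start_time + len(self.labels) * EPOCH_LEN_S


@dataclass
class AlignedPair:
    start_time: float
    labels_a: tuple
    labels_b: tuple
    padded_a: np.ndarray
    padded_b: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels_a) != len(self.labels_b):
            raise ValueError("aligned sequences must have equal length")

    def __len__(self) -> int:
        return len(self.labels_a)


def _place(w: RecordingWindow, grid_start: float, n: int):
    """Snap a window onto the grid; W-fill and flag uncovered epochs."""
    offset = w.start_time - grid_start
    k = int(round(offset / EPOCH_LEN_S))
    residual = offset - k * EPOCH_LEN_S
    if abs(residual) > 1e-9:
        logger.info("device %s: %.1f s sub-epoch offset snapped to boundary",
                    w.device_id, residual)
    labels = ["W"] * n
    padded = np.ones(n, dtype=bool)
    for i, lab in enumerate(w.labels):
        j = k + i
        if 0 <= j < n:
            labels[j] = lab
            padded[j] = False
    return tuple(labels), padded


def align_pair(a: RecordingWindow, b: RecordingWindow) -> AlignedPair:
    """Align two recordings onto the grid anchored at the earlier lights-off.

    Both label sequences are emitted at equal length covering the union of
    the two windows (from the anchor onward); epochs a device does not
    cover carry W and a padded flag.  Swapping the arguments swaps only the
    padding pattern."""
    if min(a.end_time, b.end_time) <= max(a.start_time, b.start_time):
        raise ValueError("recordings do not overlap in time")
    grid_start = min(a.lights_off_time, b.lights_off_time)
    end = max(a.end_time, b.end_time)
    n = max(1, int(math.ceil((end - grid_start) / EPOCH_LEN_S)))
    labels_a, padded_a = _place(a, grid_start, n)
    labels_b, padded_b = _place(b, grid_start, n)
    return AlignedPair(start_time=grid_start, labels_a=labels_a,
                       labels_b=labels_b, padded_a=padded_a, padded_b=padded_b)
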