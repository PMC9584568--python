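"""Shared fixtures: on-the-fly EDF/WFDB fixture writers and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest


def write_minimal_edf(path, signals, fs, labels, units,
                      phys_range=(-5.0, 5.0)):
    """Write a minimal EDF file (synthetic test fixture, int16 records)."""
    ns = len(signals)
    n_rec = int(len(signals[0]) / fs)
    pmin, pmax = phys_range
    dmin, dmax = -32768, 32767

    def field(vals, w):
        return b"".join(str(v).encode().ljust(w)[:w] for v in vals)

    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2000".ljust(80)
    hdr += b"01.01.00" + b"00.00.00"
    hdr += str(256 * (1 + ns)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(ns).encode().ljust(4)
    hdr += field(labels, 16)
    hdr += field([""] * ns, 80)
    hdr += field(units, 8)
    hdr += field([pmin] * ns, 8) + field([pmax] * ns, 8)
    hdr += field([dmin] * ns, 8) + field([dmax] * ns, 8)
    hdr += field([""] * ns, 80)
    hdr += field([int(fs)] * ns, 8)
    hdr += field([""] * ns, 32)
    assert len(hdr) == 256 * (1 + ns)
    spr = int(fs)
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for sig in signals:
                seg = np.asarray(sig[r * spr:(r + 1) * spr], dtype=float)
                dig = np.round((seg - pmin) / (pmax - pmin)
                               * (dmax - dmin) + dmin).astype("<i2")
                f.write(dig.tobytes())


def write_minimal_wfdb(basepath, signals, fs, names, gain=200.0,
                       fmt="dat"):
    """Write a minimal WFDB record (synthetic test fixture): text header
    plus interleaved int16 ``.dat`` or a MATLAB ``.mat`` matrix."""
    basepath = str(basepath)
    n_sig = len(signals)
    n = len(signals[0])
    record = basepath.rsplit("/", 1)[-1]
    sig_file = f"{record}.{ 'mat' if fmt == 'mat' else 'dat'}"
    lines = [f"{record} {n_sig} {fs} {n}"]
    for name in names:
        lines.append(f"{sig_file} 16 {gain}(0)/mV 16 0 0 0 0 {name}")
    with open(basepath + ".hea", "w") as f:
        f.write("\n".join(lines) + "\n")
    dig = np.round(np.asarray(signals, dtype=float) * gain).astype("<i2")
    if fmt == "mat":
        from scipy.io import savemat

        savemat(basepath + ".mat", {"val": dig})
    else:
        dig.T.reshape(-1).tofile(basepath + ".dat")


@pytest.fixture
def edf_writer():
    return write_minimal_edf


@pytest.fixture
def wfdb_writer():
    return write_minimal_wfdb


@pytest.fixture(scope="session")
def clean_ecg_10min():
    """10 minutes of noise-free synthetic ECG at 256 Hz with ground truth."""
    from somnohr.synthetic import (EcgSynthConfig, HypnogramModelConfig,
                                   simulate_hypnogram, simulate_rr_series,
                                   synthesize_ecg)

    h = simulate_hypnogram(HypnogramModelConfig(n_epochs=20, seed=42))
    rr = simulate_rr_series(h, seed=43)
    ecg = synthesize_ecg(rr, EcgSynthConfig(fs=256.0, baseline_wander_amp=0.0))
    return ecg, rr
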