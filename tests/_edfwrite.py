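"""Minimal synthetic EDF writer for test fixtures.

Produces a bare-bones but standard-conforming EDF file (one data record
per second, 16-bit samples) purely so reader tests have a file to open;
no installed package in the test environment can write EDF.  Not part of
the package API and not suitable for real data.
"""

from __future__ import annotations

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width}")
    return b.ljust(width)


def write_edf(path, samples_uv: np.ndarray, fs: float, channels: list[str]) -> None:
    """Write channels x time microvolt data as a synthetic EDF file.

    Requires integer fs and a whole number of seconds of data.
    """
    samples_uv = np.asarray(samples_uv, dtype=float)
    n_ch, n_samp = samples_uv.shape
    fs_i = int(fs)
    if fs_i != fs or n_samp % fs_i != 0:
        raise ValueError("need integer fs and whole seconds of data")
    n_records = n_samp // fs_i

    # per-channel scaling to int16 over a fixed +-1000 uV physical range
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    clipped = np.clip(samples_uv, phys_min, phys_max)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((clipped - phys_min) * scale + dig_min).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))                       # version
        fh.write(_pad("X X X X", 80))                # patient id (anonymous)
        fh.write(_pad("Startdate X X X X", 80))      # recording id
        fh.write(_pad("01.01.00", 8))                # start date
        fh.write(_pad("00.00.00", 8))                # start time
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))                       # reserved
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))                       # record duration, s
        fh.write(_pad(str(n_ch), 4))
        for ch in channels:
            fh.write(_pad(ch, 16))                   # label
        for _ in channels:
            fh.write(_pad("", 80))                   # transducer
        for _ in channels:
            fh.write(_pad("uV", 8))                  # physical dimension
        for _ in channels:
            fh.write(_pad(str(phys_min), 8))
        for _ in channels:
            fh.write(_pad(str(phys_max), 8))
        for _ in channels:
            fh.write(_pad(str(dig_min), 8))
        for _ in channels:
            fh.write(_pad(str(dig_max), 8))
        for _ in channels:
            fh.write(_pad("", 80))                   # prefiltering
        for _ in channels:
            fh.write(_pad(str(fs_i), 8))             # samples per record
        for _ in channels:
            fh.write(_pad("", 32))                   # reserved
        for rec in range(n_records):
            chunk = digital[:, rec * fs_i : (rec + 1) * fs_i]
            fh.write(chunk.tobytes())
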