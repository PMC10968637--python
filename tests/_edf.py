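"""Minimal EDF writer for test fixtures (synthetic data only).

Writes a standard-conformant EDF file (16-bit samples, one data record per
second) just rich enough for standard readers; not a general exporter.
"""

from __future__ import annotations

import numpy as np


def write_minimal_edf(path, signal: np.ndarray, fs: int, ch_names: list[str]) -> None:
    n_ch, n_s = signal.shape
    assert n_s % int(fs) == 0, "signal length must be a whole number of seconds"
    n_rec = n_s // int(fs)
    pmin, pmax, dmin, dmax = -1000.0, 1000.0, -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s.ljust(n)[:n].encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("X", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    hdr += b"".join(pad(c, 16) for c in ch_names)
    hdr += b"".join(pad("", 80) for _ in ch_names)
    hdr += b"".join(pad("uV", 8) for _ in ch_names)
    hdr += b"".join(pad(str(pmin), 8) for _ in ch_names)
    hdr += b"".join(pad(str(pmax), 8) for _ in ch_names)
    hdr += b"".join(pad(str(dmin), 8) for _ in ch_names)
    hdr += b"".join(pad(str(dmax), 8) for _ in ch_names)
    hdr += b"".join(pad("", 80) for _ in ch_names)
    hdr += b"".join(pad(str(int(fs)), 8) for _ in ch_names)
    hdr += b"".join(pad("", 32) for _ in ch_names)

    dig = np.clip(
        np.round((signal - pmin) / (pmax - pmin) * (dmax - dmin) + dmin), dmin, dmax
    ).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(dig[c, r * int(fs) : (r + 1) * int(fs)].tobytes())
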