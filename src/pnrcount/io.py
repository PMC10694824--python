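"""Reading and writing photon-count histograms as two-column CSV.

Format: a header line ``photon_count,occurrences`` followed by one row per
bin.  Bins may appear in any order; missing intermediate bins are treated as
zero.  Counts are written as plain integers (never scientific notation) so
histograms with ``nu`` up to 1e14 round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import PhotonHistogram

__all__ = ["read_histogram", "write_histogram"]

HEADER = "photon_count,occurrences"


def read_histogram(path: str | Path) -> PhotonHistogram:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip().replace(" ", "") != HEADER:
        raise ValueError(f"{path}: expected header '{HEADER}'")
    bins: dict[int, int] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two comma-separated fields, got {raw!r}")
        try:
            i, c = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer value in {raw!r}") from exc
        if i < 0:
            raise ValueError(f"{path}:{lineno}: negative photon number {i}")
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative count {c}")
        if i in bins:
            raise ValueError(f"{path}:{lineno}: duplicate bin {i}")
        bins[i] = c
    if not bins:
        raise ValueError(f"{path}: no data rows")
    counts = np.zeros(max(bins) + 1, dtype=float)
    for i, c in bins.items():
        counts[i] = c
    return PhotonHistogram(counts)


def write_histogram(hist: PhotonHistogram, path: str | Path) -> None:
    path = Path(path)
    rows = [HEADER]
    for i, c in enumerate(hist.counts):
        rows.append(f"{i},{int(round(c))}")
    path.write_text("\n".join(rows) + "\n")
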