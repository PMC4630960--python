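"""Signal-table CSV dialect.

A documented plain-text interchange format for peak-height tables: the first
line is the dispensation order string; every following line is
``well_id,h1,...,hm`` with m the order length.  Heights are written with six
significant digits, so write-then-read round-trips up to that formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pyrogram import ALPHABET, PyroSignal


@dataclass
class SignalTable:
    """Peak-height table: one multiplex well per row under one order."""

    order: str
    well_ids: list[str]
    heights: np.ndarray  # (n_wells, m)

    def __post_init__(self) -> None:
        self.heights = np.atleast_2d(np.asarray(self.heights, float))
        if self.heights.shape != (len(self.well_ids), len(self.order)):
            raise ValueError("heights shape must be (n_wells, order length)")

    def __len__(self) -> int:
        return len(self.well_ids)

    def signals(self) -> list[PyroSignal]:
        return [PyroSignal(h, order_id=self.order, well_id=w)
                for w, h in zip(self.well_ids, self.heights)]


class SignalFormatError(ValueError):
    pass


def read_signals(path) -> SignalTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise SignalFormatError(f"{path}: empty file")
    order = lines[0].strip()
    if not order or set(order) - ALPHABET:
        raise SignalFormatError(
            f"{path}:1: header must be a dispensation order over ACGT, got {order!r}")
    m = len(order)
    well_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != m + 1:
            raise SignalFormatError(
                f"{path}:{lineno}: expected {m + 1} fields (well_id + {m} heights), "
                f"got {len(parts)}")
        try:
            heights = [float(x) for x in parts[1:]]
        except ValueError as e:
            raise SignalFormatError(f"{path}:{lineno}: non-numeric height ({e})")
        if any(h < 0 for h in heights):
            raise SignalFormatError(f"{path}:{lineno}: negative peak height")
        well_ids.append(parts[0])
        rows.append(heights)
    if not rows:
        raise SignalFormatError(f"{path}: no signal rows")
    return SignalTable(order=order, well_ids=well_ids, heights=np.array(rows))


def write_signals(table: SignalTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(table.order + "\n")
        for wid, row in zip(table.well_ids, table.heights):
            fh.write(wid + "," + ",".join(f"{h:.6g}" for h in row) + "\n")
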