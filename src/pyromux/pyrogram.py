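"""Deterministic pyrogram physics.

Pyrosequencing reads a template by dispensing one nucleotide at a time.
At each dispensation the polymerase extends through the homopolymer run of
that base at the current position (or not at all), and the emitted light is
proportional to the number of bases incorporated.  A pyrogram is therefore a
vector of peak heights, one per dispensation, and for a known template it is
fully determined by the template sequence and the dispensation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_nucseq(seq: str, name: str = "sequence") -> str:
    """Validate a nucleotide string over {A,C,G,T}; returns it unchanged."""
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError(f"{name} must be a non-empty string, got {seq!r}")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{name} contains invalid characters {sorted(bad)}: {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement. Involution: rc(rc(s)) == s."""
    validate_nucseq(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DispensationOrder:
    """A fixed sequence of dispensed nucleotides, with an optional label."""

    dispensations: str
    id: str = ""

    def __post_init__(self) -> None:
        validate_nucseq(self.dispensations, "dispensation order")

    def __len__(self) -> int:
        return len(self.dispensations)

    def __str__(self) -> str:
        return self.dispensations


def _order_str(order) -> str:
    s = order.dispensations if isinstance(order, DispensationOrder) else order
    return validate_nucseq(s, "dispensation order")


@dataclass
class PyroSignal:
    """A vector of non-negative peak heights, one per dispensation.

    Theoretical signals carry integer incorporation counts; observed and
    standardized signals are real-valued.  One type serves both so the
    dictionary and instrument data share a single code path.
    """

    heights: np.ndarray
    order_id: str = ""
    standardized: bool = False
    well_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 1:
            raise ValueError("heights must be a 1-D vector")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")

    def __len__(self) -> int:
        return len(self.heights)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.heights, dtype=dtype)


def simulate_pyrogram(seq: str, order) -> PyroSignal:
    """Simulate the theoretical pyrogram of ``seq`` under a dispensation order.

    A read pointer starts at the first base.  Each dispensation incorporates
    the full homopolymer run of that base at the pointer (possibly zero) and
    the pointer advances by the run length.  The sum of heights equals the
    number of template bases consumed, which never exceeds ``len(seq)``.
    """
    validate_nucseq(seq)
    disp = _order_str(order)
    heights = np.zeros(len(disp), dtype=float)
    pos = 0
    n = len(seq)
    for j, base in enumerate(disp):
        run = 0
        while pos + run < n and seq[pos + run] == base:
            run += 1
        heights[j] = run
        pos += run
    oid = order.id if isinstance(order, DispensationOrder) else ""
    return PyroSignal(heights=heights, order_id=oid, standardized=False)


def consumed_length(seq: str, order) -> int:
    """Number of template bases read by ``order``; equals ``len(seq)`` iff
    the order fully sequences the template."""
    return int(simulate_pyrogram(seq, order).heights.sum())


def fuph_standardize(signal: PyroSignal, fuph: float) -> PyroSignal:
    """Divide all peak heights by the first unitary peak height (FUPH).

    Standardization brings instrument signals onto the incorporation-count
    scale of theoretical pyrograms (whose FUPH is 1 by construction).
    """
    if not fuph > 0:
        raise ValueError(f"FUPH must be positive, got {fuph}")
    return replace(signal, heights=signal.heights / float(fuph), standardized=True)
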