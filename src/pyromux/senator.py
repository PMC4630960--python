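"""Dispensation-order design: cover every allele template and de-correlate atoms.

The designer searches for a nucleotide dispensation order whose uniplex atom
signals have low pairwise Pearson correlation, so that a multiplex signal can
be decomposed unambiguously.  Search is a deterministic breadth-first beam:
orders grow one dispensation at a time (consecutive repeats are pruned — a
repeated nucleotide can never incorporate after an exhausted run), partial
candidates are ranked by remaining uncovered template bases then partial atom
correlation, and feasible candidates compete lexicographically on
(max pairwise atom correlation, length, alphabetical order string).

Two coverage notions are supported.  ``"full"`` requires every allele
template to be sequenced end to end.  ``"variant"`` only requires the read
to extend through the variant position of both alleles — the minimum needed
to genotype — which is the property the shipped panels' printed orders
actually satisfy (several of their templates are read only partially).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dictionary import (
    PyroDictionary,
    ambiguity_index,
    build_dictionary,
    enumerate_combination_signals,
    pairwise_correlations,
)
from .panel import Panel
from .pyrogram import DispensationOrder, simulate_pyrogram

_BASES = "ACGT"


def atom_correlation_matrix(dictionary: PyroDictionary) -> np.ndarray:
    """Pairwise Pearson correlations between atom signals (unit diagonal;
    constant atoms correlate 0 with everything)."""
    if len(dictionary) < 2:
        raise ValueError("need at least 2 atoms")
    return pairwise_correlations(dictionary.matrix.T)


def _max_offdiag(C: np.ndarray) -> float:
    mask = ~np.eye(len(C), dtype=bool)
    return float(C[mask].max()) if mask.any() else 0.0


@dataclass(frozen=True)
class OrderSearchConfig:
    max_length: int = 20
    beam_width: int = 64
    coverage: str = "full"  # "full" | "variant"
    seed: int = 0  # reserved for stochastic restarts; search itself is deterministic

    def __post_init__(self) -> None:
        if self.max_length < 1 or self.beam_width < 1:
            raise ValueError("max_length and beam_width must be >= 1")
        if self.coverage not in ("full", "variant"):
            raise ValueError(f"unknown coverage mode {self.coverage!r}")


def _templates(panel: Panel) -> list[tuple[str, str, str, int]]:
    """(snp_id, allele, template, required_read_length) per allele."""
    out = []
    for snp in panel:
        for allele in snp.alleles:
            t = snp.template(allele)
            out.append((snp.snp_id, allele, t, len(t)))
    return out


def _required(panel: Panel, coverage: str) -> list[tuple[str, str, str, int]]:
    req = _templates(panel)
    if coverage == "variant":
        out = []
        for snp in panel:
            for allele in snp.alleles:
                t = snp.template(allele)
                # variant position on the sequencing strand
                other = snp.template(
                    snp.allele_alt if allele == snp.allele_ref else snp.allele_ref)
                vpos = next(i for i, (a, b) in enumerate(zip(t, other)) if a != b)
                out.append((snp.snp_id, allele, t, vpos + 1))
        return out
    return req


def _consumed(template: str, order: str) -> int:
    pos = 0
    n = len(template)
    for base in order:
        while pos < n and template[pos] == base:
            pos += 1
    return pos


def _objective(panel: Panel, order: str) -> float:
    sigs = np.array([simulate_pyrogram(t, order).heights
                     for _, _, t, _ in _templates(panel)])
    return _max_offdiag(pairwise_correlations(sigs))


def select_order(panel: Panel, cfg: OrderSearchConfig = OrderSearchConfig()
                 ) -> tuple[DispensationOrder, float]:
    """Beam-search a dispensation order for ``panel``.

    Returns the best feasible order and its objective (max pairwise atom
    correlation).  Raises if no feasible order exists within
    ``cfg.max_length``, naming the uncovered templates.
    """
    req = _required(panel, cfg.coverage)
    best: Optional[tuple[float, int, str]] = None  # (objective, length, order)
    beam: list[str] = [""]
    for _ in range(cfg.max_length):
        candidates = []
        for prefix in beam:
            for b in _BASES:
                if prefix and prefix[-1] == b:
                    continue  # a consecutive repeat can never incorporate
                candidates.append(prefix + b)
        scored = []
        for cand in candidates:
            remaining = sum(max(0, need - _consumed(t, cand))
                            for _, _, t, need in req)
            if remaining == 0:
                obj = _objective(panel, cand)
                key = (obj, len(cand), cand)
                if best is None or key < best:
                    best = key
            scored.append((remaining, _objective(panel, cand), cand))
        scored.sort()
        beam = [c for _, _, c in scored[: cfg.beam_width]]
    if best is None:
        probe = beam[0] if beam else ""
        uncovered = sorted(f"{sid}:{allele}" for sid, allele, t, need in req
                           if _consumed(t, probe) < need)
        raise RuntimeError(
            f"no feasible order of length <= {cfg.max_length} "
            f"(coverage={cfg.coverage}); uncovered templates: {uncovered}"
        )
    obj, _, order = best
    return DispensationOrder(order, id=f"designed-{panel.name}"), obj


@dataclass
class OrderReport:
    """Validation of a dispensation order against a panel."""

    order: str
    full_coverage: dict[str, bool]  # "snp:allele" -> template fully sequenced
    variant_coverage: dict[str, bool]  # read extends through the variant site
    atom_corr_max: float
    ambiguity_max_corr: float
    unique_combinations: bool

    @property
    def all_fully_covered(self) -> bool:
        return all(self.full_coverage.values())

    @property
    def all_variants_covered(self) -> bool:
        return all(self.variant_coverage.values())

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "full_coverage": self.full_coverage,
            "variant_coverage": self.variant_coverage,
            "all_fully_covered": self.all_fully_covered,
            "all_variants_covered": self.all_variants_covered,
            "atom_corr_max": self.atom_corr_max,
            "ambiguity_max_corr": self.ambiguity_max_corr,
            "unique_combinations": self.unique_combinations,
        }


def validate_order(panel: Panel, order) -> OrderReport:
    """Coverage, atom-correlation and signal-uniqueness report for an order."""
    order_s = str(order if not isinstance(order, DispensationOrder)
                  else order.dispensations)
    tmp_panel = Panel(name=panel.name, snps=panel.snps,
                      order=DispensationOrder(order_s), group=panel.group)
    full = {f"{sid}:{al}": _consumed(t, order_s) >= need
            for sid, al, t, need in _required(tmp_panel, "full")}
    var = {f"{sid}:{al}": _consumed(t, order_s) >= need
           for sid, al, t, need in _required(tmp_panel, "variant")}
    d = build_dictionary(tmp_panel)
    corr_max = _max_offdiag(atom_correlation_matrix(d)) if len(d) > 1 else 0.0
    combos = enumerate_combination_signals(tmp_panel, d)
    M = np.array([sig for _, sig in combos])
    unique = len(np.unique(M, axis=0)) == len(M)
    if len(combos) > 1:
        try:
            amb = ambiguity_index(tmp_panel, d).max_corr
        except ValueError:  # every combination signal constant (degenerate order)
            amb = 0.0
    else:
        amb = 0.0
    return OrderReport(order=order_s, full_coverage=full, variant_coverage=var,
                       atom_corr_max=corr_max, ambiguity_max_corr=amb,
                       unique_combinations=unique)
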