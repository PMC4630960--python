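"""Turnaround-time, reagent-cost and waste comparison of uniplex vs multiplex.

Genotyping nine SNPs per patient classically takes nine uniplex PCR +
pyrosequencing runs; the multiplex design replaces them with one quadruplex
and one quintuplex run.  The comparison model holds the per-step durations
and per-patient reagent costs as data; shared preparation steps (buffy coat,
DNA extraction, quantification) are identical in both workflows and excluded
from the headline totals, but reported separately.  All arithmetic is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class CostTatModel:
    """Per-step durations (min) and per-patient reagent costs (US$)."""

    pcr_min: float = 165.0
    pyro_uniplex_min: float = 60.0
    pyro_multiplex_min: float = 70.0
    shared_prep_min: tuple[float, float, float] = (30.0, 30.0, 20.0)  # buffy, extraction, quantification
    cost_extraction: float = 16.5
    cost_pcr_uniplex: float = 71.0
    cost_pyro_uniplex: float = 141.5
    cost_pcr_multiplex: float = 16.0
    cost_pyro_multiplex: float = 31.5
    currency: str = "US$"


#: waste items for a full 96-well plate run: name -> (uniplex, multiplex)
DEFAULT_WASTE = {
    "pcr_plates": (9, 2),
    "pipette_tips_pcr": (936, 222),
    "pyrosequencing_plates": (9, 2),
    "pipette_tips_pyrosequencing": (918, 211),
    "reagent_bottles": (18, 4),
}


@dataclass(frozen=True)
class TatReport:
    uniplex_min: float
    multiplex_min: float
    reduction_pct: float
    shared_prep_min: float

    def to_dict(self) -> dict:
        return {"uniplex_min": self.uniplex_min, "multiplex_min": self.multiplex_min,
                "reduction_pct": self.reduction_pct,
                "shared_prep_min": self.shared_prep_min}


@dataclass(frozen=True)
class CostReport:
    uniplex_total: float
    multiplex_total: float
    reduction_pct: float
    currency: str = "US$"

    def to_dict(self) -> dict:
        return {"uniplex_total": self.uniplex_total,
                "multiplex_total": self.multiplex_total,
                "reduction_pct": self.reduction_pct, "currency": self.currency}


def tat_compare(model: CostTatModel = CostTatModel(),
                n_uniplex_runs: int = 9, n_multiplex_runs: int = 2) -> TatReport:
    """Total assay time: (PCR + pyrosequencing) x number of runs, per workflow."""
    if n_uniplex_runs < 1 or n_multiplex_runs < 1:
        raise ValueError("run counts must be >= 1")
    uni = (model.pcr_min + model.pyro_uniplex_min) * n_uniplex_runs
    multi = (model.pcr_min + model.pyro_multiplex_min) * n_multiplex_runs
    return TatReport(
        uniplex_min=uni, multiplex_min=multi,
        reduction_pct=100.0 * (1.0 - multi / uni),
        shared_prep_min=sum(model.shared_prep_min),
    )


def cost_compare(model: CostTatModel = CostTatModel()) -> CostReport:
    """Per-patient reagent cost: extraction + PCR + pyrosequencing."""
    uni = model.cost_extraction + model.cost_pcr_uniplex + model.cost_pyro_uniplex
    multi = model.cost_extraction + model.cost_pcr_multiplex + model.cost_pyro_multiplex
    red = 100.0 * (1.0 - multi / uni) if uni > 0 else 0.0
    return CostReport(uniplex_total=uni, multiplex_total=multi,
                      reduction_pct=red, currency=model.currency)


def waste_compare(items: Mapping[str, tuple[float, float]] = None) -> dict:
    """Uniplex vs multiplex consumable counts with percent reduction per item."""
    items = DEFAULT_WASTE if items is None else items
    out = {}
    for name, (uni, multi) in items.items():
        red = 100.0 * (1.0 - multi / uni) if uni else 0.0
        out[name] = {"uniplex": uni, "multiplex": multi, "reduction_pct": red}
    return out
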