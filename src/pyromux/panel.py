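"""SNP panel definitions and genotype states.

A panel groups bi-allelic SNPs into one multiplex pyrosequencing assay with
a shared dispensation order.  Each SNP carries two short unique nucleotide
sequences (UNS), one per allele, as expected downstream of its sequencing
primer.  UNS strings are stored exactly as tabulated (genomic sense); for
assays sequenced with a reverse primer (``as_read = False``) the reverse
complement is taken before simulating pyrograms.

The nine prostate-cancer risk SNPs used throughout the tests ship as a
built-in fixture: a quadruplex group (rs1016343, rs10993994, rs16901979 and
the X-linked rs5945619) read under order CTGCATGACTCGAT, and a quintuplex
group (rs10896449, rs1859962, rs4242382, rs4430796, rs6983267) under
AGATCGCTACGACTG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .pyrogram import DispensationOrder, reverse_complement, validate_nucseq

QUADRUPLEX_ORDER = DispensationOrder("CTGCATGACTCGAT", id="quadruplex")
QUINTUPLEX_ORDER = DispensationOrder("AGATCGCTACGACTG", id="quintuplex")

#: genotype states for diploid and hemizygous (single-copy) SNPs
DIPLOID_STATES = ("hom_ref", "het", "hom_alt")
HAPLOID_STATES = ("hemi_ref", "hemi_alt")

#: allele weights (w_ref, w_alt) per genotype state; the heterozygote carries
#: each allele at half height (equal template amounts)
STATE_WEIGHTS = {
    "hom_ref": (1.0, 0.0),
    "het": (0.5, 0.5),
    "hom_alt": (0.0, 1.0),
    "hemi_ref": (1.0, 0.0),
    "hemi_alt": (0.0, 1.0),
}


@dataclass(frozen=True)
class SNPDef:
    """One bi-allelic SNP of a multiplex panel."""

    snp_id: str
    chromosome: str
    allele_ref: str
    allele_alt: str
    uns_ref: str
    uns_alt: str
    orientation: str = "forward"  # strand of the sequencing primer design
    as_read: bool = True  # False: reverse-complement UNS before simulation
    ploidy: int = 2
    maf: float = 0.0  # minor allele frequency, assigned to allele_alt
    allelic_or: float = 1.0

    def __post_init__(self) -> None:
        validate_nucseq(self.uns_ref, f"{self.snp_id} uns_ref")
        validate_nucseq(self.uns_alt, f"{self.snp_id} uns_alt")
        if self.uns_ref == self.uns_alt:
            raise ValueError(f"{self.snp_id}: allele UNS must differ")
        if len(self.uns_ref) != len(self.uns_alt):
            raise ValueError(f"{self.snp_id}: allele UNS must have equal length")
        ndiff = sum(a != b for a, b in zip(self.uns_ref, self.uns_alt))
        if ndiff != 1:
            raise ValueError(
                f"{self.snp_id}: allele UNS differ at {ndiff} positions, expected 1"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.snp_id}: bad orientation {self.orientation!r}")
        if self.ploidy not in (1, 2):
            raise ValueError(f"{self.snp_id}: ploidy must be 1 or 2")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF must lie in [0, 0.5]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_ref, self.allele_alt)

    @property
    def variant_position(self) -> int:
        """0-based position at which the two UNS differ."""
        return next(
            i for i, (a, b) in enumerate(zip(self.uns_ref, self.uns_alt)) if a != b
        )

    def uns(self, allele: str) -> str:
        """UNS of one allele, as tabulated (genomic sense)."""
        if allele == self.allele_ref:
            return self.uns_ref
        if allele == self.allele_alt:
            return self.uns_alt
        raise KeyError(f"{self.snp_id} has no allele {allele!r}")

    def template(self, allele: str) -> str:
        """Sequence actually read by the sequencing primer for one allele."""
        u = self.uns(allele)
        return u if self.as_read else reverse_complement(u)

    @property
    def states(self) -> tuple[str, ...]:
        return DIPLOID_STATES if self.ploidy == 2 else HAPLOID_STATES


@dataclass(frozen=True)
class GenotypeState:
    """A genotype of one SNP: hom/het for diploids, hemi for single-copy."""

    snp_id: str
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATE_WEIGHTS:
            raise ValueError(f"unknown genotype state {self.state!r}")

    @property
    def weights(self) -> tuple[float, float]:
        return STATE_WEIGHTS[self.state]

    def label(self, snp: SNPDef) -> str:
        """Human-readable genotype, e.g. ``C/T`` or a bare ``T`` for hemizygotes."""
        r, a = snp.alleles
        return {
            "hom_ref": f"{r}/{r}",
            "het": f"{r}/{a}",
            "hom_alt": f"{a}/{a}",
            "hemi_ref": r,
            "hemi_alt": a,
        }[self.state]

    @staticmethod
    def from_label(snp: SNPDef, label: str) -> "GenotypeState":
        """Parse ``C/T``-style (order-insensitive) or single-letter labels."""
        label = label.strip()
        r, a = snp.alleles
        if "/" in label:
            pair = frozenset(label.split("/"))
            if snp.ploidy != 2:
                raise ValueError(f"{snp.snp_id} is not diploid: {label!r}")
            if pair == {r}:
                return GenotypeState(snp.snp_id, "hom_ref")
            if pair == {a}:
                return GenotypeState(snp.snp_id, "hom_alt")
            if pair == {r, a}:
                return GenotypeState(snp.snp_id, "het")
        else:
            prefix = "hemi" if snp.ploidy == 1 else "hom"
            if label == r:
                return GenotypeState(snp.snp_id, f"{prefix}_ref")
            if label == a:
                return GenotypeState(snp.snp_id, f"{prefix}_alt")
        raise ValueError(f"cannot parse genotype {label!r} for {snp.snp_id} ({r}/{a})")


@dataclass(frozen=True)
class Panel:
    """An ordered set of SNPs assayed together under one dispensation order."""

    name: str
    snps: tuple[SNPDef, ...]
    order: DispensationOrder
    group: str = "custom"

    def __post_init__(self) -> None:
        if len(self.snps) == 0:
            raise ValueError("panel must contain at least one SNP")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")

    def __iter__(self):
        return iter(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    def snp(self, snp_id: str) -> SNPDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(f"panel {self.name!r} has no SNP {snp_id!r}")


# ---------------------------------------------------------------------------
# panel file I/O and built-in fixtures

_PANEL_COLUMNS = [
    "snp_id", "chromosome", "group", "allele_ref", "allele_alt",
    "uns_ref", "uns_alt", "orientation", "as_read", "ploidy", "maf", "allelic_or",
]


def _snp_from_record(rec: dict) -> SNPDef:
    as_read = rec["as_read"]
    if isinstance(as_read, str):
        as_read = as_read.strip().lower() in ("true", "1", "yes")
    return SNPDef(
        snp_id=str(rec["snp_id"]),
        chromosome=str(rec["chromosome"]),
        allele_ref=str(rec["allele_ref"]),
        allele_alt=str(rec["allele_alt"]),
        uns_ref=str(rec["uns_ref"]),
        uns_alt=str(rec["uns_alt"]),
        orientation=str(rec["orientation"]),
        as_read=bool(as_read),
        ploidy=int(rec["ploidy"]),
        maf=float(rec["maf"]),
        allelic_or=float(rec["allelic_or"]),
    )


def load_panel(path, name: Optional[str] = None,
               order: Optional[str] = None, group: Optional[str] = None) -> Panel:
    """Load a panel from TSV (columns as in the shipped fixture) or JSON.

    With ``group`` set, only SNPs of that group are kept.  ``order`` may be
    given explicitly; for the shipped groups it defaults to the printed
    quadruplex/quintuplex orders.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["snps"]
        order = order or payload.get("order")
        name = name or payload.get("name", path.stem)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(_PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel file {path} lacks columns {sorted(missing)}")
        records = df.to_dict("records")
        name = name or path.stem
    if group is not None:
        records = [r for r in records if str(r.get("group", "")) == group]
        if not records:
            raise ValueError(f"no SNPs of group {group!r} in {path}")
    snps = tuple(_snp_from_record(r) for r in records)
    if order is None:
        groups = {str(r.get("group", "")) for r in records}
        builtin = {"quadruplex": QUADRUPLEX_ORDER, "quintuplex": QUINTUPLEX_ORDER}
        if len(groups) == 1 and next(iter(groups)) in builtin:
            odo = builtin[next(iter(groups))]
        else:
            raise ValueError("dispensation order required for this panel")
    else:
        odo = order if isinstance(order, DispensationOrder) else DispensationOrder(order)
    return Panel(name=name, snps=snps, order=odo,
                 group=group or "custom")


def save_panel(panel: Panel, path) -> None:
    """Write a panel back to the TSV dialect of the shipped fixture."""
    rows = []
    for s in panel.snps:
        rows.append({
            "snp_id": s.snp_id, "chromosome": s.chromosome, "group": panel.group,
            "allele_ref": s.allele_ref, "allele_alt": s.allele_alt,
            "uns_ref": s.uns_ref, "uns_alt": s.uns_alt,
            "orientation": s.orientation, "as_read": str(s.as_read).lower(),
            "ploidy": s.ploidy, "maf": s.maf, "allelic_or": s.allelic_or,
        })
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def _fixture_path(filename: str):
    return resources.files("pyromux.data").joinpath(filename)


def _builtin_records() -> list[dict]:
    with resources.as_file(_fixture_path("pca9_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str).to_dict("records")


def builtin_panel(group: str) -> Panel:
    """The shipped 9-SNP prostate-cancer panel, by multiplex group.

    ``group`` is ``"quadruplex"`` or ``"quintuplex"``.
    """
    orders = {"quadruplex": QUADRUPLEX_ORDER, "quintuplex": QUINTUPLEX_ORDER}
    if group not in orders:
        raise KeyError(f"unknown built-in group {group!r}")
    records = [r for r in _builtin_records() if r["group"] == group]
    return Panel(
        name=f"pca9-{group}",
        snps=tuple(_snp_from_record(r) for r in records),
        order=orders[group],
        group=group,
    )


def quadruplex_panel() -> Panel:
    return builtin_panel("quadruplex")


def quintuplex_panel() -> Panel:
    return builtin_panel("quintuplex")


def builtin_cohort() -> pd.DataFrame:
    """The 10-patient reference genotype table (wide form, one SNP per column)."""
    with resources.as_file(_fixture_path("pca9_cohort.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)
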