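"""Standardized learning dictionaries of uniplex atom signals.

Each SNP allele contributes one theoretical "atom": the pyrogram of its
allele template under the panel's dispensation order, FUPH-standardized
(theoretical FUPH = 1).  Experimental uniplex signals can be appended after
FUPH standardization; they are used alongside, not instead of, the
theoretical atoms.  A multiplex pyro-signal is modelled as a non-negative
combination of atoms, with heterozygotes contributing both allele atoms at
half height.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .panel import GenotypeState, Panel, SNPDef
from .pyrogram import PyroSignal, fuph_standardize, simulate_pyrogram


@dataclass
class Atom:
    """One standardized uniplex pyro-signal for a single SNP allele."""

    snp_id: str
    allele: str
    source: str  # "theoretical" | "experimental"
    signal: PyroSignal
    duplicate_of: Optional[str] = None  # label of an identical theoretical atom

    @property
    def label(self) -> str:
        return f"{self.snp_id}:{self.allele}" + (
            "" if self.source == "theoretical" else f":{self.source}"
        )


@dataclass
class PyroDictionary:
    """Ordered collection of atoms sharing one dispensation order."""

    atoms: list[Atom]
    order_id: str = ""

    def __post_init__(self) -> None:
        lengths = {len(a.signal) for a in self.atoms}
        if len(lengths) > 1:
            raise ValueError("all atoms must share one dispensation order length")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_dispensations(self) -> int:
        return len(self.atoms[0].signal)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    @property
    def matrix(self) -> np.ndarray:
        """m-dispensations x K-atoms design matrix."""
        return np.column_stack([a.signal.heights for a in self.atoms])

    def atoms_for(self, snp_id: str, allele: Optional[str] = None) -> list[Atom]:
        out = [a for a in self.atoms if a.snp_id == snp_id]
        if allele is not None:
            out = [a for a in out if a.allele == allele]
        if not out:
            raise KeyError(f"dictionary has no atom for {snp_id!r}"
                           + (f" allele {allele!r}" if allele else ""))
        return out

    @property
    def distinct_theoretical_count(self) -> int:
        """Number of distinct theoretical atom signals (duplicates counted once)."""
        vecs = {tuple(a.signal.heights) for a in self.atoms if a.source == "theoretical"}
        return len(vecs)


def build_dictionary(
    panel: Panel,
    experimental_signals: Optional[Iterable[tuple[str, str, PyroSignal, float]]] = None,
) -> PyroDictionary:
    """Build the standardized dictionary for a panel.

    One theoretical atom per SNP allele (orientation handled by
    ``SNPDef.template``).  ``experimental_signals`` is an optional iterable of
    ``(snp_id, allele, signal, fuph)``; each is FUPH-standardized and
    appended.  Identical theoretical signals are kept but flagged via
    ``duplicate_of`` so callers can detect unresolvable alleles.
    """
    atoms: list[Atom] = []
    seen: dict[tuple, str] = {}
    for snp in panel:
        for allele in snp.alleles:
            sig = simulate_pyrogram(snp.template(allele), panel.order)
            sig.standardized = True  # theoretical FUPH = 1
            atom = Atom(snp_id=snp.snp_id, allele=allele, source="theoretical",
                        signal=sig)
            key = tuple(sig.heights)
            if key in seen:
                atom.duplicate_of = seen[key]
            else:
                seen[key] = atom.label
            atoms.append(atom)
    m = len(panel.order)
    if experimental_signals is not None:
        for snp_id, allele, sig, fuph in experimental_signals:
            panel.snp(snp_id).uns(allele)  # validates snp/allele
            if len(sig) != m:
                raise ValueError(
                    f"experimental signal for {snp_id}:{allele} has length "
                    f"{len(sig)}, expected {m}"
                )
            atoms.append(Atom(snp_id=snp_id, allele=allele, source="experimental",
                              signal=fuph_standardize(sig, fuph)))
    return PyroDictionary(atoms=atoms, order_id=str(panel.order.id or panel.order))


def genotype_signal(dictionary: PyroDictionary, g: GenotypeState) -> PyroSignal:
    """Theoretical uniplex signal of one genotype.

    Homozygous/hemizygous states return the allele atom at weight one; the
    heterozygote is the half-height superposition of both allele atoms (the
    heterozygote correction: homozygote peaks are twice their heterozygous
    counterparts).
    """
    def theo(allele_idx_label=None, allele=None):
        cands = [a for a in dictionary.atoms
                 if a.snp_id == g.snp_id and a.source == "theoretical"
                 and (allele is None or a.allele == allele)]
        if not cands:
            raise KeyError(f"no theoretical atom for {g.snp_id!r}")
        return cands

    cands = theo()
    alleles = []
    for a in cands:
        if a.allele not in alleles:
            alleles.append(a.allele)
    ref, alt = alleles[0], alleles[-1]
    w_ref, w_alt = g.weights
    h = (w_ref * theo(allele=ref)[0].signal.heights
         + w_alt * theo(allele=alt)[0].signal.heights)
    return PyroSignal(heights=h, order_id=dictionary.order_id, standardized=True)


def enumerate_combination_signals(
    panel: Panel,
    dictionary: Optional[PyroDictionary] = None,
    force_diploid: bool = False,
) -> list[tuple[tuple[GenotypeState, ...], np.ndarray]]:
    """All theoretical multiplex signals over the Cartesian product of
    per-SNP genotype states.

    Diploid SNPs contribute three states (hom/het/hom), single-copy SNPs two
    hemizygous states unless ``force_diploid`` enumerates every SNP as
    tri-state (useful to mirror enumeration conventions that ignore ploidy).
    The multiplex signal is the equal-weight sum of per-SNP genotype signals.
    """
    if dictionary is None:
        dictionary = build_dictionary(panel)
    per_snp: list[list[GenotypeState]] = []
    for snp in panel:
        states = ("hom_ref", "het", "hom_alt") if (force_diploid or snp.ploidy == 2) \
            else ("hemi_ref", "hemi_alt")
        per_snp.append([GenotypeState(snp.snp_id, s) for s in states])
    out = []
    cache = {
        (g.snp_id, g.state): genotype_signal(dictionary, g).heights
        for states in per_snp for g in states
    }
    for combo in itertools.product(*per_snp):
        sig = np.sum([cache[(g.snp_id, g.state)] for g in combo], axis=0)
        out.append((combo, sig))
    return out


def _pairwise_pearson_max(matrix: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Max off-diagonal Pearson correlation over rows; constant rows are
    assigned correlation 0 with everything and excluded from the argmax."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    C = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, -np.inf)
    C[~ok, :] = -np.inf
    C[:, ~ok] = -np.inf
    if not np.isfinite(C).any():
        raise ValueError("no valid (non-constant) signal pair")
    i, j = np.unravel_index(np.argmax(C), C.shape)
    return float(C[i, j]), (int(min(i, j)), int(max(i, j)))


def pairwise_correlations(matrix: np.ndarray) -> np.ndarray:
    """Symmetric Pearson correlation matrix over rows, unit diagonal;
    correlations involving a constant row are set to 0."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    C = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class AmbiguityResult:
    """Worst-case similarity between theoretical multiplex signals."""

    max_corr: float
    pair: tuple[tuple[GenotypeState, ...], tuple[GenotypeState, ...]]
    n_combinations: int


def ambiguity_index(
    panel: Panel,
    dictionary: Optional[PyroDictionary] = None,
    force_diploid: bool = False,
) -> AmbiguityResult:
    """Maximum pairwise Pearson correlation over all theoretical multiplex
    genotype-combination signals of a panel.

    A low value means every genotype combination produces a distinctive
    signal, i.e. the dispensation order de-correlates the assay.
    """
    combos = enumerate_combination_signals(panel, dictionary, force_diploid)
    if len(combos) < 2:
        raise ValueError("need at least 2 genotype combinations")
    M = np.array([sig for _, sig in combos])
    mx, (i, j) = _pairwise_pearson_max(M)
    return AmbiguityResult(max_corr=mx, pair=(combos[i][0], combos[j][0]),
                           n_combinations=len(combos))
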