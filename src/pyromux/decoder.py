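"""Sparse non-negative decomposition of multiplex pyro-signals and genotype calls.

An observed multiplex signal y (length m) is modelled as y ~ D x with D the
m x K dictionary of standardized uniplex atoms and x >= 0 the per-atom
contributions.  With penalty 0 this is plain non-negative least squares
(naturally sparse); an optional L1 penalty lambda gives

    min_x ||y - D x||^2 + lambda * sum(x),   x >= 0.

Per SNP, reference and alternate allele weights are aggregated over that
SNP's atoms; the alternate-allele fraction f = w_alt / (w_ref + w_alt)
drives the genotype call (the heterozygote correction is implicit: a
heterozygote places ~half weight on each allele atom).  The confidence index
R is the Pearson correlation between the observed signal and its fitted
reconstruction.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, dictionary built in ``fit``, coefficients via ``transform``,
genotype labels via ``predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso

from .dictionary import PyroDictionary, build_dictionary
from .panel import GenotypeState, Panel
from .pyrogram import PyroSignal


@dataclass
class Decomposition:
    """Non-negative atom contributions fitted to one observed signal."""

    coefficients: np.ndarray  # one per atom, FUPH units
    atom_labels: list[str]
    fitted: np.ndarray
    observed: np.ndarray
    residual_norm: float
    confidence_r: float
    penalty_lambda: float = 0.0


@dataclass
class GenotypeCall:
    """Per-SNP call with allele fraction and signal-contribution shares."""

    snp_id: str
    call: Optional[GenotypeState]
    genotype: str  # e.g. "C/T", "T", or "no_call"
    allele_fraction_alt: float
    contribution_abs: float
    contribution_rel: float  # percent of the well's total SNP contribution
    flags: list[str] = field(default_factory=list)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class AdviserGenotyper(BaseEstimator):
    """Multiplex pyro-signal genotyper by sparse non-negative regression.

    Parameters
    ----------
    panel : Panel
        SNP panel whose dispensation order and allele templates define the
        theoretical dictionary.
    penalty_lambda : float or "auto", default 0.0
        L1 penalty on atom contributions.  0 is plain NNLS.  "auto" picks the
        smallest value on a fixed grid at which every retained atom clears
        ``min_rel_contribution``.
    hom_fraction_max : float, default 0.2
        Alternate-allele fraction at or below which a homozygous/hemizygous
        reference call is made (symmetrically, >= 1 - hom_fraction_max calls
        the alternate).
    het_fraction_lo, het_fraction_hi : float, default 0.3 / 0.7
        Window of alternate-allele fractions called heterozygous (diploid
        SNPs only).  Fractions in neither window yield ``no_call``.
    min_rel_contribution : float, default 1.0
        Percent of total signal below which a SNP's call is flagged
        ``low_contribution``.
    min_confidence_r : float, default 0.95
        Wells whose fit correlation R falls below this flag every call
        ``low_confidence``.
    contribution_mode : {"coefficient", "light"}, default "coefficient"
        Absolute contribution of a SNP: sum of its atom coefficients, or the
        coefficient-weighted total light (sum of atom peak heights).

    Attributes
    ----------
    dictionary_ : PyroDictionary
    matrix_ : ndarray of shape (m, K)
    atom_labels_ : list of str
    n_features_in_ : int
    """

    _LAMBDA_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)

    def __init__(
        self,
        panel: Optional[Panel] = None,
        penalty_lambda=0.0,
        hom_fraction_max: float = 0.2,
        het_fraction_lo: float = 0.3,
        het_fraction_hi: float = 0.7,
        min_rel_contribution: float = 1.0,
        min_confidence_r: float = 0.95,
        contribution_mode: str = "coefficient",
    ):
        self.panel = panel
        self.penalty_lambda = penalty_lambda
        self.hom_fraction_max = hom_fraction_max
        self.het_fraction_lo = het_fraction_lo
        self.het_fraction_hi = het_fraction_hi
        self.min_rel_contribution = min_rel_contribution
        self.min_confidence_r = min_confidence_r
        self.contribution_mode = contribution_mode

    # -- fitting ----------------------------------------------------------

    def fit(self, X=None, y=None):
        """Build the dictionary.

        ``X``/``y`` optionally supply experimental uniplex atoms: ``X`` a
        (n_atoms, m) array of raw signals and ``y`` a sequence of
        ``(snp_id, allele, fuph)`` labels.
        """
        if self.panel is None:
            raise ValueError("panel must be set before fit")
        if not (0.0 <= self.hom_fraction_max < self.het_fraction_lo
                < self.het_fraction_hi <= 1.0):
            raise ValueError("require 0 <= hom_fraction_max < het_fraction_lo"
                             " < het_fraction_hi <= 1")
        experimental = None
        if X is not None:
            X = np.atleast_2d(np.asarray(X, float))
            if y is None or len(y) != len(X):
                raise ValueError("experimental signals require one"
                                 " (snp_id, allele, fuph) label per row")
            experimental = [
                (sid, allele, PyroSignal(row), float(fuph))
                for row, (sid, allele, fuph) in zip(X, y)
            ]
        self.dictionary_ = build_dictionary(self.panel, experimental)
        self.matrix_ = self.dictionary_.matrix
        self.atom_labels_ = self.dictionary_.labels
        self.n_features_in_ = self.matrix_.shape[0]
        return self

    def _check_fitted(self):
        if not hasattr(self, "matrix_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    # -- decomposition ----------------------------------------------------

    def _solve(self, y: np.ndarray, lam: float) -> np.ndarray:
        D = self.matrix_
        if lam == 0.0:
            coef, _ = nnls(D, y)
            return coef
        # sklearn Lasso(positive=True) minimizes
        #   1/(2n) ||y - D x||^2 + alpha ||x||_1 with x >= 0,
        # identical to ||y - D x||^2 + lam * sum(x) for alpha = lam / (2n).
        n = len(y)
        model = Lasso(alpha=lam / (2.0 * n), positive=True, fit_intercept=False,
                      max_iter=50000, tol=1e-12)
        model.fit(D, y)
        return np.asarray(model.coef_, float)

    def decompose(self, signal) -> Decomposition:
        """Decompose one observed signal into atom contributions."""
        self._check_fitted()
        y = np.asarray(signal.heights if isinstance(signal, PyroSignal) else signal,
                       dtype=float)
        if y.ndim != 1 or len(y) != self.n_features_in_:
            raise ValueError(
                f"signal length {y.shape} does not match dictionary "
                f"({self.n_features_in_} dispensations)")
        if np.all(y == 0):
            raise ValueError("all-zero signal cannot be decomposed")
        lam = self.penalty_lambda
        if lam == "auto":
            scale = float(np.abs(self.matrix_.T @ y).max())
            for g in self._LAMBDA_GRID:
                lam_try = g * scale
                coef = self._solve(y, lam_try)
                rel = self._relative_contributions(coef)
                retained = [r for r in rel.values() if r > 0]
                if all(r >= self.min_rel_contribution for r in retained):
                    lam = lam_try
                    break
            else:
                lam = self._LAMBDA_GRID[-1] * scale
                coef = self._solve(y, lam)
        else:
            lam = float(lam)
            coef = self._solve(y, lam)
        fitted = self.matrix_ @ coef
        return Decomposition(
            coefficients=coef,
            atom_labels=list(self.atom_labels_),
            fitted=fitted,
            observed=y,
            residual_norm=float(np.linalg.norm(y - fitted)),
            confidence_r=_pearson(y, fitted),
            penalty_lambda=lam,
        )

    def _snp_weights(self, coef: np.ndarray) -> dict[str, tuple[float, float]]:
        """Aggregate atom coefficients into (w_ref, w_alt) per SNP."""
        out = {}
        for snp in self.panel:
            w = {snp.allele_ref: 0.0, snp.allele_alt: 0.0}
            for k, atom in enumerate(self.dictionary_.atoms):
                if atom.snp_id != snp.snp_id:
                    continue
                c = coef[k]
                if self.contribution_mode == "light":
                    c = c * float(atom.signal.heights.sum())
                w[atom.allele] += c
            out[snp.snp_id] = (w[snp.allele_ref], w[snp.allele_alt])
        return out

    def _relative_contributions(self, coef: np.ndarray) -> dict[str, float]:
        weights = self._snp_weights(coef)
        totals = {sid: wr + wa for sid, (wr, wa) in weights.items()}
        grand = sum(totals.values())
        if grand <= 0:
            return {sid: 0.0 for sid in totals}
        return {sid: 100.0 * t / grand for sid, t in totals.items()}

    # -- calling ----------------------------------------------------------

    def call_genotypes(self, dec: Decomposition) -> list[GenotypeCall]:
        """Convert a decomposition into per-SNP genotype calls."""
        self._check_fitted()
        weights = self._snp_weights(dec.coefficients)
        rel = self._relative_contributions(dec.coefficients)
        low_r = dec.confidence_r < self.min_confidence_r
        calls = []
        for snp in self.panel:
            w_ref, w_alt = weights[snp.snp_id]
            total = w_ref + w_alt
            flags = []
            if total > 0:
                f = w_alt / total
            else:
                f = float("nan")
                flags.append("no_signal")
            state = None
            if total > 0:
                if f <= self.hom_fraction_max:
                    state = "hom_ref" if snp.ploidy == 2 else "hemi_ref"
                elif f >= 1.0 - self.hom_fraction_max:
                    state = "hom_alt" if snp.ploidy == 2 else "hemi_alt"
                elif snp.ploidy == 2 and self.het_fraction_lo <= f <= self.het_fraction_hi:
                    state = "het"
                else:
                    flags.append("ambiguous_fraction")
            gstate = GenotypeState(snp.snp_id, state) if state else None
            if rel[snp.snp_id] < self.min_rel_contribution:
                flags.append("low_contribution")
            if low_r:
                flags.append("low_confidence")
            calls.append(GenotypeCall(
                snp_id=snp.snp_id,
                call=gstate,
                genotype=gstate.label(snp) if gstate else "no_call",
                allele_fraction_alt=f,
                contribution_abs=total,
                contribution_rel=rel[snp.snp_id],
                flags=flags,
            ))
        return calls

    # -- sklearn surface --------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Atom coefficients for each row of ``X`` (n_wells, m)."""
        X = np.atleast_2d(np.asarray(X, float))
        return np.array([self.decompose(row).coefficients for row in X])

    def fit_transform(self, X, y=None):
        # fit() takes experimental atoms, not wells; here X is wells to decode
        return self.fit().transform(X)

    def predict(self, X) -> np.ndarray:
        """Genotype labels, shape (n_wells, n_snps), SNPs in panel order."""
        X = np.atleast_2d(np.asarray(X, float))
        out = []
        for row in X:
            calls = self.call_genotypes(self.decompose(row))
            out.append([c.genotype for c in calls])
        return np.array(out, dtype=object)

    def call_table(self, X, well_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Tidy per-(well, SNP) call table with fractions, shares and R."""
        X = np.atleast_2d(np.asarray(X, float))
        if well_ids is None:
            well_ids = [f"well{i + 1}" for i in range(len(X))]
        rows = []
        for wid, row in zip(well_ids, X):
            dec = self.decompose(row)
            for c in self.call_genotypes(dec):
                rows.append({
                    "well_id": wid, "snp_id": c.snp_id, "genotype": c.genotype,
                    "allele_fraction_alt": c.allele_fraction_alt,
                    "contribution_abs": c.contribution_abs,
                    "contribution_rel": c.contribution_rel,
                    "confidence_r": dec.confidence_r,
                    "flags": ";".join(c.flags),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers and assay-balancing helpers

def decompose(observed, panel: Panel, penalty_lambda=0.0, **kwargs) -> Decomposition:
    """Decompose one signal against a panel's theoretical dictionary."""
    est = AdviserGenotyper(panel=panel, penalty_lambda=penalty_lambda, **kwargs).fit()
    return est.decompose(observed)


def call_genotypes(observed, panel: Panel, **kwargs) -> list[GenotypeCall]:
    est = AdviserGenotyper(panel=panel, **kwargs).fit()
    return est.call_genotypes(est.decompose(observed))


def relative_contribution_summary(
    wells: Iterable[Sequence[GenotypeCall]],
) -> dict[str, float]:
    """Mean relative contribution (%) per SNP across wells."""
    acc: dict[str, list[float]] = {}
    n = 0
    for calls in wells:
        n += 1
        for c in calls:
            acc.setdefault(c.snp_id, []).append(c.contribution_rel)
    if n == 0:
        raise ValueError("need at least one well")
    return {sid: float(np.mean(v)) for sid, v in acc.items()}


def suggest_primer_adjustment(
    observed_share: dict[str, float],
    current_conc: dict[str, float],
    target_share: Optional[dict[str, float]] = None,
    conc_grid: Optional[Sequence[float]] = None,
) -> tuple[dict[str, float], list[str]]:
    """Rescale PCR primer concentrations toward balanced signal shares.

    new = current * target_share / observed_share, optionally snapped to the
    nearest value of ``conc_grid``.  SNPs with zero observed share are left
    unchanged and returned in the flagged list.
    """
    if target_share is None:
        equal = 100.0 / len(observed_share)
        target_share = {sid: equal for sid in observed_share}
    adjusted = {}
    flagged = []
    for sid, conc in current_conc.items():
        share = observed_share.get(sid, 0.0)
        if share <= 0:
            adjusted[sid] = conc
            flagged.append(sid)
            continue
        new = conc * target_share[sid] / share
        if conc_grid is not None:
            new = min(conc_grid, key=lambda g: abs(g - new))
        adjusted[sid] = new
    return adjusted, flagged
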