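"""Synthetic cohorts and noisy pyro-signals.

The generator reproduces the statistical structure the decoder assumes: a
multiplex well is the per-SNP-weighted sum of allele atoms (heterozygotes at
half height), scaled by a first-unitary-peak-height factor, with optional
per-SNP amplification imbalance, a constant background and additive Gaussian
peak noise whose standard deviation grows affinely with peak height
(sd = sd_base + sd_prop * height).  Heights are clipped at zero.

Genotypes are drawn under Hardy-Weinberg equilibrium from each SNP's minor
allele frequency; single-copy (X-linked) SNPs in males are hemizygous
Bernoulli draws.  The ten reference patients of the shipped panel are
available as a fixed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dictionary import PyroDictionary, build_dictionary, genotype_signal
from .panel import GenotypeState, Panel, builtin_cohort
from .pyrogram import PyroSignal


@dataclass(frozen=True)
class NoiseModel:
    """Peak-noise and scale model for simulated wells."""

    sd_base: float = 0.03
    sd_prop: float = 0.02
    background: float = 0.0
    fuph_scale: float = 7.0  # raw-height scale; irrelevant to calls (scale invariance)

    def __post_init__(self) -> None:
        if self.sd_base < 0 or self.sd_prop < 0 or self.background < 0:
            raise ValueError("noise parameters must be non-negative")
        if not self.fuph_scale > 0:
            raise ValueError("fuph_scale must be positive")


@dataclass(frozen=True)
class EfficiencyModel:
    """Per-SNP amplification weights (PCR imbalance); default 1.0 each."""

    weights: Mapping[str, float] = field(default_factory=dict)

    def weight(self, snp_id: str) -> float:
        w = self.weights.get(snp_id, 1.0)
        if not w > 0:
            raise ValueError(f"efficiency weight for {snp_id} must be positive")
        return w


@dataclass
class Cohort:
    """Per-patient genotype assignments for one panel."""

    patients: list[dict[str, GenotypeState]]
    sexes: list[str]
    ids: list[str]

    def __len__(self) -> int:
        return len(self.patients)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_cohort(panel: Panel, n: int, seed=0, male_fraction: float = 1.0) -> Cohort:
    """Draw ``n`` patients under Hardy-Weinberg equilibrium.

    The MAF is the frequency of the alternate allele.  Diploid SNPs draw
    hom_ref/het/hom_alt with probabilities ((1-p)^2, 2p(1-p), p^2);
    single-copy SNPs in males draw the alternate allele Bernoulli(p).
    Females carry two X copies and are drawn diploid at ploidy-1 SNPs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    patients = []
    sexes = []
    for i in range(n):
        sex = "M" if rng.random() < male_fraction else "F"
        geno = {}
        for snp in panel:
            p = snp.maf
            if snp.ploidy == 1 and sex == "M":
                state = "hemi_alt" if rng.random() < p else "hemi_ref"
            else:
                u = rng.random()
                if u < (1 - p) ** 2:
                    state = "hom_ref"
                elif u < (1 - p) ** 2 + 2 * p * (1 - p):
                    state = "het"
                else:
                    state = "hom_alt"
            geno[snp.snp_id] = GenotypeState(snp.snp_id, state)
        patients.append(geno)
        sexes.append(sex)
    return Cohort(patients=patients, sexes=sexes,
                  ids=[f"P{i + 1}" for i in range(n)])


def table_cohort(panel: Panel) -> Cohort:
    """The ten shipped reference patients, restricted to ``panel``'s SNPs."""
    df = builtin_cohort()
    patients = []
    for _, row in df.iterrows():
        geno = {}
        for snp in panel:
            geno[snp.snp_id] = GenotypeState.from_label(snp, row[snp.snp_id])
        patients.append(geno)
    return Cohort(patients=patients, sexes=list(df["sex"]),
                  ids=[str(p) for p in df["patient_id"]])


def simulate_multiplex_well(
    genotypes: Mapping[str, GenotypeState],
    panel: Panel,
    dictionary: Optional[PyroDictionary] = None,
    eff: Optional[EfficiencyModel] = None,
    noise: Optional[NoiseModel] = None,
    rng=None,
    well_id: Optional[str] = None,
) -> PyroSignal:
    """Simulate one multiplex well for a full per-SNP genotype assignment.

    With zero noise, unit efficiency and fuph_scale 1 this reproduces the
    theoretical combination signal exactly.
    """
    if dictionary is None:
        dictionary = build_dictionary(panel)
    eff = eff or EfficiencyModel()
    noise = noise or NoiseModel()
    rng = _rng(rng if rng is not None else 0)
    m = len(panel.order)
    clean = np.zeros(m)
    for snp in panel:
        g = genotypes[snp.snp_id]
        clean += eff.weight(snp.snp_id) * genotype_signal(dictionary, g).heights
    clean = noise.fuph_scale * clean + noise.background
    sd = noise.sd_base + noise.sd_prop * clean
    noisy = clean + rng.normal(0.0, 1.0, size=m) * sd
    return PyroSignal(heights=np.clip(noisy, 0.0, None),
                      order_id=str(panel.order.id or panel.order),
                      standardized=False, well_id=well_id)


def simulate_uniplex_well(
    genotype: GenotypeState,
    snp_id: str,
    panel: Panel,
    dictionary: Optional[PyroDictionary] = None,
    noise: Optional[NoiseModel] = None,
    rng=None,
    well_id: Optional[str] = None,
) -> PyroSignal:
    """Single-SNP special case: only ``snp_id`` contributes to the well."""
    if genotype.snp_id != snp_id:
        raise ValueError("genotype does not belong to snp_id")
    if dictionary is None:
        dictionary = build_dictionary(panel)
    noise = noise or NoiseModel()
    rng = _rng(rng if rng is not None else 0)
    clean = noise.fuph_scale * genotype_signal(dictionary, genotype).heights \
        + noise.background
    sd = noise.sd_base + noise.sd_prop * clean
    noisy = clean + rng.normal(0.0, 1.0, size=len(clean)) * sd
    return PyroSignal(heights=np.clip(noisy, 0.0, None),
                      order_id=str(panel.order.id or panel.order),
                      standardized=False, well_id=well_id)
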