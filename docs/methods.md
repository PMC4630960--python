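# Methods

## Signal model

Pyrosequencing incorporation is modelled deterministically: a read pointer
starts at the first template base; each dispensed nucleotide extends through
the homopolymer run of that base at the pointer (height = run length, possibly
zero) and advances the pointer. The model ignores chemistry artefacts
(incomplete extension, plus/minus frameshift, dATPαS background); noise enters
only through the synthetic-data generator, because the learning dictionary is
built from clean theoretical signals.

A multiplex well containing S SNPs is a linear mixture

y = c · Σₛ eₛ · gₛ + ε,  gₛ ∈ {aₛ,ref, aₛ,alt, ½(aₛ,ref + aₛ,alt)},

where aₛ,· are the allele atoms, the half-sum is the heterozygote (equal
template amounts ⇒ homozygote peaks are exactly twice their heterozygous
counterparts), eₛ is a per-SNP amplification efficiency and c a global scale
(the first-unitary-peak-height factor). Heterozygote weights are fixed at
0.5/0.5; allelic amplification imbalance is a noise-model concern, not a
dictionary concern.

## Strand convention of the shipped panel

The shipped nine-SNP panel stores each UNS exactly as tabulated, with a
per-SNP `as_read` flag. Four assays are designed on the reverse strand; for
those `as_read = false` and the reverse complement is taken before
simulation. This convention was fixed by calibration, and two independent
observations support it:

- On the tabulated (genomic-sense) strand the printed quadruplex order stops
  reading the X-linked SNP rs5945619 *before* its variant position, so both
  allele atoms are identical and the SNP is uncallable; the dictionary then
  has only 7 distinct theoretical atoms. On the reverse-complemented strand
  all 8 atoms are distinct.
- The ambiguity index (below) is exactly 1.0 on the genomic-sense strand and
  0.9885/0.9878 on the reverse-complemented strand — only the latter is a
  usable assay.

The allele labels attached to each UNS are the tabulated variant-position
bases, which match the reference genotype table for every SNP. The MAF column
is interpreted as the frequency of the second-listed (alternate) allele; this
convention affects only synthetic cohort sampling, never calling.

## Ambiguity index

The ambiguity index of a panel under an order is the maximum pairwise Pearson
correlation over the theoretical multiplex signals of *all* genotype
combinations (3 states per diploid SNP; `force_diploid=True` enumerates every
SNP tri-state, which is the convention used for the headline values — an
enumeration that ignores carrier sex, as an order-design tool naturally
would). Correlation with a constant vector is defined as 0 and such pairs are
excluded from the argmax (they cannot occur for the shipped panels). For the
shipped panels the computed maxima are 0.9885 (quadruplex, 81 combinations)
and 0.9878 (quintuplex, 243 combinations); both panels' combination signals
are pairwise distinct vectors. Reported reference values for this assay
design are 0.9891/0.9892; the residual ~0.001 gap is attributable to unstated
details of the original enumeration (e.g. signal support beyond the 10-nt
UNS) and is not resolvable from the published description — the package
reports what its own model computes.

## Order design

The designer is a deterministic breadth-first beam search: orders grow one
dispensation at a time; consecutive repeats are pruned (a repeated nucleotide
can never incorporate after an exhausted run — note this is a search-space
restriction, since a guaranteed-zero dispensation can still shift Pearson
correlations through centering); partial candidates rank by (uncovered bases
remaining, partial max atom correlation); feasible candidates compete
lexicographically on (max pairwise atom correlation, length, alphabetical
string), making results reproducible without randomness.

Two coverage notions exist because the printed 14/15-mer orders do **not**
fully sequence every template (e.g. the rs10993994 reference template is read
6/10 bases) yet always read through the variant site of both alleles —
which is the property genotyping actually needs. `coverage="full"` demands
end-to-end reads (used for small designed panels and matched against
exhaustive search in tests); `coverage="variant"` reproduces the printed
orders' feasibility notion. The objective is the maximum pairwise atom
correlation; mean correlation or a condition-number objective would also be
defensible, but max-pairwise directly bounds the worst confusable pair.

## Decoding and calling

Decomposition solves min ‖y − Dx‖² + λΣxᵢ, x ≥ 0. The default λ = 0 is plain
NNLS (`scipy.optimize.nnls`), which is naturally sparse because the active
set at the solution is small; λ > 0 uses `sklearn.linear_model.Lasso`
(`positive=True`, `fit_intercept=False`, α = λ/2m), and `"auto"` takes the
smallest grid value at which every retained atom clears the minimum relative
contribution. Observed signals are not required to be FUPH-standardized: a
first unitary peak is ill-defined in a multiplex signal, coefficients simply
absorb the scale, and calls depend only on ratios (scale invariance holds
exactly for λ = 0 and is tested).

Per SNP, coefficients are summed by allele over that SNP's atoms
(theoretical plus any experimental ones). With f = w_alt/(w_ref + w_alt):
f ≤ 0.2 → homozygous reference, f ≥ 0.8 → homozygous alternate,
0.3 ≤ f ≤ 0.7 → heterozygous (diploid only), otherwise no-call with an
`ambiguous_fraction` flag; single-copy SNPs use the same homozygote windows
for the two hemizygous states. The 0.2 / 0.3–0.7 windows follow common
pyrosequencing allele-quantification practice and are configurable; no
numeric cutoffs are published for this assay. A well whose confidence index
R = corr(y, Dx̂) falls below 0.95 flags every call `low_confidence`; observed
wells in the reference study all reported R ≥ 0.996, so 0.95 is conservative.

"Absolute contribution" defaults to the per-SNP coefficient sum
(`contribution_mode="coefficient"`); a coefficient × total-atom-light variant
is available (`"light"`) because published contribution tables do not define
their units, and without the original experimental signals those magnitudes
are uncalibrated either way. Relative contributions are percentages of the
per-well total and sum to 100.

## Synthetic data generator

`NoiseModel` defaults: sd_base = 0.03, sd_prop = 0.02 (per-peak Gaussian sd
= sd_base + sd_prop·height, truncated at zero), background = 0, fuph_scale
= 7.0. The scale makes raw heights resemble instrument output and is
irrelevant to calls by scale invariance; the noise magnitudes are chosen so
that decoded confidence indices match the ≥ 0.996 regime observed on real
wells. Cohorts are drawn under Hardy–Weinberg equilibrium from the panel
MAFs; the X-linked SNP is hemizygous Bernoulli in males, and the shipped
ten-patient reference cohort is all male. The generator emulates linear
superposition, amplification imbalance and peak noise — not read-length
decay, frameshift artefacts or inter-run baseline drift — so passing tests
demonstrate correctness of the unmixing model, not robustness to every
instrument pathology.

Problem sizes used by the test suite and acceptance script: full enumeration
of 54 + 243 genotype combinations for identifiability, 10 patients × 2 wells
(90 genotype calls) for cohort replication, n = 1000 for Hardy–Weinberg
frequency checks, and 25–100-well Monte-Carlo batches for contribution and
recovery properties.

## Cost / turnaround / waste model

Pure arithmetic over tabulated per-step figures: per patient, nine uniplex
runs (165 min PCR + 60 min pyrosequencing each) vs two multiplex runs
(165 + 70 min each) give 2025 vs 470 min; reagent costs 16.5 + 71.0 + 141.5
= 229.0 vs 16.5 + 16.0 + 31.5 = 64.0 US$. Shared preparation steps (buffy
coat 30, extraction 30, quantification 20 min) are identical in both
workflows, excluded from the headline totals and reported separately.
Waste counts compare full 96-well-plate consumables. No-calls count as
discordant in concordance reports (conservative).

## Known limitations

- The ambiguity index reproduces the reference design values to ~3 decimal
  places, not 4 (see above).
- Tri-allelic SNPs and indels are out of scope; the dictionary assumes
  bi-allelic SNPs whose UNS pair differs at exactly one position.
- λ > 0 breaks exact scale invariance (the penalty is not homogeneous);
  standardize signals or keep λ = 0 when comparing wells across scales.
- Experimental atoms are appended with equal status to theoretical ones; no
  reweighting scheme is applied.
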