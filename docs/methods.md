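# Methods

`phenodiv` implements the statistical core of a two-domain germplasm study:
colorimetric phenolic/antioxidant assays quantified per genotype on one side,
diploid SSR (microsatellite) marker diversity on the other, and a Mantel
permutation test asking whether the two induce congruent distance structures
over the same genotypes. This note records the models, the defaults and why
they were chosen, and what the synthetic-data generator does and does not
emulate.

## Assay quantification

All five assays share one skeleton: a raw spectrophotometer response is
converted to a concentration, scaled by the dilution factor applied at the
bench, propagated through the extraction geometry (sample mass `m` grams
extracted into volume `V` mL), and reported in the field's conventional
units.

* **TPC (Folin–Ciocalteau)** and **TFC (AlCl₃)**: a linear standard curve
  `A = s·c + b` is fitted by ordinary least squares to gallic-acid /
  rutin standards (µg/mL). Inverse prediction gives the measured
  concentration; `c · DF · V` is the mass of equivalents in the extract,
  reported as mg / 100 g fresh weight (FW). The curve's `r²` is carried so
  callers can reject bad fits; predictions outside the calibration range are
  flagged as extrapolations, not rejected.
* **TAC (pH-differential)**: the monomeric anthocyanin signal is
  `A = (A510 − A700)_{pH 1.0} − (A510 − A700)_{pH 4.5}`; cyanidin-3-glucoside
  equivalents follow from `mg/L = A · 449.2 · DF · 1000 / (26 900 · l)` with
  molar mass 449.2 g/mol, extinction coefficient 26 900 L mol⁻¹ cm⁻¹ and path
  length `l` fixed at 1 cm (standard cuvette; the protocol leaves it
  implicit). Slightly negative `A` — routine for yellow-fruited genotypes
  whose anthocyanins sit at the detection limit (published values run
  0.3–1.1 mg/100 g) — clamps to zero with a warning rather than erroring.
* **ABTS**: percent inhibition of the radical-cation blank,
  `(A_blank − A_sample)/A_blank · 100`, mapped to Trolox equivalents through a
  linear inhibition-vs-concentration curve. The 20–80 % inhibition window and
  the 0.70 ± 0.02 blank target are quality flags, not hard rejections: a
  flagged record is still quantified, and the caller decides.
* **FRAP**: absorbance at 593 nm against a Trolox curve (mM), reported as
  µmol TE/g FW.

Fresh-weight results convert to dry weight by dividing the per-gram value by
the tissue's dry-matter fraction; mg/100 g units are rebased to mg/g in the
same step, matching how dry-weight phenolic contents are conventionally
reported.

Dilution factors are per-record inputs with per-assay defaults
(TPC 2, TFC 1, TAC 10, FRAP 10, ABTS 10), chosen so that the published value
ranges of the berry screen land inside the default calibration ranges and,
for ABTS, inside the inhibition window. They are configuration, not
hard-wired chemistry.

## Genotype statistics

Per-genotype summaries are mean ± SE (`sd/√n`, ddof = 1) over replicates.
One-way fixed-effects ANOVA uses the standard between/within decomposition.
Multiple comparisons use **Duncan's multiple range test**: means are ranked,
and the range spanning `p` ranked means is tested against the critical range
`R_p = q(α_p, p, df_error) · √(MSE/n)` with Duncan's protection level
`α_p = 1 − (1−α)^{p−1}` (studentized-range quantiles from scipy; harmonic
mean of `n` with a warning when group sizes differ — the design this package
targets is balanced at n = 3). A range whose endpoints differ by less than
`R_p` is homogeneous together with everything inside it. The resulting
pairwise significance matrix is rendered as a compact-letter display by the
insert-and-absorb algorithm; ties in the mean ranking break by input order so
output is deterministic. The letter display satisfies, by construction and by
test, the defining property: significant pairs share no letter,
non-significant pairs share at least one.

Correlations between assays are Pearson `r` computed **across genotype
means**, not across the 75 individual replicates: a published germplasm table
presents means ± SE, and mean-level correlation is the standard reading of
such tables. Replicate-level correlation would mix within- and
between-genotype variance and is deliberately not what `pearson_matrix`
computes. Fold ranges (max/min) and grand means over genotypes complete the
summary layer.

## SSR diversity

Genotypes are diploid; a call is two allele fragment sizes in bp, pre-binned
by the caller (no binning window is applied). Missing calls drop out of that
locus's denominators only — genotypes are never list-wise deleted. Per locus:

* allele frequencies are plain counts over `2·n_typed` observed alleles;
* `Ho` is the fraction of typed genotypes whose two alleles differ;
* `He = 1 − Σ p_i²` (gene diversity). The default is the uncorrected
  plug-in estimator, matching the common software convention; the unbiased
  `2n/(2n−1)` variant is available behind `bias_corrected=True` and is what
  the parameter-recovery tests use, since the plug-in estimator's `O(1/n)`
  downward bias is a noticeable fraction of the sampling SE at high `He`;
* `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²`, always ≤ He.

Study-level summaries (total alleles, mean alleles/locus, mean He/Ho/PIC)
exclude monomorphic loci by default, mirroring the convention of reporting
marker statistics for polymorphic markers only.

## Distances, UPGMA, Mantel

**Biochemical distance** is Euclidean over genotype mean vectors, z-scored
per variable by default: total phenolics run in the hundreds of mg/100 g
while anthocyanins run in the tens, so unstandardized distance would be a
TPC ruler with noise. A flag disables standardization.

**Genetic distance** offers two codominant encodings. The default,
`allele_size_euclidean`, treats each locus as the sorted two-allele-size
vector (sorting makes heterozygote order irrelevant) and takes
`√(Σ_ℓ ‖x_ℓ − y_ℓ‖² / L_used)`, i.e. per-locus-normalized Euclidean distance
over the loci typed in both genotypes, so pairs with missing loci remain
comparable. A per-locus mean-size variant sits behind a flag. The
alternative, `shared_allele`, is `1 −` (mean proportion of shared alleles
per locus). A known property of the size metric, documented rather than
hidden: loci with wide allele-size spreads dominate it, because a 24 bp
indel-scale gap contributes 100× the squared distance of a 2 bp repeat-unit
step.

**UPGMA** is classical average-linkage agglomeration with ultrametric node
heights equal to half the merge distance, so cophenetic distances reproduce
an ultrametric input exactly (a fixed point, verified against scipy's
average-linkage cophenetic matrix). Ties in the minimum distance break
toward the clusters containing the smallest original leaf indices, making
the Newick output bit-reproducible. Cutting at `k` clusters undoes the
`k−1` highest merges.

**Mantel test**: `r` is the Pearson correlation of upper-triangle entries
after aligning the two matrices by genotype label; the p-value is one-sided
(upper tail), permuting rows and columns of the second matrix jointly, with
the `+1` correction `p = (1 + #{r* ≥ r})/(B + 1)`. Default `B = 9999`;
every permutation stream is seeded. With `B` permutations the test at
`α = 0.05` is exact-size under exchangeability, which the type-I acceptance
check confirms empirically.

## Synthetic data

The generator reproduces the design of the real study: 25 genotypes × 3
replicates, genotype-level truths taken from the packaged published means,
multiplicative replicate noise `Normal(µ, cv·µ)` truncated at zero with
`cv = 0.08` — the magnitude implied by the published SEs relative to their
means — and raw absorbance records obtained by inverting the quantification
chain through the default curves, so the assay module can be tested end to
end (the two directions are exact inverses at `cv = 0`).

SSR genotypes are drawn under Hardy–Weinberg equilibrium with free
recombination at a 7-locus panel mirroring the study's allele counts
(2, 3, 2, 2, 3, 7, 2); frequencies are skewed to roughly match the published
per-locus He profile (mostly 0.1–0.2, one diverse 7-allele locus at ~0.81).
Dry-matter fractions are drawn uniformly from the reported 10.8–18.4 % range.

The **association mechanism** is a deterministic dosage shift: each copy of a
designated allele at one biallelic locus adds a fixed increment to the TPC
and FRAP truths before assay noise. Presets express the increment in units
of the between-genotype SD of each trait: `moderate` = 1 SD/copy,
`strong` = 2 SD/copy. The designated locus is given a wide (24 bp) gap
between its two alleles so the default size metric — whose variance budget
follows size spreads — actually carries the signal; with the shared-allele
metric the six unlinked noise loci dilute a single-locus signal enough that
even an arbitrarily large dosage effect tops out near 84 % Mantel power at
n = 24, which is why the power guarantee is stated for the default metric.

What the generator does **not** emulate: genotype-by-environment variation,
correlated replicate errors within an extraction batch, allele-size binning
noise, null alleles, linkage between loci, and any pedigree structure among
genotypes. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Numerical and testing choices

* Calibration requires ≥ 3 points and non-degenerate concentrations; a flat
  response line fits with `r² = 0` rather than crashing, and inversion of a
  zero-slope curve is an error.
* Negative quantified values (possible when a reading sits below the curve
  intercept) clamp to zero and are flagged.
* Parameter-recovery tests compare estimates against **theoretical** SEs
  (binomial/delta-method for He, Ho, PIC; `cv·µ/√n` for assay means): with
  n = 3 replicates an estimated-SE interval is a 2-df t statistic whose
  ±3 SE coverage is only ~90 %, which would make a ≥ 95 % recovery criterion
  fail by construction rather than by defect.
* The recovery test panel uses allele frequencies chosen for well-behaved
  finite-sample coverage of 2-SE intervals (coverage oscillates on the
  binomial lattice); the bias-corrected He estimator is used there for the
  same reason.
* Measurement noise attenuates mean-level correlations by the reliability
  factor (~0.96 per assay at cv = 0.08, n = 3); the generator test checks the
  seed-averaged correlation against the noise-free fixture value.
* Simulation sizes in `scripts/acceptance.py` (500 null Mantel simulations,
  150 power runs, 199 permutations each) are the package's reporting
  defaults, chosen to give ~1 % Monte-Carlo error on the reported rates; the
  test suite runs the larger versions (1000 and 200).

## Known limitations

* Duncan's MRT is implemented for one-way balanced-ish designs only; no
  two-way or repeated-measures support.
* `He` assumes autosomal codominant diploid markers; no null-allele or
  Hardy–Weinberg tests are provided.
* The Mantel test is the plain (not partial) test, one-sided by design.
* Exact reproduction of a published dendrogram topology or Mantel `r`
  requires the underlying allele-size matrix; when only summary tables are
  published, those quantities are out of reach and the package's guarantees
  are the property-based ones above.
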