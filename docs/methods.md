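# Methods

This note documents the statistical models implemented in `irproteo`, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Hierarchical quantification model

Scan-level log2 ratios (one per MS/MS scan per condition, versus the
baseline channel) are modelled as

    x_s = mu_q + e_P + e_S,
    e_P ~ N(0, sigma_P^2),    e_S ~ N(0, sigma_S^2(I)),

where `mu_q` is the protein's true log2 fold change under that condition,
`e_P` a peptide-level deviation (digestion, labeling and ionization biases
that differ between peptides of one protein) and `e_S` scan-level
measurement error whose variance may depend on spectral intensity `I`.

**Scan variance curve.** Within-peptide replicate scatter identifies
`sigma_S^2(I)`: residuals about each (peptide, condition) mean are pooled
into equal-count intensity bins (default 5), each bin's unbiased pooled
variance is computed with degrees-of-freedom weights `(n_g − 1)/n_g` per
scan, and the bin values are made non-increasing in intensity by
pooled-adjacent-violators (scan noise physically shrinks with signal). A
single constant bin is used when `n_bins = 1` or fewer than 500 scans
contribute residual degrees of freedom — too few scans make the
quantile-binned curve unstable. If no peptide has two scans in any
condition the scan variance is unidentifiable and fitting raises an error.

**Aggregation.** Peptides: `x_p = Σ w_s x_s / Σ w_s`, `v_p = 1/Σ w_s` with
`w_s = 1/sigma_S^2(I_s)`. Proteins: `x_q = Σ W_p x_p / Σ W_p`,
`v_q = 1/Σ W_p` with `W_p = 1/(v_p + sigma_P^2)`. No minimum number of
peptides per protein is imposed; a single-peptide, single-scan protein is
retained with `v_q = sigma_S^2(I) + sigma_P^2`.

**Variance components by moment matching.** `sigma_P^2` is chosen (1-D
monotone root find; Brent's method, xtol 1e-10) so that the standardized
peptide residuals

    z_p = (x_p − x_q) / sqrt(1/W_p − 1/Σ W_p)

have unit mean square over peptides of multi-peptide proteins; the
`1/Σ W_p` term is the leverage correction for `x_p`'s own contribution to
`x_q`. `sigma_Q^2` is found analogously from the protein deviations about
the weighted grand mean. Both are clipped at zero; if no multi-peptide
protein exists, `sigma_P^2 = 0` with a warning. This moment-matching
calibration is this package's own construction; its contract is the null
one — for unchanged proteins

    Zq = (x_q − grand_mean) · sqrt(W_q),    W_q = 1/(v_q + sigma_Q^2)

is ~N(0, 1) — and the test suite verifies both the null calibration
(mean, SD, tail fraction) and recovery of generator-true components.

**Per-condition standardization.** Conditions (region × timepoint) are
standardized independently: `sigma_P^2`, `sigma_Q^2`, the grand mean and
Zq are all computed within a condition, because downstream significance
calls are per-condition and per-condition moment matching pins the null Zq
variance at exactly 1 there. The scan-variance curve, an instrument
property, is fitted once on all conditions pooled. The standalone
`estimate_variance_components` helper pools conditions instead (one scalar
pair for the whole table), which is the convenient form for parameter-
recovery studies. Technical replicates are analyzed separately and
reported side by side; no cross-replicate averaging is applied.

## Category coordination

`Zc = Σ_{members} Zq / sqrt(n)` over the n quantified, de-duplicated
members of a category (equal member weights; a variance-weighted variant
was considered and rejected to keep the null distribution exactly N(0,1)
regardless of coverage). Two-sided p-values come from the normal
distribution, and Benjamini–Hochberg runs within each condition by default
(a `global` scope is available). The minimum category size defaults to 5,
below which the normal approximation and the interpretation of
"coordination" both weaken. No trimming of extreme members is applied by
default; a trim option would bias Zc under genuine coordination.

**Cluster taxonomy.** Four-point Zc time profiles of categories significant
at ≥ 1 time point are classified by ordered rules (priority a > b > c > d >
e, first match wins); see `classify_profile` for the exact predicates. Two
numeric choices matter:

- *Return band* (default 2.5): a profile has "returned to baseline" when
  `|Zc|` at day 7 is below this band. Under correct standardization the Zc
  of a truly recovered category is N(0, 1) at that time point, so a band of
  1 would mislabel ~32% of genuinely recovered profiles; 2.5 covers ~98.8%
  of the sampling noise while still sitting well below the magnitudes
  (≥ 4–5) of the sustained clusters it must exclude.
- *Monotonicity slack* (same value): cluster d's non-increasing check
  allows each step to rise by up to the band, again to absorb unit-variance
  noise on each point.

The archetype-recovery acceptance test injects each of the five template
shapes at sqrt(n)·delta ≈ 7 (50 members, delta = 1.0 SD) — chosen from the
normal-theory power analysis so that every rule's conditions hold with
probability ≥ 0.98 per seed — and requires ≥ 95% correct labels over 100
seeds through the full pipeline.

## Label-free iBAQ

Theoretical peptide counts use fully tryptic digestion: cleave after K or
R except before P, zero missed cleavages, length window 7–30 residues (the
standard observable window); repeated peptides count per occurrence. iBAQ
is summed intensity over that count, and abundances are reported as
percentages of the identified proteome *within each animal*, so
between-group tests act on composition-normalized values and are invariant
to per-animal loading. Proteins with zero theoretical peptides are flagged
unquantifiable and excluded from the percentage denominator.

Group comparisons use the two-sided Mann-Whitney test: exact by full
enumeration of all C(nA+nB, nA) labelings of the pooled sample (valid
under ties) when nA+nB ≤ 12, else the tie-corrected normal approximation
with continuity correction; the U statistic reported is the standard
`#{a > b} (+ ties/2)` count. Note the granularity floor: with 5 vs 5
animals the smallest achievable exact two-sided p is 2/252 ≈ 0.0079, which
bounds what any multiplicity adjustment over hundreds of proteins can call
significant — the recovery test therefore checks that a true fold change
attains the floor and the top rank, not an unreachable adjusted threshold.

## PRM quantification

Only b/y-series fragment ions are accepted as quantifier transitions.
Peak areas use the trapezoid rule (common chromatography practice;
Simpson's rule buys nothing at typical sampling rates) over either an
explicit window or automatic boundaries: the contiguous region around the
smoothed-trace apex where the smoothed trace stays above 5% of its
maximum. Peptide values are the sum of their transition areas; protein
values default to the sum of monitored peptides (configurable to mean).
The loading normalizer is the total base-peak area — the integral of the
per-scan maximum intensity across all traces of the run — which cancels
global loading differences exactly and by simulation leaves equal-analyte
runs within a few percent despite 2× loading. Technical replicates
(1–2 per animal) are arithmetically averaged.

## CMR wall thickening

SWT = (ESWT − EDWT)/EDWT × 100 per segment; regional values average the
designated mid-apical segments (anteroseptal + anterior ischemic,
inferolateral + inferior remote); SWT ≤ 30% (boundary inclusive) marks a
dysfunctional segment. Group summaries pool across groups by
total-sum-of-squares combination,

    SS = Σ (n_i − 1) s_i^2 + Σ n_i (m_i − m̄)^2,    sd = sqrt(SS/(N − 1)),

which equals the SD of the concatenated raw animals exactly — verified
against a brute-force oracle built from the moment-matched generator.
Because published group cells are rounded to one decimal, pooled values
recomputed from them can differ from raw-data pooling by ±0.1 in
rounding-ambiguous cells. Longitudinal modelling (generalized linear mixed
models in the source workflow) is out of scope here: the package provides
the descriptive pooled statistics and the sequential Holm–Bonferroni
adjustment layer only.

## Synthetic-data generators

The generators reproduce the statistical structure the analysis assumes,
with defaults matching the emulated design: 2 regions × 4 time points
versus baseline, ~5,000 proteins (tests use smaller catalogs), 5 animals
per group, geometric peptide-per-protein (mean 3) and scan-per-peptide
(mean 2) counts truncated at 1 (the long-tailed coverage of shotgun data),
log-uniform spectral intensities over 1e5–1e8, and noise SDs
sigma_S = 0.2, sigma_P = 0.3, sigma_Q = 0.5 log2 units — nominal values of
realistic magnitude for isobaric data; the instrument's true
variance-intensity curve is not published, so the scan SD is homoscedastic
by default with an optional `a + b/sqrt(I)` low-intensity term to exercise
the variance-fitting stage. One condition maps to one channel (pooled
5-animal samples, no replicate channels).

Category effects are specified in units of each member protein's *total
null standard deviation* `sqrt(sigma_Q^2 + v_q_theory)`, which the
generator computes exactly from its own noise parameters and the protein's
simulated coverage; an effect of delta therefore yields E[Zq] = delta and
E[Zc] = sqrt(n)·delta by construction, which is what the power-law and
detection tests measure. Effect time courses follow the five archetype
templates mapping 1:1 onto clusters a–e. Category memberships are disjoint
draws from a seed-determined shuffle.

Label-free intensities are log-normal around protein abundance × a fixed
per-peptide response factor × the group fold change (log2 SD 0.3 per
animal). Chromatograms are Gaussian peaks plus white noise (clipped at
zero) on a uniform grid. CMR records are affinely moment-matched so each
group's sample mean and SD equal their targets to machine precision, with
EDWT fixed at 10 mm.

Not emulated: mass spectra, retention-time drift, missing values and
missing-channel mechanisms, isotopic impurity, shared (razor) peptides,
batch effects, and any correlation between peptide response and sequence.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the assumed error model, not robustness
to those real-data pathologies.

## Numerical choices and degenerate inputs

Root finds use Brent's method on monotone moment functions with bracket
expansion from [0, 1]; components clip at zero when the data are less
dispersed than their within-level noise explains. Scan variances are
floored at 1e-12 when inverted so that noise-free synthetic data aggregate
exactly instead of dividing by zero. Zero-scan peptides, zero-peptide
proteins, empty integration windows, non-positive normalizers, EDWT ≤ 0
and out-of-range p-values all raise explicit errors. Group-by reductions
use index-ordered summation, so row order affects results only at the
1e-15 level (the permutation-invariance test allows 1e-12).

## Monte-Carlo problem sizes

The null-FDR experiment uses the specified 500 datasets of 2,000 proteins
and 200 disjoint size-10 categories (~2 minutes on one CPU). Under
independent complete-null p-values Benjamini–Hochberg attains E[FDP] = α
exactly, so the estimate sits near 0.05 by design, pulled slightly below
it by the finite-population correlation of standardized Zq (members of a
size-10 category share the sample standardization, giving
Var(Zc) ≈ 1 − 9/1999); its Monte-Carlo standard error at 4,000
dataset-condition units is ≈ 0.003. Other Monte-Carlo tests use 100 seeds
with 300–2,000-protein catalogs, sized so each test's sampling error is
several times smaller than the band it asserts.
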