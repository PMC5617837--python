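# irproteo

Quantitative proteomics and cardiac-MRI statistics for longitudinal
ischemia/reperfusion (I/R) myocardium studies.

After an acute myocardial infarction treated by reperfusion, both the
ischemic and the remote (non-infarcted) myocardium remodel rapidly during
the first week. Studies of this process quantify thousands of proteins by
multiplexed isobaric labeling across regions and time points, validate the
main changes with label-free (iBAQ) and targeted (PRM) mass spectrometry,
and track regional contractility by systolic wall thickening on cine CMR.
`irproteo` implements that analysis stack as a tested Python library for
proteomics analysts and methodologists: the statistical core, the
surrounding file plumbing, and seeded synthetic-data generators that
emulate the full study design so every stage can be exercised and
calibrated without raw instrument data.

## The statistics at the core

**Hierarchical weighted quantification (Zq).** Scan-level log2 ratios
decompose into three error levels,

    x_s = mu_q + e_P + e_S,   e_P ~ N(0, sigma_P^2),   e_S ~ N(0, sigma_S^2(I)),

with scan variance allowed to grow at low spectral intensity. Estimates are
inverse-variance weighted at each level (`x_p = Σ w_s x_s / Σ w_s` with
`w_s = 1/sigma_S^2(I_s)`; `x_q = Σ W_p x_p / Σ W_p` with
`W_p = 1/(v_p + sigma_P^2)`), the components `sigma_P^2`, `sigma_Q^2` are
calibrated by moment matching so standardized residuals have unit variance,
and each protein's change is reported as

    Zq = (x_q − grand_mean) · sqrt(W_q),   W_q = 1/(v_q + sigma_Q^2),

which is ~N(0, 1) for unchanged proteins. No minimum peptide count is
imposed; single-peptide proteins are retained with wide variances.

**Category coordination (Zc).** Coordinated moderate changes across a
functional category of n quantified proteins are detected by the
standardized category average `Zc = Σ Zq / sqrt(n)` (~N(0, 1) under the
null, ≈ sqrt(n)·delta under a shared shift delta), with two-sided normal
p-values controlled by Benjamini–Hochberg within each region × timepoint.
Significant categories' four-point time profiles are classified into five
clusters: sustained early up (a), early down recovering (b), late up
peaking at day 7 (c), progressive down (d), transient early excursion (e).

**Validation stages.** iBAQ = summed peptide intensity / number of
theoretical tryptic peptides (7–30 residues, no missed cleavages),
expressed as a percentage of each animal's identified proteome; group
differences use the exact-enumeration Mann-Whitney test with BH control.
PRM quantification integrates b/y-fragment XIC peak areas (trapezoid rule)
normalized by the run's total base-peak area. Wall thickening uses
SWT = (ESWT − EDWT)/EDWT × 100, segments with SWT ≤ 30% are dysfunctional,
group (mean, SD, n) summaries pool by total-sum-of-squares combination, and
pairwise p-values adjust by sequential Holm–Bonferroni.

## Worked example

```python
from irproteo import SimulationConfig, CategoryEffect, WsppModel, SbtModel
from irproteo.simulate import generate_scan_table, category_annotations

config = SimulationConfig(
    n_proteins=1000,
    categories=(
        CategoryEffect("acute_phase", 40, "early_sustained_up", 0.8),
        CategoryEffect("thick_filament", 40, "transient_early", -0.8),
    ),
    n_null_categories=50,
    seed=42,
)
scans = generate_scan_table(config)          # 47,744 scan rows, 2 regions x 4 timepoints
results = WsppModel(scans, n_bins=5).fit()
print(results.summary())
```

```
Weighted scan-peptide-protein quantification
============================================================
scans:    47744    proteins: 1000
conditions: 8    intensity bins: 5
scan variance (log2^2): [0.0406 0.0406 0.0406 0.0406 0.0399]
------------------------------------------------------------
region      timepoint      sigma_P   sigma_Q     Zq SD
ischemic    R-120min        0.2935    0.5407    1.0000
ischemic    R-24h           0.2934    0.5343    1.0000
...
```

The fitted components recover the generator's truth (sigma_S = 0.2, so
variance 0.04; sigma_P = 0.3; sigma_Q = 0.5) and Zq is standardized to unit
SD per condition. The category stage then flags the two injected
coordinated changes and classifies their time courses:

```python
sbt = SbtModel(results, category_annotations(config)).fit(alpha=0.05)
print(sbt.summary())
```

```
Category coordination analysis (standardized category averages)
================================================================
categories scored: 52    cells: 416    significant (FDR < 0.05): 12
cluster counts: a: 1, b: 2, c: 0, d: 0, e: 0, unclassified: 101
----------------------------------------------------------------
category            region    timepoint       n       Zc       fdr
acute_phase         ischemic  R-120min       40     6.31  1.43e-08
thick_filament      remote    R-24h          40    -5.63  9.43e-07
...
```

`acute_phase` (40 members shifted +0.8 SD at every time point) scores
Zc ≈ sqrt(40)·0.8 ≈ 5 throughout and is classified cluster "a";
`thick_filament` (a negative transient) is strongly negative at 120 min /
24 h and back at baseline by day 7. The 50 null categories stay near
Zc ≈ 0.

Pooled wall-thickening statistics recompute from bundled per-group
summaries:

```python
from irproteo.cmr import pool_group_summaries
from irproteo.datasets import wall_thickening_group_summaries

pooled = pool_group_summaries(wall_thickening_group_summaries("ischemic", "baseline"))
print(f"{pooled.mean:.1f}% (SD {pooled.sd:.1f}, n={pooled.n})")
# 57.5% (SD 22.1, n=25)
```

A thin CLI mirrors the library
(`irproteo simulate|quantify|categories|labelfree|prm|cmr|report`).

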