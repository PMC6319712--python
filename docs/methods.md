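# Methods

This note documents the statistical model behind `evmir`, the design of
the synthetic-data generator, the numerical choices, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count model

Counts for miRNA *f* in library *l* are modelled as negative binomial
(NB) with mean μ_{fl} proportional to the library's effective size and
variance μ + φμ². φ is the dispersion: φ = 0 recovers Poisson; real
biological replicates of small-RNA libraries typically show φ in the
0.05–0.4 range, and the generator defaults to φ = 0.1.

### TPM quantification

Expression is reported as transcripts per million **miRNA-mapped**
reads: each library column is scaled to sum to 10⁶. No length
normalization is applied — mature miRNAs are effectively uniform length,
so this TPM is a reads-per-million quantity on the miRNA-assigned total,
not the transcript-length TPM of mRNA-seq. Column sums equal 10⁶ exactly
before any filtering, and TPM is invariant to rescaling a library's
counts.

### Detection rule

A feature is detected in a compartment when TPM **strictly exceeds** the
threshold (default 5) in **at least one replicate**. The per-replicate
rule is the default because it is the only fully operational reading of
a one-replicate-suffices footnote convention common in this literature;
a mean-based variant (`rule="mean"`) is provided. The strict inequality
matters only at the exact boundary and is tested there.

### TMM normalization

Library composition bias is corrected by the trimmed mean of M-values.
For library *k* against reference *r* (chosen, unless named, as the
library whose upper-quartile count fraction is closest to the mean of
those fractions, after dropping all-zero features):

* M = log2((y_k/N_k)/(y_r/N_r)), A = ½·log2((y_k/N_k)(y_r/N_r)),
  computed over features nonzero in both libraries;
* the most extreme 30% of M on each side and 5% of A on each side are
  trimmed (rank-based, double trimming);
* the factor is 2 to the precision-weighted mean of the kept M values,
  with delta-method weights 1/v, v = (N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r);
* factors are recentred to geometric mean 1 and multiply raw library
  sizes to give effective sizes.

The implementation is validated against an independently coded
transcription of the formula and, as a second route, against the
reference Bioconductor implementation via `Rscript` (agreement to 1e-6
on the fixtures used).

### Dispersion estimation (qCML)

Libraries of a contrast are equalized to a common size — the geometric
mean of the effective sizes — by **proportional mean scaling** of the
counts (pseudo-counts). Within a replicate group, the likelihood of the
counts conditional on their sum depends only on φ: with r = 1/φ, n
replicates and group sum z,

ℓ(φ) = Σ_i lnΓ(y_i + r) + lnΓ(n r) − lnΓ(z + n r) − n lnΓ(r).

The common dispersion maximizes the total over features and groups
(bounded scalar search on log10 φ ∈ [−8, 2]; an optimum at the lower
bound is reported as φ = 0). Optional tagwise estimation maximizes each
feature's own conditional likelihood plus a shrinkage term weighting the
across-feature mean likelihood by prior_df / residual df (prior_df = 10);
common-dispersion mode is the default because duplicate libraries give
tagwise estimates little to work with. Parameter recovery is tested:
Poisson data yield φ̂ ≤ 0.05, and planted φ = 0.2 is recovered within
25%.

### Exact test

For each feature, the two group sums (of pseudo-counts, rounded to
integers) are treated as NB with mean n_g·μ and dispersion φ/n_g. The
total z is split proportionally to group sizes to give the
conditional-null means, and the two-sided p-value is the total
conditional probability of all splits (k, z−k), k = 0..z, whose
probability does not exceed that of the observed split; ties within a
relative 1e-12 are included in the rejection set. The enumeration is
exact at any z (vectorized and chunked); φ = 0 uses the Poisson limit,
where the conditional distribution is binomial.

Design notes:

* **Proportional rescaling, not quantile adjustment.** The classical
  qCML pipeline equalizes library sizes by a quantile-adjustment
  procedure whose interpolation details are tool-internal. `evmir` uses
  plain proportional mean scaling, validated against an exhaustive
  enumeration oracle (agreement ≤ 1e-10 on all instances with group sum
  ≤ 30, and ~1e-15 in practice) rather than by bit-matching any external
  tool. With exactly equal library sizes the two approaches coincide;
  on such fixtures the p-values also match the reference implementation
  to ~1e-4 (the residual difference is that tool's internal handling of
  non-integer intermediate quantities).
* **Rounding of group sums.** Enumeration needs integer totals; rescaled
  group sums are rounded to the nearest integer. At realistic depths
  the relative effect is ≪ 1/z.
* **log2FC prior.** Fold changes use prior-count-augmented group means
  at the equalized size, log2((z_B/n_B + 0.5)/(z_A/n_A + 0.5)), so a
  feature absent from one group gets a large finite value instead of
  ±∞. Published per-feature fold changes from equivalent analyses are
  not exactly recomputable from printed means because the original
  prior and normalization internals are unstated; such printed values
  are therefore not comparison targets. Group swap negates log2FC and
  leaves p unchanged (tested).
* **Calibration.** Under a simulated null (2000 features, duplicate
  libraries) the empirical rejection rate at α = 0.05 stays within
  0.05 ± 0.015 for φ ∈ {0, 0.1, 0.4}, slightly conservative (~0.04),
  as expected for a discrete exact test.

FDR is Benjamini–Hochberg step-up, delegated to statsmodels behind
`adjust_fdr`. Calls: up iff log2FC > 1 ∧ p < 0.05 ∧ FDR < 0.05; down
symmetric; both fold-change and significance cuts are configurable
(a linear FC > 1.5 screen is `log2fc_cut = log2(1.5)`).

## Distribution logic

Venn partitions are computed as exclusive cells (2^k − 1 per k named
sets) that are pairwise disjoint and cover the union, so every
inclusion–exclusion identity holds exactly by construction. A feature is
EV-enriched when the EV-vs-CL contrast calls it up; labels are
sMV-only / Exo-only / both. The cell-silent screen intersects "fails the
CL detection rule" with "EV-enriched" — *not detected* means the
detection rule, not a low mean. Passenger (star) strands are distinct
features throughout.

## Correlation classifier

A signature is a vector of compartment-mean TPM over a feature
selection (all detected / dysregulated / EV-enriched). Each panel sample
is scored by the Pearson product-moment coefficient over the
intersection of signature and panel features; features missing from a
sample are dropped, never zero-filled (zero-filling manufactures
correlation from shared absences). An optional log2(TPM+1) transform is
available; raw TPM is the default.

The decision rule is a documented choice, since a correlation threshold
must come from somewhere: by default τ = max r over the normal
calibration samples, so specificity **on the calibration normals is
100% by construction**. The honest specificity estimate comes from
held-out normals, and here order statistics impose a hard limit: a new
normal drawn from the same distribution exceeds the maximum of n
calibration normals with probability exactly 1/(n+1), independent of
the distribution. Expected held-out specificity is therefore
n/(n+1) — ~0.857 with 6 calibration normals, ~0.96 with 24. The
Monte-Carlo recovery experiment consequently calibrates on 24 normals
and evaluates on 25 held-out null samples per panel; with signature
weight 0.6 and noise sd 0.3 it attains mean sensitivity ≈ 1.0 and mean
held-out specificity ≈ 0.95 over 20 seeded panels. Alternative rules:
fixed τ, and mean + k·sd of the calibration normals. Percentages are
rounded half-up to one decimal.

## Motif scan

Motifs are literal RNA 4-mers; matching is exact, case-insensitive
substring search with T auto-mapped to U (warned once). Counting is at
the sequence level — a precursor counts once however many occurrences
it has — with all overlapping occurrence positions reported 0-based.
No background model or enrichment statistic is computed: the output is
the raw bearing fraction.

## Synthetic-data generator

What it emulates, and the defaults:

| parameter | default | rationale |
|---|---|---|
| n_mirnas | 500 | order of detected miRNAs in deep small-RNA libraries |
| n_replicates | 2 | duplicate-library designs typical of this assay |
| compartments | 2 lines × {CL, sMV, Exo} | the cross-compartment design |
| library_size_mean | 12.77 × 10⁶ | average clean-read depth of the emulated assay |
| library size spread | uniform ±20% | realistic depth variation; exercises TMM |
| baseline means | log-normal, log10 mean 2 sd 1 | heavy-tailed miRNA abundance spanning ~0.1 to >10⁵ TPM |
| dispersion φ | 0.1 | typical biological-replicate overdispersion |
| frac_dysregulated | 0.2 | planted \|log2FC\| > 1 between the two cell lysates |
| frac_ev_enriched | 0.12 | split evenly sMV-only / Exo-only / both |
| frac_cell_silent_ev | 0.05 | CL pinned at 1 TPM, EV at 2000–5000 TPM |
| frac_passenger | 0.296 | passenger-strand share of detected features |

Planted classes are disjoint by construction and recorded exactly
(rounded counts match the configured fractions). Dysregulation folds
apply to every compartment of the second cell line — a cell-level
abundance change propagates into that cell's EVs — while EV-enrichment
folds multiply the EV compartments of both lines. Cell-silent features
are pinned after TPM-normalizing the mean matrix, guaranteeing the
"<5 TPM in CL, >1000 TPM in EV" pattern up to sampling noise: at the
default depth a 1-TPM feature cannot cross the 5-TPM rule by noise
(a ≫5σ event), whereas at strongly reduced depth a single stray read
can, which is why pipeline-scale runs in the tests use ≥10⁶ reads per
library. NB sampling uses the exact gamma–Poisson mixture; a single
seed feeds independent sub-streams (class assignment, baselines,
library sizes, counts) so changing one consumer does not shift the
others.

Tumour/normal panels: normals are the baseline profile with
multiplicative log-normal noise (sd 0.3 by default); stage-s tumours
are (1−w)·baseline + w·signature plus the same noise, w = 0.6 by
default (optionally per stage). Panel sizes default to 11 normals and
26/56/45/22 staged tumours — the shape of a public tumour-registry
panel at reduced scale. Precursor sets contain exactly
round(n·fraction) motif-bearing sequences (one guaranteed insertion;
background may add occurrences) and motif-free remainders verified by
rejection sampling.

What the generator does **not** model: isomiRs, read-level artefacts
(adapters, mapping multiplicity), correlated features, batch effects,
stage-dependent signature drift unless configured, and microarray-style
intensity data. Passing recovery tests therefore demonstrates the
statistical machinery under the stated model, not robustness to those
real-data complications.

## Pipeline and problem sizes

The orchestrated run executes nine stages (quantify, detect,
de_cell_lines, ev_enrichment, distribution, cell_silent, signature,
classify, motif), writes every stage's output as TSV/JSON with sorted
keys and no timestamps, and is byte-identical under a fixed seed
(tested). If the configured signature selection yields fewer than 3
features (possible on null data; Pearson needs 3), the run falls back
to the detected set with a warning rather than aborting.

Problem sizes used by the test suite and `scripts/acceptance.py` are
chosen to keep a full run on one CPU in the tens of seconds: 200–400
features at 0.3–2 × 10⁶ reads per library for DE and end-to-end
checks, the full default depth (12.77 × 10⁶) for the cell-silent
recovery run where the detection rule's noise floor matters, 2000
features × 3 seeds for type-I calibration, and 20 panels for the
classifier Monte-Carlo. The exact-test enumeration cost scales with
total counts, so depth is the main runtime dial; results at these sizes
exercise the same code paths as full-depth runs.

## Known limitations

* The exact test's proportional-rescaling equalization is a documented
  variant; with unequal library sizes its p-values can differ in the
  third decimal from quantile-adjusted implementations.
* Common dispersion with duplicate libraries pools all features; a
  strong mean–dispersion trend would be missed (tagwise mode mitigates
  but is off by default at n = 2).
* The decision rule for tumour prediction is a calibration choice, and
  its held-out specificity is bounded by n_cal/(n_cal+1) as derived
  above; reporting specificity on calibration normals alone would
  overstate performance.
* Venn reports are set algebra only; no graphical rendering.
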