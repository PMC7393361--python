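# Methods

`irscreen` implements a chemometric screening analysis for ATR-FTIR spectra
of blood plasma: spectra are preprocessed, split into representative
training/validation/test sets, reduced to a small number of informative
variables or components, classified, and summarized with diagnostic figures
of merit. Because cohort spectra of this kind are generally not public, the
package ships a synthetic-spectrum generator with known ground truth, and
the test suite validates every stage against it.

## Data model

Spectra live in a `SpectralDataset`: an `n_rows x n_wavenumbers` absorbance
matrix with a strictly ascending wavenumber axis (cm^-1), per-row sample
ids, optional replicate ids (triplicate acquisition is the norm) and binary
labels (`BC` positive / `HC` negative). Replicates are averaged into one
row per sample *before* any preprocessing. All peak/window lookups use the
nearest grid point; nothing assumes a particular grid spacing. The
acquisition-range default is 600-4000 cm^-1 at 2 cm^-1 spacing, which puts
451 points in the closed 900-1800 cm^-1 fingerprint window.

## Preprocessing chain

Fixed order: truncate → Savitzky-Golay → AWLS baseline → Amide I
normalization.

* **Truncation** to the biofingerprint region, closed interval, default
  900-1800 cm^-1.
* **Savitzky-Golay** smoothing, default window 7 points, 2nd-order
  polynomial (both configurable; window 15 is a common alternative for the
  same instrument class and is exposed via `PreprocessConfig`). Edges are
  handled by one-sided polynomial fits, so polynomial rows up to the filter
  order are reproduced exactly everywhere.
* **AWLS baseline correction**: asymmetric iteratively-reweighted polynomial
  fitting. Points above the current baseline estimate (peaks) get weight
  0.01, points at/below keep weight 1; default order 2, tolerance 1e-6 on
  the max baseline change, at most 50 iterations. Non-convergence uses the
  last iterate and logs a warning rather than raising — a slightly
  under-converged baseline is still a usable baseline.
* **Amide I normalization** divides each row by its maximum within
  1650 ± 10 cm^-1. The window maximum, not the literal 1650 grid point, is
  used because "the Amide I peak" denotes a band whose apex shifts by a few
  cm^-1 between samples; after this step every row's window maximum is
  exactly 1.

## Kennard-Stone 70/15/15 split

Kennard-Stone ranks samples by greedy max-min Euclidean distance on the
preprocessed spectra of the full cohort (ties to the lowest index). The
first 70% of ranks (most representative, spanning the data cloud) form the
training set, the next 15% validation, the remainder test. Validation and
test sizes are rounded to the nearest integer and the remainder goes to
training, so a 476-sample cohort yields 334/71/71. Split sizes depend only
on N, never on the spectra. KS is applied globally rather than per class:
this reproduces the 334/71/71 arithmetic independently of class balance.

## Feature reduction and the cost function G

All three reducers are tuned on the validation set through the same cost

    G = (1/N_V) Σ_n g_n,
    g_n = r²(x_n, m_own) / min_wrong r²(x_n, m_wrong),

where r² is the squared Mahalanobis distance using the **pooled training
covariance** restricted to the candidate variables (the pooled choice keeps
one covariance inversion per evaluation and matches the linear-discriminant
context the cost comes from). A validation point exactly at a wrong-class
mean gets g_n = +inf and is flagged. Fitness for the selection algorithms
is 1/G. Covariances anywhere in the package are ridged with
λ = 1e-6·trace/dim whenever their smallest eigenvalue drops below 1e-10.

* **PCA**: mean-centred SVD basis, components ordered by explained
  variance, sign fixed so each loading's largest-magnitude element is
  positive. The component count is chosen by minimizing validation G over
  1..20 (ties → fewer components).
* **SPA** (successive projections algorithm): from every possible starting
  variable a chain is grown by repeatedly appending the variable whose
  column has the largest norm after orthogonal projection out of the span
  of the chosen columns; every chain prefix (length 1..max_vars, default
  max 30) is scored with G and the best prefix wins (ties → shorter chain,
  then lower start). Selected variables are original wavenumbers — SPA
  never transforms the data space. Collinear exhaustion truncates a chain
  with a log message.
* **GA**: binary chromosomes over wavenumbers, 100 generations × 200
  chromosomes, fitness-proportional (roulette) selection, single-point
  crossover with probability 0.60, per-bit mutation 0.10/length, elitism of
  one, empty chromosomes repaired by switching on one random bit; three
  independent realizations, best final chromosome kept. Initial chromosomes
  activate ~30 random wavenumbers each (matching the SPA budget and keeping
  fitted covariances well-conditioned against the training size).
  Deterministic given its seed.

## Classifiers

LDA and QDA use the non-Bayesian squared-Mahalanobis score
`(x − m_k)ᵀ C⁻¹ (x − m_k)` with the pooled covariance (LDA) or the
per-class covariance (QDA); the predicted class minimizes the score, with
no log-determinant or prior terms. Exact ties go to the positive class and
are flagged — in a screening setting a borderline case should not be called
healthy. The ROC score is score(HC) − score(BC).

The SVM is the soft-margin dual with RBF kernel `exp(−γ‖x−z‖²)`, γ = 1.
The box constraint C is picked from {0.01, 0.1, 1, 10, 100, 1000} by
validation accuracy (ties → smaller C). The dual is solved by libsvm via
scikit-learn (tolerance 1e-6); the decision function
`Σ αᵢ yᵢ k(xᵢ, z) + b` is evaluated from the stored support vectors, and
tests cross-check it against an independent quadratic-programming solution
of the same dual.

## Figures of merit and ROC

From the confusion matrix (positive = disease): accuracy, sensitivity,
specificity, Youden's index SENS − (100 − SPEC), PPV, NPV,
F-score = 2·SENS·SPEC/(SENS+SPEC) and G-score = √(SENS·SPEC), all in
percent. **Note** the F-score here is the harmonic mean of sensitivity and
*specificity* — a convention of the screening literature, not the
precision/recall F1. PPV/NPV with a zero denominator are reported as
not-available rather than 0. Metrics are kept at full precision internally
and rounded half-away-from-zero to one decimal for display. AUC is the
Mann-Whitney statistic (ties ½), computed with scikit-learn's ROC tools.

## Synthetic cohort generator

Each sample's noiseless template is a sum of Gaussian bands at 16
biologically assigned fingerprint positions (901-1742 cm^-1), with the
Amide I band (1643 cm^-1 region) dominant by construction so normalization
is well-posed, plus a smooth quadratic baseline with a per-sample random
scale in [0.5, 1.5]. Per sample and band, amplitudes vary multiplicatively
(sd 7-10%, default 0.10) — the between-sample biological variability that
makes the two classes overlap the way measured cohort spectra do. Positive
samples additionally get an additive amplitude shift (default 0.05) on a
planted marker subset (default: the four well-separated bands at 999, 1277,
1402 and 1582 cm^-1, widths 6 cm^-1 sd). Each of the three replicates adds
iid Gaussian noise (sd 0.01). Defaults emulate the screening-cohort
conditions: 476 samples, balanced classes, 600-4000 cm^-1 at 2 cm^-1.

With the class effect set to 0 the classes are exchangeable by
construction; tests verify chance-level accuracy and AUC in that limit.

**What the generator does not emulate**: ATR penetration-depth physics,
water-vapour lines, scattering artefacts, Mie distortions, peak-position
variability, and correlated biochemical panels. Two consequences matter for
interpreting the tests. First, passing recovery tests show the selection
logic works when class information sits in band amplitudes at known
positions — not that the method would find real disease markers. Second,
because biological variability is amplitude-proportional while measurement
noise is tiny, a marker band's flank columns carry almost the same
effect-to-noise ratio as its apex; the GA fitness therefore has no gradient
toward the apex and GA runs typically select wavenumbers 2-6 cm^-1 off the
planted centres. SPA does land on apexes, because its projection chain
picks each band's maximum-variance column before G ever votes. A generator
with band-position jitter (variance concentrated off-apex) would sharpen
the GA's gradient; this is a known limitation of the present design.

## Pipeline and reproducibility

`run_all` trains all nine reduction × classifier combinations on the
training set, tunes on validation, and evaluates once on the held-out test
set; test rows never reach a fitting or tuning routine, and the provenance
log records the index sets for audit. A failing combination is logged and
skipped without aborting the rest. One global seed fans out to per-stage
seeds through a fixed `SeedSequence` derivation so any stochastic stage can
be rerun in isolation; identical config + seed reproduces byte-identical
reports.

Problem sizes in the test suite are deliberately modest so the whole suite
runs in minutes: most unit tests use cohorts of 60-100 samples on the
fingerprint grid, while the repeated recovery experiments use the full
476-sample design with 20 seeded replicates and a reduced GA schedule
(30 generations × 60 chromosomes × 1 realization) — the GA's apex-offset
behaviour is unchanged at the full 100 × 200 × 3 schedule, which the
package keeps as its default.

## Known limitations

* AWLS weights (1 / 0.01) and polynomial order are fixed defaults; strongly
  curved baselines may need a higher order.
* The per-sample weighted-SSE descent of AWLS is an empirical property of
  the asymmetric reweighting, verified on test inputs, not a theorem.
* The GA uses fitness-proportional selection, which is weak when fitness
  values are nearly equal; with highly redundant neighbouring wavenumbers
  the selected set is one of many near-equivalent optima.
* Binary classification only; no probability calibration; no confidence
  intervals on AUC.
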