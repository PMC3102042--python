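# Methods

This note documents the models and procedures implemented in `gcmsannot`,
the parameter defaults and why they were chosen, the numerical conventions
tests rely on, and what the synthetic-data generators do and do not emulate.

## Spectral representation and similarity

An EI spectrum is a vector of non-negative intensities over integer m/z
85–500: 416 variables (`MassSpectrum`). Normalization rescales so the base
peak is exactly 100; an all-zero spectrum is a hard error. Out-of-range
masses in input files are dropped with a logged warning rather than
silently rebinned.

Similarity is the Pearson correlation (degree of coincidence, DOC) of
*weighted* vectors `I(m)^a · m^b`. Hard EI ionization concentrates ion
current in low-mass fragments while the diagnostic, structure-specific
fragments sit at high mass, so high masses must count for more. The default
exponents a = 0.5, b = 2 follow the dominant convention in EI library
search (square-root intensity damping, quadratic mass emphasis); both are
exposed in `SpectrumWeighting` because the best trade-off is
instrument-dependent. With a = 1 the weighting is linear in intensity, so
DOC is invariant to prior normalization; for any exponents it is invariant
to multiplying raw intensities by a constant (the constant factors out of
the power law) — both properties are pinned by tests. A zero-variance
weighted vector has no defined correlation; such candidates are treated as
non-matches and logged.

## Retention-time correction

Anchors are pseudo-internal standards: at most eight user-chosen stable
endogenous peaks, each contributing (rt_old, rt_new). The map is piecewise
linear through the sorted anchor pairs, extended affinely beyond the first
and last segment, and a pure offset for a single anchor. This is the
simplest total, strictly monotone rule consistent with recommending early
*and* late anchors; anchor exactness, monotonicity, and round-trip
inversion are property-tested. Nonlinear warping (spline/LOESS) is out of
scope: two anchors already recover any affine drift exactly, and
chromatographic drift from column aging is well approximated as affine over
a run. The library is corrected once per batch. Units are seconds
throughout.

In the pipeline, each anchor is located as the highest-DOC peak within a
search window around its library RT (`anchor_window`, default 5 × c). The
default can be too narrow when absolute drift at the chromatogram tail
exceeds 5c, so the window is a config field; an unmatched anchor is a hard
error naming the compound.

## Identification

Candidates are the library entries within the closed window [rt − c,
rt + c]; c is deliberately user-set (column- and method-dependent). The
highest weighted-DOC candidate wins with no score floor by default
(`min_doc` = 0.0), since the RT window already constrains candidates; users
can raise `min_doc` to suppress weak matches. Ties break on smaller |ΔRT|,
then library file order, making results deterministic. One library
compound may match several peaks — sugar anomers and variable silylation
legitimately produce multiple chromatographic peaks per compound — so
one-to-one matching is not enforced; duplicates are logged.

## SIMCA class models

Each class is modeled separately by mean-centered PCA (SVD) on its m × 416
matrix of normalized training spectra. No autoscaling: all variables share
intensity units, and autoscaling would inflate noise-only bins.

* Training residual SD: `s0 = sqrt(ΣΣ e_ki² / ((m − r − 1)(p − r)))`.
* Object residual SD: `s_j = sqrt(Σ resid_i² / (p − r))`.
* Membership: `F = s_j²/s0²` against the upper F tail; member iff
  p-value > α (default 0.05).

Two df conventions are implemented because they differ materially and both
appear in the SIMCA literature: the default `(m − r − 1), (m − r − 1)²`
and a classical `(p − r), (p − r)(m − r − 1)` selectable via
`df_convention="classical"`. The default form is deliberately lenient —
its critical values sit near 2–3 rather than just above 1 — which in
practice absorbs the extra residual variance a *new* object carries from
projecting onto subspaces estimated from small m; the classical form is the
one under which the test is approximately calibrated when objects truly
come from the fitted model (verified by simulation at α = 0.05 over 2,000
draws). An object accepted by several classes takes the largest p-value;
accepted by none, it is "unknown". A model with s0 = 0 (noiseless,
degenerate training) cannot support the test and raises with advice.

Component count r is chosen per class by leave-one-out PRESS: each object
held out, PCA refit, held-out squared residual accumulated per candidate
r ∈ 1..r_max with r_max = min(5, m − 2). Because naive row-wise PRESS
decreases (weakly) with every added component, the selector returns the
*smallest* r within 1% of the minimum. This parsimony rule behaves
correctly when residual variance is spread over many of the 416 bins
(pure-noise data → r = 1; clean rank-k structure → r = k) and is the reason
the synthetic generator overlays a full-support baseline (below).

Interclass distance: `D = max(0, sqrt((s12² + s21²)/(s11² + s22²)) − 1)`
with the cross residual s_qr computed over class q's objects in class r's
model with df m_q(p − r_r), and the own-residuals s_qq recomputed on the
same per-object df scale m_q(p − r_q). This convention makes D exactly 0
for a model against itself, symmetric in the pair, and gives "D > 1 means
really different classes" its usual reading.

Important m/z ranks bins by the variance-weighted loading magnitude
`sqrt(Σ_a λ_a V_ia²)` over the r retained components — the fragments whose
coordinated variation defines the class. Mean-centering makes the ranking
invariant to constant offsets. Note that the base peak is normalized to
exactly 100 and therefore carries no variance: the normalization reference
can never rank as "important", which matches chemical intuition (it is the
class's common anchor fragment, not its discriminator).

Leave-one-out class cross-validation refits only the held-out object's own
class without that object (other classes keep full training sets), with r
resolved once per class on the full set and capped so the reduced fit stays
valid. The confusion matrix carries one "unknown" column; row sums equal
class sizes.

## Peak-table I/O

The input dialect is one row per aligned mass signal: `rt_sec, mz,
<sample_1>, …, <sample_n>`. Alignment-export layouts vary by tool and
version, so one documented dialect is pinned for bit-exact tests; real
exports are adapted by column renaming. Signals are clustered into peaks by
single-pass centroid linkage in RT order with tolerance 1.5 s (three scan
periods at the 20 Hz acquisition rate the generator assumes). Per peak, the
spectrum is each member mass's intensity averaged across samples, then
normalized; per-sample heights are read at the base-peak m/z (quantifier-
ion convention); peak RT is the intensity-weighted mean of member RTs.
Duplicate m/z within one cluster keeps the more intense signal and logs a
deconvolution warning. The organized output matrix has one row per peak —
id, RT, status, name-or-class, DOC-or-p-value, then every sample height —
and never an empty cell; unknowns are retained.

## Synthetic data

The generators exist so every stage is testable without instrument data.

*Templates.* Five class templates carry the diagnostic fragment sets of
TMS-derivatized metabolite classes — sugar phosphate {89, 147, 217, 299},
organic acid {101, 133, 147}, sugar {89, 103, 147, 217}, amine
{86, 100, 174}, fatty acid {117, 129, 132, 145} — at high relative
intensity over a seeded low-intensity random background. Default training
sizes are 12/10/12/9/13 (sugar / sugar phosphate / organic acid /
fatty acid / amine), 56 spectra in all.

*Single spectra* are template draws with multiplicative lognormal noise
(relative SD `intensity_sd_rel`, default 5%), normalized.

*Training sets* add two kinds of structure a plain noisy template lacks.
First, compound-to-compound variation within a class: two latent factors
(fixed random modulation patterns over the fragment masses, scaled by
bounded unit-variance uniform scores of relative amplitude 0.2), the base
peak excluded since it is the normalization reference. Second, a Gaussian
detector baseline (SD 6 relative-intensity units, clipped at zero) overlaid
on every bin *after* normalization. The baseline gives the residual full
rank: without it, residual variance concentrates in the handful of fragment
bins, the LOO-PRESS selector chases those axes to r_max, s0 is biased
downward, and the membership test spuriously rejects training objects. The
ordering (normalize, then baseline) keeps residual variance homogeneous
across objects; normalizing after adding noise rescales each object's
baseline by its own noisy base peak and makes object variances genuinely
unequal — an instructive failure mode of base-peak normalization on real
data as well. With these defaults the five-class benchmark is stable across
seeds: diagonal LOO confusion, nothing unassigned, all pairwise D > 1.

*Batches.* `make_synthetic_batch` lays library compounds on an RT grid
(default start 300 s, step 10 s), gives each a distinct spectrum (per-
compound intensity variation plus two compound-specific fragments), and
observes them under affine drift `rt → α·rt + β` with uniform jitter. The
first and last compounds serve as anchors and are simulated jitter-free —
pseudo-internal standards are, by selection, stable peaks. Optional extras:
class-member peaks absent from the library placed between grid points
(annotation targets) and random-spectrum noise peaks (unknown targets).
Output is byte-deterministic under a fixed seed.

*What the generators do not emulate:* chromatographic peak shapes,
co-elution and deconvolution failure, derivatization by-products, retention
drift nonlinearity, and inter-batch library heterogeneity. Passing tests
therefore demonstrate the correctness and internal calibration of the
algorithms, not identification accuracy on real chromatograms.

## Numerical conventions and degenerate inputs

* Closed RT windows; boundary entries included.
* DOC clipped to [−1, 1] against rounding; |DOC| ≤ 1 + 1e-12 asserted.
* Loadings orthonormal to 1e-9; r ≤ min(m − 2, p) enforced.
* Anchor exactness to 1e-9 s; map inversion round-trip to 1e-6 s.
* All-zero spectra, zero-variance weighted vectors, s0 = 0 models,
  non-monotone or oversized anchor sets, malformed CSV cells: explicit
  typed errors naming the offending item, never silent repair.
* All simulations take seeds; LOO orderings are deterministic.

## Problem sizes

Test-suite simulations are desk-scale by design: 56-spectrum five-class
benchmarks, 100-peak batches, 2,000-draw calibration runs — sizes at which
every documented property is already decisive while the whole suite runs
in seconds.

## Known limitations

* The F-test df default is unusual among SIMCA variants; users comparing
  against other software should set `df_convention="classical"`.
* Annotation covers the five shipped classes only; peaks from other
  chemistries either fall to "unknown" or, when their fragments overlap a
  modeled class, may be annotated into it.
* The RT map is affine between anchors; strong nonlinear drift needs more
  anchors, not a different model.
* Heights use a single quantifier ion; summed-mass quantification is a
  config option but not the default.
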