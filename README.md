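# gcmsannot

Peak identification and chemical-class annotation for GC/MS metabolomics.

A GC/MS run of a biological sample yields a few hundred aligned peaks, of
which typically only a fraction can be named against an in-house reference
library; the rest are discarded as "unknowns" even though their electron-
ionization (EI) spectra carry usable chemical information. `gcmsannot` turns
an aligned peak table (the CSV export of alignment preprocessing such as
MetAlign) into an **organized peak × sample matrix with no missing values**
in which every peak is either

* **identified** — matched to a reference-library compound,
* **annotated** — assigned a chemical class (sugar, sugar phosphate,
  organic acid, fatty acid, amine) by one-class SIMCA models, or
* **unknown** — retained as a documented row, never dropped.

It is aimed at metabolomics practitioners who already run alignment
preprocessing and keep a retention-time/spectrum reference library.

## Method

**Retention-time correction.** Instead of an n-alkane retention-index
ladder, up to eight stable endogenous peaks serve as *pseudo-internal
standards*. Each anchor pairs its library retention time rt_old with the
time rt_new at which it eluted in the current batch; library RTs are updated
through the strictly monotone piecewise-linear map through the anchor pairs
(boundary segments extended outside the anchor range; a single anchor gives
a pure offset).

**Identification.** A peak at RT *t* is compared against library entries in
the closed window [*t* − c, *t* + c] (the user-set time width c, seconds).
Spectra are vectors of relative intensities over integer m/z 85–500 (416
variables, base peak normalized to 100). Because EI crowds ion current into
low masses, spectra are weighted before comparison,

    w(m) = I(m)^a · m^b        (defaults a = 0.5, b = 2),

and similarity is the Pearson product-moment correlation of the weighted
vectors — the *degree of coincidence* (DOC). The candidate with the highest
DOC wins; ties break on smaller |ΔRT|.

**Class annotation (SIMCA).** Each chemical class K is modeled by
mean-centered PCA on its m × 416 training matrix, keeping r components
(chosen per class by leave-one-out cross-validation):
X_K = T_K V_Kᵀ + E_K. The training residual standard deviation is

    s0 = sqrt( ΣΣ e_ki² / ((m − r − 1)(p − r)) ),

and an unidentified peak x, projected into the class subspace, has residual
distance s_j = sqrt( Σ resid² / (p − r) ). Membership is an F-test on
F = s_j² / s0², by default with (m − r − 1) and (m − r − 1)² degrees of
freedom (a classical convention (p − r), (p − r)(m − r − 1) is selectable);
the peak belongs to K when the residual variances are *not* significantly
different (p-value > α, default 0.05). A peak accepted by several classes
takes the largest p-value; a peak accepted by none is reported unknown.
Model separation is summarized by the interclass distance

    D = sqrt( (s12² + s21²) / (s11² + s22²) ) − 1   (clamped at 0),

where s_qr is the residual of class q's training spectra in class r's
model; D > 1 indicates genuinely distinct classes.

## Worked example

The package ships seeded generators for everything it consumes, so a full
run needs no external data:

```sh
gcmsannot simulate --out demo --seed 3   # library, peaks, training, config
gcmsannot run --config demo/config.yaml
```

prints

```
56 peaks: 50 identified, 5 annotated, 1 unknown
  annotated as amine: 1
  annotated as fatty acid: 1
  annotated as organic acid: 1
  annotated as sugar: 1
  annotated as sugar phosphate: 1
organized matrix written to demo/organized_matrix.csv
```

The simulated batch contains 50 library compounds under a linear RT drift
(rt → 1.02·rt + 3 s), five class-member peaks deliberately absent from the
library, and one structureless noise peak. After anchor-based RT correction
all 50 library peaks are identified, the five class-only peaks are each
annotated with their true class, and the noise peak lands in the unknown
row. The first lines of the organized matrix:

```
peak_id,rt_sec,status,annotation,score,S01,S02,S03,S04,S05
P0001,309,identified,cmpd_001,0.9999612226,10332.18063,8325.740952,...
P0002,314.1,annotated,sugar phosphate,0.7252727409,8631.34841,...
```

`score` is the DOC for identified peaks and the membership p-value for
annotated ones; the sample columns hold the base-peak (quantifier-ion)
heights, with no empty cells anywhere. `gcmsannot fit` serializes the SIMCA
models to JSON, and `gcmsannot classify` applies saved models to a peak
table; see `gcmsannot --help`.

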