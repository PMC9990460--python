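# Methods

## Screen model

The pipeline analyses a plate-based RNAi screen in which each library
gene occupies one pooled-siRNA well per daughter plate. The default
design is a 623-gene library on 7 master plates of 96 wells (89 library
wells + 7 control wells per plate), reformatted so that every gene is
measured in 3 replicate wells per condition, under two conditions
(LPS-stimulated, untreated/PBS), with the whole screen repeated twice —
6 wells per gene per condition in total, and 24 daughter plates per
condition and repeat (21 carrying library wells, padded with 3
control-only plates), i.e. 96 assay plates for the full design. Control
wells on every plate: 3 nontargeting-siRNA wells (the normalization
reference), 2 transfection-reagent-only wells, and 2 LPS-untreated
wells. The paper-facing counts (623/7/24/96) are asserted in tests; the
split of controls per plate is a package choice, as only "multiple
controls per plate" is documented for such screens.

Well addressing is plate-reader style (`A01`–`H12`). The pooled
3-siRNA reagent is modelled as a single library well per replicate, and
the three replicate wells of a gene sit on three daughter plates (one
per reformatting pass), not side by side on one plate.

## Assay quantification

- **Nitrite (Griess)**: OD inverted through an OLS standard curve
  `OD = slope·conc + intercept` fitted to sodium-nitrite standards;
  a fit with r² < 0.95 is flagged. Below-blank ODs clamp to 0 µM with a
  flag rather than erroring — they are ordinary reader noise.
- **LDH cytotoxicity**: `% cytotoxicity = 100 × experimental/maximum`,
  the maximum being the lysis-control (full kill) signal; clamped to
  [0, 100] with a flag.
- **Migration velocity**: from the wound-width time series,
  `v = (W_first − W_last) / (2·(t_last − t_first))` µm/h. The divisor 2
  is the two-edge convention (both wound edges advance); it is a
  documented convention, configurable only in the sense that callers can
  rescale. Negative velocities (wound widening) are allowed and flagged.
  A helper converts IncuCyte-style relative wound confluence to an
  equivalent width, `W = W₀·(1 − confluence)`, for exports without
  widths.
- **Phagocytosis**: background-subtracted fluorescence as fold over the
  same-plate nontargeting-control mean.

## Normalization and hit selection

Every well value is divided by the mean of the nontargeting-siRNA wells
of its own plate (same condition). Because plate-level factors multiply
all wells of a plate equally, this in-plate normalization cancels them
exactly — the property that justifies carrying controls on every plate,
and one the simulator asserts (a plate-effect SD of 1.5 log2 units
leaves recovered fold changes untouched to 1e−9).

Per gene × assay × condition, wells are pooled across the two screen
repeats before computing statistics (one SSMD/FC per gene per assay is
reported downstream; the per-repeat split is retained for the
replicate-correlation QC). The SSMD estimator is method-of-moments with
independent-group variance sum and n−1 denominators; a UMVUE variant
(Γ(K/2)/Γ((K−1)/2)·Δ/√SS, unbiased under equal group variances) sits
behind a switch. Degenerate inputs: both variances zero with equal
means → 0; with unequal means → a signed-infinity sentinel plus warning,
so a perfectly separated noiseless contrast is treated as an extreme
effect rather than an error (hit calling accepts ±inf, rejects NaN).

Cutoffs are inclusive and symmetric: |log2 FC| ≥ 0.5 and |SSMD| ≥ 1.65.
The Methods-style linear bounds (1.5-fold / 0.7-fold) correspond to
2^±0.5 ≈ 1.41/0.71; the log2 form is authoritative here and both are
exposed as one configurable threshold pair. Percentages of the library
are reported to one decimal with round-half-even.

**LPS dependence.** Evaluated on linear-scale fold changes of hits.
For phenotype-increasing hits the criterion is
`fc_LPS / fc_untreated > 1.5`. For phenotype-decreasing hits both fold
changes lie below 1 and the plain ratio would invert the intended
meaning, so the ratio is taken on magnitudes (`fc_untreated / fc_LPS`):
in both directions the shift away from 1 must be 1.5-fold stronger
under LPS. This interpretation for the decreasing branch is a package
decision and is flagged as such.

## Quality control

1. **Plate gate**: SSMD between the in-plate LPS-untreated wells
   (positive contrast) and the nontargeting wells, computed on the NO
   readout (the sharpest LPS separation); pass at |SSMD| ≥ 1.0, the
   conventional "moderate effect" boundary — configurable and echoed in
   report headers. Untreated/PBS plates carry no built-in separation
   contrast, so they inherit the verdict of the positionally paired LPS
   plate. All wells of failing plates are excluded before hit selection;
   this is asserted by record counting.
2. **Replicate reproducibility**: Pearson r of per-gene mean log2 FC
   between the two screen repeats, per assay; pass at r ≥ 0.8.
   Duplicated screens return exactly 1.0 (short-circuited past float
   round-off).
3. **Interassay CV**: `100·SD/mean` across the per-repeat mean library
   phenotype, per assay; pass below 20%. Library wells rather than
   controls are summarised because plate-normalized assays (phagocytosis
   fold) have control summaries pinned at 1, which would degenerate the
   CV to 0.

No spatial polish (B-score/median polish) is applied; the screen's
in-plate-control design addresses plate effects directly, and none is
described for this protocol.

## Integration and enrichment

Hit sets labelled `assay:category` are intersected exhaustively: the
overlap table reports every exclusive Venn region (counts of genes in
exactly that combination), pairwise/full intersections, per-set unique
counts, and the union (which the exclusive regions partition — asserted).
Over-representation uses the hypergeometric upper tail with the screened
library (not the genome) as universe — screen hits can only come from
the library — and Benjamini–Hochberg adjustment across sets. Term
networks/κ-score grouping of external enrichment suites are out of
scope.

## Synthetic screen generator

A library well's phenotype value is
`baseline(assay, condition) × 2^(e + p + edge + ε)` with `e` the gene's
true log2 effect (0 for nulls and, for LPS-dependent genes, in the
untreated condition), `p ~ N(0, 0.1)` a per-plate factor shared by all
wells of the plate including controls, `ε ~ N(0, 0.25)` per-well noise,
and an optional additive edge bias for border wells (default 0).
Multiplicative log-normal noise reflects positive, heteroscedastic
plate-reader readouts. Default spike structure: 10% of genes per assay,
|effect| uniform in 0.5–2.0 log2 units with random sign, 30% of genes
LPS-dependent (between the ~46% and ~17% observed for the migration and
phagocytosis assays in this kind of screen).

Values are then pushed through each assay's forward observation model:
Griess OD via the standard curve (slope 0.02 OD/µM, blank 0.05), LDH
absorbance against a lysis maximum of 6 AU, a wound-width series
(initial width 2000 µm, linear closure at 2v µm/h, sampled every 2 h
for 48 h — matching live-imaging cadence), and fluorescence over a
100 AU background. Baselines (LPS/PBS): nitrite 20/2 µM, LDH 0.9/0.3 AU,
velocity 2.5/5 µm/h, phagocytosis 1000/500 AU. They are chosen so (a)
the LPS-vs-untreated control contrast is strong enough for the plate QC
gate in every assay, and (b) the forward→inverse loop is exact across
the default effect range in the noiseless limit (no censoring at full
wound closure or 100% cytotoxicity). Censoring does exist at the model
boundaries — extreme effect+noise combinations can close the wound
early or exceed the lysis maximum — and compresses, never inflates,
recovered effects.

Randomness: `SeedSequence(seed, spawn_key=(0,))` for the truth draw and
`(1, plate_index)` per plate, so identical seeds are bit-identical and
growing the design does not reshuffle existing plates.

**What the simulator does not emulate**: cell-composition heterogeneity
(astrocyte/microglia fractions), siRNA off-target or partial-knockdown
effects, spatial within-plate gradients beyond a uniform edge offset,
image-level artifacts, or correlated noise between the multiplexed
assays. Passing recovery tests therefore demonstrate the correctness of
the statistical chain under the stated noise model, not robustness to
every failure mode of real screens.

## Test and verification sizes

The acceptance-style checks run the full 623-gene design (≈ 230k readout
rows, a few seconds); property tests use a structurally complete 60-gene
single-master-plate design. Estimator-bias checks average 200 seeded
30-gene screens; the observed log2-FC bias (≈ −0.014) is the Jensen term
from dividing by a finite 3-well control mean and stays within the
±0.02 band. The ORA null calibration uses 11 sets of 100–300 genes and
150-gene null draws: sizes large enough that the discrete hypergeometric
attainable levels approach the nominal α (smaller sets are conservative
by discreteness alone). Brute-force reimplementations (plain-Python
SSMD/Hedges' g/log2 FC, Monte-Carlo call-rate oracles) are kept
independent of the library code paths they verify.

## Known limitations

- LPS-dependence is only assessed for genes called hits under LPS and
  screened in both conditions; no uncertainty is attached to the ratio.
- The per-plate QC contrast presumes the untreated-well separation is
  expressed in the gated assay; screens without an NO-like readout
  should pass an explicit `qc_assay`.
- Validation concordance compares categorical calls only; it does not
  model the direction or size of validation effects.
- The pipeline assumes positive phenotype values for log-ratio
  normalization; clamped-to-zero wells propagate as −inf log ratios and
  surface in the hit table rather than being imputed.
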