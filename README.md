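# gliascreen

Analysis pipeline for multiplexed 96-well siRNA phenotype screens, built
around the screen design used to interrogate glial kinase signaling: a
623-kinase pooled-siRNA library arrayed on seven master plates,
reformatted into triplicate daughter plates, screened twice under two
conditions (LPS-stimulated vs untreated mixed glial cultures), and read
out with four assays in parallel — nitric-oxide production (Griess
nitrite), LDH cytotoxicity, wound-healing migration, and Zymosan
phagocytosis.

It is intended for screeners and computational biologists who need a
tested, reproducible route from raw plate-reader exports to hit lists:
control-based normalization, plate-level quality control, dual-flashlight
hit calling, LPS-dependence classification, effect sizes, and cross-assay
integration — plus a ground-truthed synthetic screen generator for
validating the whole chain.

## The statistics at the core

Per gene *g* and assay, every knockdown well is normalized to the mean of
the nontargeting-siRNA wells of its own plate, which cancels plate-level
multiplicative effects. Pooling the replicate wells of both screen
repeats (n = 6 wells/gene/condition by default):

- **Average fold change** — mean of the per-well log2 ratios,
  `FC_g = mean_i log2(x_gi / x̄_neg,plate(i))`.
- **Strictly standardized mean difference** —
  `SSMD_g = (mean(sample) − mean(control)) / sqrt(var(sample) + var(control))`
  with unbiased (n−1) group variances, contrasting the gene's normalized
  wells against the pooled same-plate control wells.
- **Dual-flashlight call** — *increased* iff `FC_g ≥ +0.5` (log2) and
  `SSMD_g ≥ +1.65`; *decreased* iff `FC_g ≤ −0.5` and `SSMD_g ≤ −1.65`;
  boundaries inclusive; otherwise *none*.
- **LPS dependence** — a hit is LPS-dependent when its linear fold change
  under LPS exceeds the untreated fold change by more than 1.5-fold
  (ratio taken on magnitudes for phenotype-decreasing hits).
- **Hedges' g** — bias-corrected standardized mean difference
  `g = J·(mean(sample) − mean(control))/s_pooled`, `J = 1 − 3/(4·df − 1)`,
  labelled large/moderate/small at |g| ≥ 0.8/0.5/0.2.

QC layers: per-plate control SSMD gate (|SSMD| ≥ 1.0 between the in-plate
LPS-untreated and nontargeting wells; failing plates contribute nothing
downstream), replicate-screen Pearson correlation (pass at r ≥ 0.8), and
interassay CV (< 20%). Cross-assay integration reports Venn-style overlap
regions and hypergeometric over-representation with Benjamini–Hochberg
adjustment against the library as universe.

## Worked example

Simulate and analyse a small screen (60 genes, one master plate, 15%
spiked hits) end to end:

```sh
cat > config.yaml <<'YAML'
design:
  n_genes: 60
  n_master_plates: 1
  pad_to_daughters: null
simulation:
  seed: 11
  hit_fraction: 0.15
thresholds:
  fc_log2: 0.5
  ssmd: 1.65
  lps_ratio: 1.5
YAML
gliascreen run --config config.yaml --out out/
```

which prints the per-stage row counts

```
{"wells_in": 22512, "values": 3216, "values_after_qc": 3216, "plates_failed_qc": 0, "gene_assay_stats": 480}
```

(22,512 raw readout rows — the wound assay contributes a 25-point width
time series per well — quantified into 3,216 per-well phenotype values,
no plate lost to QC, and 480 gene × assay × condition statistics). The
LPS-condition hits of the NO assay in `out/hits_no.tsv`:

```
gene_id  mean_log2fc      ssmd  category lps_dependent
KIN0024    -1.081112 -3.238341 decreased         False
KIN0030     1.461719  3.644583 increased          True
KIN0033     1.647960  6.255008 increased         False
KIN0035    -0.995906 -3.757716 decreased          True
KIN0046    -1.223723 -4.012979 decreased         False
KIN0058    -1.421701 -5.022856 decreased         False
```

e.g. knocking down KIN0030 raised NO production 2.8-fold (log2 FC 1.46)
with a strongly reliable separation from controls (SSMD 3.6), and the
effect required LPS stimulation. `out/` also contains dual-flashlight
tables for plotting, the QC report (TSV + JSON), phenotype-overlap
counts, the simulation ground truth and a manifest with file digests —
reruns are byte-identical for the same config and seed.

The same stages are scriptable individually (`gliascreen simulate`,
`quantify`, `qc`, `hits`, `integrate`) or callable as library functions
(`gliascreen.simulate_screen`, `score_genes`, ...).

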