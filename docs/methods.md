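# Methods

## The model of thymocyte development behind the simulator

Each simulated cell carries two latent variables: a maturation time
`t ∈ [0, 1]` and an eventual lineage branch (CD4 or CD8). Cells are drawn
per sorted surface phenotype — CD69− DP, CD69+ DP, TCRβhi DP, CD4+CD8low,
CD4 SP, CD8 SP — with `t` uniform in one of five consecutive stage windows
(the two SP subsets share the last window; their branch, not their time,
separates them). Adjacent windows overlap by 10% of their width so that
sort boundaries mix, as real gates do. SP cells' branches match their
phenotype; earlier cells are assigned a branch 50/50.

Gene programs and their kinetics (all on the count-mean scale, per-gene
baselines log-normal):

| program | default size | kinetic | default amplitude |
|---|---|---|---|
| maturation_up / maturation_down | 80 + 80 | logistic ramp in `t`, pinned to baseline at one end and baseline × fold at the other | fold 8 |
| activation_pulse | 80 | Gaussian bump centred at `t = 0.5` (width 0.15), equal to baseline at both ends; the rise above baseline is multiplied by `activation_scale` | amplitude 6 |
| cd4_lineage / cd8_lineage | 40 + 40 | late sigmoid (onset 0.75) gated on the matching branch | fold 6 |
| housekeeping | 177 | flat | — |
| coreceptor (Cd4, Cd8a, Cd8b1) | 3 | product of steep logistic on/off windows | on-mean ≈ 2000 counts |

The amplitudes were fixed once so that the variance decomposition of the
log-normalised data is dominated by maturation, then activation, then
lineage (roughly 54/20/18% of the first five PCs on the default data) —
the ordering the analysis assigns to PC1/PC2/PC3. Counts are negative
binomial (dispersion θ = 2, so variance = μ + μ²/2) around the kinetic
means, scaled so the mean library is 10⁶ reads (deep SMART-seq-like
libraries, which makes the 5×10⁵–1.5×10⁶ QC window directly applicable),
then zeroed independently per gene with a per-program dropout
probability: 0.03 for the coreceptor genes (their observed detection in
cells that should express them is 92–99% at this depth) and 0.05
elsewhere.

### Coreceptor timing regimes

The coreceptor genes follow on/off windows in `t`:

- **sequential** (unperturbed thymus): every signalled cell shuts off
  *Cd8a* at `t = 0.35` (the Cd4+Cd8a− audition stage); CD8-fated cells
  shut off *Cd4* and re-express *Cd8a* at `t = 0.55`. The switch times
  span the intermediate sort windows, so CD69+ DP cells are mostly
  Cd4+Cd8a+ with emerging Cd4+Cd8a−, TCRβhi DP mix all three classes and
  CD4+CD8low splits between the single-positive states.
- **simultaneous** (MHC class II-deficient-like): CD4-path cells shut
  off *Cd8a* and CD8-path cells shut off *Cd4* at the same `t = 0.55`,
  so both single-positive states arise together.

The smooth windows use steepness 400, which keeps the *detectable* range
of a coreceptor gene (count ≥ 1 at on-mean ≈ 2000) within ~0.02 of the
time axis of its on-window; with a shallower transition, detection-level
expression leaks far outside the window and the binary classifier can no
longer mirror the latent state.

The MHC class II-deficient condition is modelled as (a) simultaneous
timing, (b) `activation_scale = 0.5` (weaker TCR signals when ligands are
restricted to MHC class I; the true reduction is not quantified, so the
scale is exposed rather than fixed), and (c) a silenced CD4-lineage
program with the CD8-lineage program ungated — every selected cell in
such a thymus is CD8-fated, so gating the CD8 program on the coreceptor
path would create a branch-asymmetric expression signal that contaminates
the maturation axis.

### What the generator does not emulate

No batch effects beyond a label, no UMI structure, no read-level
artefacts, no doublets or ambient RNA, no mean-dependent dropout, and no
transcriptome-scale gene panel (500 genes vs ~15k expressed). Passing
tests therefore show that the pipeline recovers the designed structure
under realistic sampling noise — not that it is robust to the full
artefact spectrum of real thymus data.

## Analysis pipeline

- **QC**: cells kept with total counts in [500000, 1500000].
- **Normalisation**: `log(1 + count × 10⁴ / cell_total)`.
- **HVG selection**: lowess trend of log10 variance on log10 mean
  (window fraction 0.3, widened so every window holds ≥ 10 genes);
  counts standardised by the trend, clipped at √n_cells; score =
  variance of clipped values; *Cd4*/*Cd8a*/*Cd8b1* removed after scoring
  so the embedding cannot simply encode the states it later orders.
  Default size 2000 (on the 500-gene synthetic panel this keeps all
  non-excluded genes, with a warning). Ties break lexically.
- **PCA**: per-gene centring/unit scaling on the HVG submatrix, clipped
  at ±10 SD to bound outlier leverage; full SVD; variance reported both
  as a fraction of total variance and of the first five PCs. Axis signs
  are set biologically (SP right of pre-selection DP on PC1; activation
  markers positively correlated with PC2; CD4 SP above CD8 SP on PC3),
  because every downstream ordering statement depends on direction.
- **Axis annotation**: per-gene Pearson correlation with the PC and a
  natural-cubic-spline F-test (df = 4, knots at equal quantiles) of the
  null of no change along the PC. Top genes (by spline p-value by
  default, by |R| optionally) are tested for membership in the
  activation/lineage reference sets by two-sided Fisher exact tests
  against the all-genes background; a PC is labelled by its most
  significant set below α = 0.01. The pipeline's default list size is
  100 — proportionate, on a 500-gene panel, to taking the top 1000 of a
  ~15k-gene transcriptome.
- **Coreceptor calls**: detection threshold τ = 1 raw count (exposed as
  a parameter; at SMART-seq depth ≥ 1 read is the natural reading of
  "detected"). Cd4−Cd8a− calls are retained in the table but excluded
  from ordering and subset DE, with their count reported. Detection
  frequencies in the sorted reference populations are the dropout audit.
- **Ordering**: per-state histograms over 20 equal-width bins on the
  pooled axis range, each normalised to its own maximal bin. One-sided
  two-sample KS with the direction fixed a priori (CD4_state before
  CD8_state); exact p by enumeration of group assignments when the
  smaller sample has ≤ 8 observations (valid under ties), otherwise
  `exp(−2D²nm/(n+m))`. A condition is called *sequential* when this test
  rejects at α = 0.01 and *simultaneous* otherwise.
- **Pseudotime**: single-lineage Hastie–Stuetzle principal curve —
  initial arc-length by projection on the points' first principal axis,
  then alternating lowess smoothing of each coordinate against arc
  length (fraction 0.3, 200-point grid) and projection onto the
  polyline; convergence when the mean squared movement of projected
  points falls below 10⁻⁴ of the total variance (cap 20 iterations; a
  non-converged fit returns its best iterate, flagged). Pseudotime is
  arc length normalised to [0, 1], oriented to increase with the first
  input coordinate. A single curve suffices because trajectory analysis
  is applied only to pooled selection intermediates.
- **Differential expression**: per-gene two-sided Wilcoxon rank-sum with
  midrank tie correction and continuity correction; exact permutation
  tails (subset-sum counting over doubled midranks) when the smaller
  group has ≤ 10 cells; no fold-change pre-filter; BH adjustment within
  each comparison. log2FC is the ratio of `mean(expm1(values)) + 1`
  between groups on the normalised scale — a declared convention, stated
  explicitly because several are in circulation. Lineage-specificity
  contrasts and gene-set enrichment share one Fisher exact
  implementation. Cross-comparison coherence combines the Pearson
  correlation of log2FC vectors with a linear-by-linear association test
  (integer scores, M² = (N−1)r², χ²₁) on the 3×3 down/flat/up table at a
  |log2FC| threshold of 0.25 — the discretisation is a declared choice.

## Determinism and problem sizes

One pipeline seed fans out through `numpy.random.SeedSequence` to
per-stage child seeds, so an identical configuration reproduces a
byte-identical report. Default problem sizes — 50 cells per sorted subset
(300 per condition), 500 genes, and 100 cells per subset where the
ordering statistics themselves are the object of study — were chosen to
match the scale at which the sorted-plate experimental design operates
while keeping any analysis re-runnable in seconds.

## Known limitations

The KS exact path enumerates assignments conditional on the observed
values, which differs from continuous-distribution exact tables in the
presence of ties (it is the correct permutation test there). The
principal curve is single-lineage and will fold on data whose dominant
variance direction is orthogonal to the trajectory. Axis labels for a
condition lacking a lineage dichotomy (the KO, whose CD4 program is
silent) are legitimately `unassigned` for PC3. The spline F-test assumes
roughly Gaussian residuals; on strongly zero-inflated genes its p-values
are approximate, which is why the enrichment step, not the per-gene test,
carries the axis interpretation.
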