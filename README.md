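# thymotrace

Ordering CD4/CD8 coreceptor expression states of thymocyte selection
intermediates from deep single-cell RNA-seq.

## The scientific problem

CD4 helper and CD8 cytotoxic T cells both arise from CD4+CD8+
double-positive (DP) thymocyte progenitors. How a cell's coreceptor
expression is matched to its TCR's MHC-class restriction — the CD4/CD8
lineage choice — hinges on the order in which selection intermediates pass
through coreceptor transcript states: *Cd4*+*Cd8a*+ → *Cd4*+*Cd8a*− →
*Cd4*−*Cd8a*+ under kinetic-signalling models. Because intermediates are
rare and surface phenotype does not report coreceptor gene activity, the
question needs deep full-length scRNA-seq in which transcript detection is
near-binary, so a cell's state can be read from whether *Cd4* and *Cd8a*
counts are detected at all.

`thymotrace` is a library for this analysis, aimed at computational
immunologists. It provides:

- a **ground-truthed simulator** of SMART-seq-like thymocyte counts with a
  latent maturation time, an activation pulse, a CD4/CD8 lineage branch
  and piecewise coreceptor kinetics under two timing regimes
  (`sequential` vs `simultaneous`, the latter emulating an MHC class
  II-deficient thymus);
- the **analysis pipeline**: QC by library size, log-normalisation,
  highly-variable-gene selection excluding *Cd4*/*Cd8a*/*Cd8b1*, PCA with
  biologically oriented axes (PC1 maturation, PC2 activation, PC3
  lineage), Fisher-exact axis annotation against reference gene sets, a
  natural-spline test of change along an axis, binary coreceptor state
  calls with a detection-frequency dropout audit, and a principal-curve
  pseudotime;
- the **ordering statistics**: per-state max-normalised frequency curves
  along an axis and a one-sided two-sample Kolmogorov–Smirnov test with
  the a-priori direction *Cd4*+*Cd8a*− before *Cd4*−*Cd8a*+, exact by
  enumeration for small samples, plus centroid distances, rank-sum
  differential expression with Benjamini–Hochberg control, Fisher exact
  lineage-specificity contrasts and condition-shift tests.

For two samples with ECDFs F_A, F_B the ordering statistic is
D = sup_x (F_A(x) − F_B(x)), with one-sided p = exp(−2D²nm/(n+m)) for
large samples and full enumeration of group assignments otherwise; a
small p with the fixed direction means state A occupies earlier axis
positions than state B.

## Worked example

```sh
python examples/04_ordering_wt_vs_ko.py
```

prints (seed 0):

```
MHCII_KO : simultaneous (one-sided KS CD4-before-CD8: D=0.031, p=0.966)
WT       : sequential   (one-sided KS CD4-before-CD8: D=0.569, p=7.88e-07)

WT intermediates per coreceptor state: {'DP_state': 46, 'CD4_state': 72, 'CD8_state': 31}
WT frequency-curve peak bins along PC1: {'DP_state': 2, 'CD4_state': 3, 'CD8_state': 12}
pseudotime corroboration (KS p): {'WT': '6.32e-11', 'MHCII_KO': '0.929'}
```

In the wild-type condition the *Cd4*+*Cd8a*− intermediates peak in an
earlier PC1 bin than the *Cd4*−*Cd8a*+ intermediates and the one-sided KS
test rejects strongly: the states arise sequentially. In the MHC class
II-deficient condition the same test is null — the two single-positive
states arise simultaneously, so the timing of coreceptor expression is
signal-dependent rather than hardwired. The pseudotime axis (principal
curve through PC1–3) corroborates both verdicts. Other examples cover
simulation (`01`), embedding and axis annotation (`02`), coreceptor state
calling (`03`) and differential expression (`05`); a thin CLI
(`thymotrace simulate|run|report`) wraps the same pipeline.

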