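"""Order coreceptor states along maturation, wild type versus MHC II KO.

Runs the full two-condition pipeline: in the wild type the Cd4+Cd8a-
state precedes the Cd4-Cd8a+ state along oriented PC1 (one-sided KS
test), while in the MHC class II-deficient condition the two states
arise simultaneously.
"""
import thymotrace as tt

bundle = tt.run_pipeline(tt.PipelineConfig(seed=0))

for cond, v in sorted(bundle["comparison"]["verdicts"].items()):
    print(f"{cond:9s}: {v['verdict']:12s} "
          f"(one-sided KS CD4-before-CD8: D={v['d']:.3f}, p={v['p']:.3g})")

wt = bundle["conditions"]["WT"]
print("\nWT intermediates per coreceptor state:", wt["intermediate_state_counts"])
print("WT frequency-curve peak bins along PC1:", wt["ordering_pc1"]["peak_bins"])
print("pseudotime corroboration (KS p):",
      {c: f"{bundle['conditions'][c]['ordering_pseudotime']['ks']['CD4_before_CD8']['p']:.3g}"
       for c in bundle["conditions"]})
# A small KS p with the fixed a-priori direction means Cd4+Cd8a-
# intermediates sit earlier on the maturation axis than Cd4-Cd8a+ ones;
# the KO's large p means the order collapses when TCR ligands are
# restricted to MHC class I - the timing is signal-dependent, not hardwired.
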