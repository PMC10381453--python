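"""Cross-validate all seven model families leave-one-joint-out.

Fits one-block PLS-DA per modality, the three two-block fusions, and the
three-block fusion on a simulated study with a moderate planted class
effect (3x the replicate noise), selecting the latent-variable count that
minimises the cross-validated misclassification rate.  All samples of one
joint are held out together, so no within-animal information leaks into
training.
"""

import cartifuse as cf

study = cf.generate_study(cf.default_config(seed=1))
prepared = cf.prepare_blocks(study.blocks, study.design, cf.REFERENCE_SPECS)
y = study.design.labels

print(f"{'model':16s} {'acc%':>5s} {'sens%':>6s} {'spec%':>6s} {'LV':>3s}")
for fam in cf.model_families(prepared.modalities):
    cv = cf.run_cv(prepared.subset(fam), y, study.design, A_max=10)
    rep = cf.report(cv, label="+".join(fam))
    print(f"{rep['model']:16s} {rep['accuracy_pct']:5d} "
          f"{rep['sensitivity_pct']:6d} {rep['specificity_pct']:6d} "
          f"{rep['lv']:3d}")

print("\nAccuracy is the out-of-fold fraction of the 120 samples classified")
print("correctly at the selected LV; sensitivity/specificity are the damaged")
print("and control per-class rates. Fusion should match or beat one-block.")
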