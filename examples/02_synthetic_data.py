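"""Generate a synthetic mutagenesis dataset with known ground truth.

The generator mimics a curated affinity-mutagenesis compendium: mutations
grouped by complex, class proportions near 208/670/1076, per-class ddG
mixture components truncated at the +/-0.5 kcal/mol thresholds, and 33
features whose informativeness is controlled by the separability knob.
"""

from ppimut import GeneratorConfig, generate

ds = generate(GeneratorConfig(n_mutations=1000, separability=2.0, seed=7,
                              unlabeled_multiplier=2))

print(f"labeled mutations:   {len(ds.labeled)}")
print(f"unlabeled pool:      {len(ds.unlabeled)} (latent truth kept aside)")
print("class fractions:")
for label, frac in ds.labeled.labels.value_counts(normalize=True).items():
    print(f"  {label:12s} {frac:.3f}")
print("ddG range per class (kcal/mol):")
for label, group in ds.labeled.frame.groupby("label")["ddg"]:
    print(f"  {label:12s} [{group.min():+.2f}, {group.max():+.2f}]")
print(f"informative features: {', '.join(ds.informative_features[:4])} ...")

# Every beneficial ddG sits strictly below -0.5 and every detrimental one
# strictly above +0.5, so labels re-derive exactly from the latent ddG.
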