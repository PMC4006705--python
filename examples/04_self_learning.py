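"""Self-learning random forest versus its supervised baseline.

The protocol: fit a forest on the labeled set, pseudo-label every
unlabeled mutation, merge, and refit once.  On data where the unlabeled
pool is informative the refit forest matches or improves the baseline.
"""

from ppimut import LearnerConfig, PROBLEM_3, generate, GeneratorConfig, predict, train, truth_accuracy

ds = generate(GeneratorConfig(n_mutations=500, separability=1.0, seed=5,
                              unlabeled_multiplier=2))
train_part = ds.labeled.select([i < 400 for i in range(len(ds.labeled))])
test_part = ds.labeled.select([i >= 400 for i in range(len(ds.labeled))])
probe = test_part.drop_labels()

supervised = train(train_part, PROBLEM_3, LearnerConfig(kind="rf", seed=5))
semi = train(train_part, PROBLEM_3, LearnerConfig(kind="rf_sl", seed=5),
             unlabeled=ds.unlabeled)

print("pseudo-label counts:", semi.training_summary["pseudo_label_counts"])
print(f"supervised RF held-out accuracy:    {truth_accuracy(predict(supervised, probe), ds):.3f}")
print(f"self-learning RF held-out accuracy: {truth_accuracy(predict(semi, probe), ds):.3f}")

# Every unlabeled mutation receives exactly one pseudo-label; with an
# empty unlabeled pool the two models would be identical.
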