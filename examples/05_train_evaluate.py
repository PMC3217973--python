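"""Train, cross-validate and independently test a splicing-factor classifier.

Amino-acid composition plus binary domain features feed an RBF-kernel SVM;
C and gamma are grid-searched to maximise pooled five-fold CV accuracy, and
the frozen model is then evaluated on an independently generated test set.
Sensitivity is the recall on splicing factors, specificity on negatives.
"""

from spliceid import (
    FeatureConfig,
    SyntheticSpec,
    assemble_features,
    build_vocabulary,
    evaluate,
    generate_dataset,
    grid_search,
    train_svm,
)

pos, neg = generate_dataset(SyntheticSpec(seed=1))
vocab = build_vocabulary(pos)
config = FeatureConfig(blocks=("aac", "domain"), vocabulary=vocab)
X, y = assemble_features(pos + neg, config)

gs = grid_search(X, y, C_grid=[2.0**e for e in range(-1, 10, 2)],
                 gamma_grid=[2.0**e for e in range(-9, 2, 2)], k=5, seed=1)
pooled = gs.cv.pooled
print(f"grid search winner: C={gs.best_C}, gamma={gs.best_gamma}")
print(f"pooled 5-fold CV:  Sn={pooled.sensitivity:.2f}%  "
      f"Sp={pooled.specificity:.2f}%  Acc={pooled.accuracy:.2f}%")

model = train_svm(X, y, gs.best_C, gs.best_gamma, seed=1, config=config)
test_pos, test_neg = generate_dataset(SyntheticSpec(n_pos=100, n_neg=400, seed=2))
metrics = evaluate(model, test_pos + test_neg)
print(f"independent test:  Sn={metrics.sensitivity:.2f}%  "
      f"Sp={metrics.specificity:.2f}%  Acc={metrics.accuracy:.2f}%")
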