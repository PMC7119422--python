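"""Train the complex decision tree on synthetic spheroids and classify.

Reproduces the engineered branch end to end: generate a labelled training
set (40 per coarse group), extract the 15 features, train with 20-fold
cross-validation on the 12-feature subset, classify unseen spheroids, and
re-examine group-1/3 calls with the secondary lumen-descriptor tree.
"""

import dataclasses

import numpy as np

import spheropol as sp
from spheropol.classify import train_secondary_tree

params = dataclasses.replace(sp.SCALED_PARAMS, z_planes=1)

train = sp.generate_dataset(
    {"1_regular": 40, "2_inverse": 40, "3a_aggregate": 20, "3b_multilumen": 20},
    params,
    seed=7,
)
test = sp.generate_dataset(
    {"1_regular": 25, "2_inverse": 25, "3a_aggregate": 13, "3b_multilumen": 12},
    params,
    seed=1007,
)

f_train = sp.extract_features_batch(train.stacks, n_slices=1)
f_test = sp.extract_features_batch(test.stacks, n_slices=1)
y_train = [l.coarse_label for l in train.labels]
y_test = [l.coarse_label for l in test.labels]

model = sp.train_tree(f_train, y_train, folds=20, seed=7)
print(f"20-fold CV accuracy on 120 training spheroids: {model.cv_accuracy:.1%}")

records = sp.predict(model, f_test)
acc = np.mean([r.predicted == y for r, y in zip(records, y_test)])
print(f"accuracy on {len(y_test)} unseen spheroids:          {acc:.1%}")

secondary = train_secondary_tree(f_train, y_train, seed=7)
records = sp.reclassify(records, f_test, secondary)
acc2 = np.mean([r.final == y for r, y in zip(records, y_test)])
n_changed = sum(r.reclassified for r in records)
print(f"after group-1/3 reclassification ({n_changed} changed): {acc2:.1%}")

ranked = sp.feature_importance(f_train, y_train, seed=7)
print("\ntop five features by impurity-decrease importance:")
for name, score in ranked[:5]:
    print(f"  {name:<28} {score:.3f}")
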