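"""Accuracy as a function of ensemble size.

Sweeps N_learn over {1, 5, 10, 25, 50} on weakly separated Gaussian
features with 10x10 CV: accuracy rises steeply for small ensembles and
plateaus by a few dozen weak learners.
"""

import numpy as np

from nirsbag import (
    GaussianFeatureConfig,
    generate_gaussian_features,
    stratified_folds,
    sweep_hyperparameters,
)

features = generate_gaussian_features(
    GaussianFeatureConfig(
        class_means=np.vstack([np.zeros(36), np.full(36, 0.25)]),
        n_per_class=30,
        seed=4,
    )
)
folds = stratified_folds(features.labels, k=10, repetitions=10, seed=4)
sweep = sweep_hyperparameters(
    features, {"n_learn": [1, 5, 10, 25, 50]}, folds, seed=4
)

for n, acc in zip(sweep.values, sweep.mean_accuracies):
    bar = "#" * int(round(60 * acc))
    print(f"N_learn = {n:3d}: {100 * acc:5.1f}%  {bar}")
print(f"selected ensemble size: {sweep.selected} "
      "(argmax of mean accuracy, ties to the smaller size)")
# A single bootstrap-trained learner (N=1) is noticeably worse than the
# ensemble; past ~25 learners extra members change little.
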