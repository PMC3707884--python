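"""Hyperparameter grid search and decision-threshold sweep.

The grid searches (log2 C, log2 w_ratio) by cross-validated balanced
accuracy on shared folds.  The sweep then shifts the decision threshold of
a trained model: sensitivity can only fall and specificity only rise as the
threshold increases, tracing the trade-off around the hyperplane.
"""

import numpy as np

from orfsvm import (
    ScalingModel,
    encode_matrix,
    grid_search,
    make_benchmark,
    threshold_sweep,
    train,
)

bench = make_benchmark(250, 250, signal="yeast_like", seed=4)
X = encode_matrix([s.sequence for s in bench.sequences], (1, 2, 3, 5))
y = np.array([s.label for s in bench.sequences])

result = grid_search(
    X, y, log2C_grid=[-5, -3.5, -2, 0], log2w_grid=[-0.6, 0.0, 0.6], k=3, seed=0
)
print(f"grid best: C = 2^{result.best_log2C}, w_ratio = 2^{result.best_log2w}")
print(f"best CV balanced accuracy: {result.accuracy.max():.2f}%")

scaler = ScalingModel.fit(X)
model = train(scaler.transform(X), y, C=result.best_C, w_ratio=result.best_w_ratio)
print("\nthreshold sweep (offset, Sn, Sp):")
for t, sn, sp in threshold_sweep(model, scaler.transform(X), y, [-1.0, -0.5, 0.0, 0.5, 1.0]):
    print(f"  {t:+.1f}   Sn {sn:6.2f}%   Sp {sp:6.2f}%")
print("lowering the threshold buys sensitivity at the cost of specificity")
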