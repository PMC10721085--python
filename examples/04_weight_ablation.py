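"""Robustness of the readout to losing sensors.

Fits a readout on standardized coordinates, then zeroes weight columns
— always both coordinates of the same feature point, weakest (by the
basis class's absolute weight) first, never retraining — and tracks the
test accuracy.  The curve decays in plateaus separated by sharp steps:
most units are redundant, and accuracy collapses only once a class's
few load-bearing units are gone.
"""

import numpy as np

from swayrc import fit_readout, make_benchmark
from swayrc.experiments import ablation_trace

bench = make_benchmark("six_class", seed=1, mode="series")
# standardized inputs; alpha scaled to the unit-variance data
model = fit_readout(bench.X_train, bench.y_train, alpha=1e3,
                    standardize=True, n_classes=6)

for basis in (0, 1):
    trace = ablation_trace(model, bench.X_test, bench.y_test,
                           basis_class=basis, order="increasing")
    marks = "  ".join(f"{c:3d}:{a:.2f}" for c, a in
                      zip(trace.removed_counts[::4],
                          trace.accuracies[::4]))
    print(f"basis class {basis}  (removed:accuracy)  {marks}")

print()
print("Reading: with 0 units removed accuracy is ~1.0; it stays flat")
print("while redundant units disappear and drops in steps when the")
print("basis class loses its informative feature points.")
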