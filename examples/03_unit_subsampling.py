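"""How many reservoir units does six-class classification need?

Retrains the ridge readout on random subsets of 1..10 of the 48 tracked
coordinates (100 subsets each here; the full study uses 1000) and prints
the median and quartiles of the test accuracy.  A single unit is at
chance; around eight units the median clears 90%.
"""

import numpy as np

from swayrc import make_benchmark
from swayrc.experiments import subsample_experiment

bench = make_benchmark("six_class", seed=1, mode="series")

print("units  median   q25     q75")
for n_units in range(1, 11):
    res = subsample_experiment(bench.X, bench.labels, n_units=n_units,
                               n_trials=100, seed=2, alpha=1e6,
                               train_idx=bench.train_idx,
                               test_idx=bench.test_idx)
    q25, q75 = np.quantile(res.accuracies, [0.25, 0.75])
    print(f"{n_units:5d}  {res.median:.3f}   {q25:.3f}   {q75:.3f}")

print()
print("Every coordinate of every tracked point is an interchangeable")
print("sensor: the wind class is encoded redundantly across the plant.")
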