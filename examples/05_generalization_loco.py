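"""Does the readout generalize to a wind condition it never saw?

Trains on five of the six classes (standardized inputs) and scores the
held-out class's data.  The top-scoring classes share the excluded
condition's wind *direction*: the readout has learned direction as a
feature, not just memorized six clusters.
"""

import numpy as np

from swayrc import make_benchmark
from swayrc.experiments import leave_one_class_out

bench = make_benchmark("six_class", seed=1, mode="series")
table = bench.labels.class_table

for excluded in range(6):
    res = leave_one_class_out(bench.X, bench.labels, excluded, alpha=1e6)
    direction, speed = table[excluded]
    tops, counts = np.unique(res.top_class, return_counts=True)
    top = int(tops[counts.argmax()])
    print(f"excluded class {excluded} (dir {direction:5.1f} deg, speed "
          f"{speed}): top class {top} (dir {table[top][0]:5.1f} deg), "
          f"same-direction dominance {res.dominance:.2f}")

print()
print("dominance = fraction of held-out steps whose top class blows from")
print("the same direction as the class the readout never trained on.")
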