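"""Recompute a full metric table from a bare confusion matrix.

Useful for auditing published results: given only labelled-vs-predicted
counts, derive per-class and overall accuracy, sensitivity, specificity
and precision.  Overall values micro-aggregate (sum one-vs-rest
TP/TN/FP/FN across classes first), which weights each behaviour by how
often it occurs.
"""

import numpy as np

from broileracc.evaluate import ConfusionMatrix3, format_report

# labelled rows x predicted columns over (sit, stand, walk)
counts = np.array(
    [
        [1690, 170, 5],
        [73, 230, 30],
        [0, 21, 278],
    ]
)
print(format_report(ConfusionMatrix3(counts)))
print()
print("note how standing, the rarest class, shows the weakest sensitivity")
print("and precision — windows at posture transitions are easily confused.")
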