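"""Collapse a fine disability-profile matrix into coarse model states.

Destination probabilities are summed over each coarse group; source
rows merging into one coarse state are combined as a weighted average
(equal weights here), which preserves row-stochasticity.
"""

import numpy as np

from markovcea import ProfilePartition, StateSpace, TransitionMatrix, aggregate_profiles

fine = TransitionMatrix(
    StateSpace(("p1", "p2", "p3"), frozenset()),
    np.array([[0.5, 0.3, 0.2],
              [0.1, 0.6, 0.3],
              [0.3, 0.3, 0.4]]),
)
part = ProfilePartition(("p1", "p2", "p3"), {"p1": "X", "p2": "Y", "p3": "Y"})
coarse = aggregate_profiles(fine, part)
print(coarse.to_frame().to_string())
# Row X keeps p1's destinations summed into {X}=p1 and {Y}=p2+p3;
# row Y averages p2's and p3's collapsed rows. Each row still sums to 1.
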