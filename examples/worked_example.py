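"""Score one agency of a tiny 4-agency network from all four perspectives.

Agency A's four rating vectors are: self-perceived (1,1,1) and self-expected
(1,2,3) down its column, group-perceived (2,3,4) and group-expected (1,1,1)
along its row.  The script prints A's P1-P4 integration scores.
"""

import numpy as np

from netagree import PERSPECTIVES, RatingMatrixPair, agency_scores

n = 4
perceived = np.full((n, n), np.nan)
expected = np.full((n, n), np.nan)
perceived[1:, 0] = [1, 1, 1]   # A's self-perceived ratings of B, C, D
expected[1:, 0] = [1, 2, 3]    # A's self-expected ratings
perceived[0, 1:] = [2, 3, 4]   # B, C, D's perceived involvement with A
expected[0, 1:] = [1, 1, 1]    # ... and what they expect of A
for i in range(1, n):          # B/C/D dyads: constant filler, not used by A
    for j in range(1, n):
        if i != j:
            perceived[i, j] = expected[i, j] = 3

pair = RatingMatrixPair(["A", "B", "C", "D"], perceived, expected)
scores = agency_scores(pair, "A")

print("Agency A integration scores (agreed/valid -> %):")
for p in PERSPECTIVES:
    s = scores.get(p)
    print(f"  {p}: {s.agreed}/{s.valid} -> {100 * s.score:5.1f}%")
print(
    "\nP2 = 100% means A's own perception of its involvement matches what\n"
    "every other agency expects of it, while P1 = 0% shows the group's\n"
    "perception never matches the group's expectation - a perception gap."
)
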