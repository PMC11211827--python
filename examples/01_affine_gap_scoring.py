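"""Scoring the indel difference between two gap patterns.

Takes an ancestor/descendant pair of binary gap patterns (1 = residue,
0 = gap), computes the site-difference vector d, the gap-opening vector
g of the affine penalty, and the implied number of indel events.
"""

import numpy as np

import indelopt as idl

ancestor = np.array([1, 0, 0, 1, 1], dtype=np.uint8)  # 10011
child = np.array([0, 0, 1, 0, 1], dtype=np.uint8)     # 00101

d, g = idl.affine_gap_vectors(ancestor, child)
_, g_no_reversal = idl.affine_gap_vectors(ancestor, child, include_reversal=False)

print("ancestor          :", "".join(map(str, ancestor)))
print("child             :", "".join(map(str, child)))
print("differences d     :", "".join(map(str, d)))
print("openings g (basic):", "".join(map(str, g_no_reversal)))
print("openings g (full) :", "".join(map(str, g)))
print("branch cost at alpha=2:", int(d.sum() + 2 * g.sum()))
print("indel events on branch:", idl.branch_indel_events(ancestor, child))

# d marks the three sites where the patterns disagree.  The basic rule
# opens an event where a run of differences starts (sites 1 and 3); the
# full rule also charges site 4, where an insertion in the child abuts a
# deletion — two distinct indel events, so g = 10110 and the branch
# costs 3 + 2*3 = 9.
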