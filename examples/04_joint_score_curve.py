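"""The signed joint score S and its range.

Evaluates S(WT, MT) on example pairs and on a dense grid to show the
design of the score: antisymmetric, zero when nothing changes, and
saturating towards (but never reaching) -1 and +1.
"""

import numpy as np

from varbind.scan import joint_score

pairs = [(0.7, 0.7), (0.9, 0.6), (0.6, 0.9), (1.0, 0.0), (0.0, 1.0)]
print(f"{'WT':>5} {'MT':>5} {'S':>12}")
for wt, mt in pairs:
    print(f"{wt:>5.2f} {mt:>5.2f} {joint_score(wt, mt):>12.6f}")

grid = np.linspace(0, 1, 1001)
wt, mt = np.meshgrid(grid, grid, indexing="ij")
s = joint_score(wt, mt)
print(f"\ngrid of {s.size} (WT, MT) pairs:"
      f"  min S = {s.min():.9f}, max S = {s.max():.9f}")
print("The extremes stay strictly inside (-1, 1): the pseudocount "
      "alpha = 0.1 caps |F| at 1/alpha = 10, so |S| <= 2/(1+2^-20) - 1.")
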