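"""Tree statistics and topology distances used to summarise posteriors.

Computes tree length, height, treeness (internal-branch fraction) and
the Pybus–Harvey gamma statistic for a simulated ultrametric tree, and
exact rooted SPR distances to edited copies of it.
"""

import numpy as np

from errophylo import (gamma_statistic, parse_newick, simulate_yule,
                       spr_distance, tree_height, tree_length, treeness)
from errophylo.spr import apply_random_spr

rng = np.random.default_rng(3)
tree = simulate_yule(m=20, birthrate=5.0, rng=rng)

print(f"tree length : {tree_length(tree):.4f}  (sum of branch lengths)")
print(f"tree height : {tree_height(tree):.4f}  (root to tips)")
print(f"treeness    : {treeness(tree):.4f}  (internal / total length)")
print(f"gamma       : {gamma_statistic(tree):+.4f}  "
      "(~N(0,1) under constant-rate pure birth)")

print("\nrooted SPR distances after k random prune-regraft edits:")
edited = tree
for k in range(1, 5):
    edited = apply_random_spr(edited, rng)
    d = spr_distance(tree, edited)
    print(f"  {k} edits -> distance {d} (<= {k}: edits can cancel)")

small = parse_newick("((a:1,b:1):2,c:3);")
print(f"\nworked example ((a:1,b:1):2,c:3): length {tree_length(small):g}, "
      f"height {tree_height(small):g}, treeness {treeness(small):.4f} (=2/7)")
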