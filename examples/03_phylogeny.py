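"""From a Newick string to the Brownian species correlation matrix.

Supertrees built from taxonomy have no usable branch lengths: set them to
one, apply Grafen's ultrametrization (node height proportional to descendant
tip count, depth scaled to 1), and read off the Brownian correlation —
shared root-to-ancestor path length divided by tree depth.
"""

import ornameta as om

tree = om.read_newick("(((heron,egret),stork),(gull,tern));")
tree = om.grafen_transform(om.set_unit_branch_lengths(tree))
print(f"tree depth after Grafen transform: {om.tree_depth(tree):.6f}")

A = om.brownian_correlation(tree)
print("\nBrownian correlation matrix:")
print(A.to_frame().round(3).to_string())

pruned = om.prune(tree, ["heron", "egret", "gull"])
print("\npruned to three species (entries unchanged):")
print(om.brownian_correlation(pruned).to_frame().round(3).to_string())
# Sister species (heron, egret) share almost their whole root-to-tip path, so
# they correlate strongly; the two families correlate 0.
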