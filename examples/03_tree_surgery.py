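"""Tree editing: reroot, prune, collapse and rotate by leaf-name selector.

Every operation addresses its node as a *set of leaf names* resolved to
their last common ancestor — the same portable selectors used inside
saved pipeline documents.
"""

from phylopipe import (collapse, parse_newick, prune, reroot_on_branch,
                       rotate, traverse, write_newick)
from phylopipe.layout import visible_terminals


def total_length(tree):
    return sum(n.length or 0 for n in traverse(tree, "preorder"))


tree = parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);").trees[0]
print("original:   ", write_newick(tree))

rerooted = reroot_on_branch(tree, {"D", "E"}, fraction=0.5)
print("rerooted:   ", write_newick(rerooted))
print("            total branch length conserved:",
      round(total_length(tree), 9) == round(total_length(rerooted), 9))

pruned = prune(tree, {"C"})
print("pruned C:   ", write_newick(pruned),
      "(degree-2 node suppressed, lengths merged)")

collapsed = collapse(tree, {"A", "B", "C"}, True)
print("collapsed:  ", [t.name or "<clade>"
                       for t in visible_terminals(collapsed)],
      "- the clade now occupies one terminal slot")

rotated = rotate(tree, {"A", "B", "C", "D", "E"})
print("rotated:    ", write_newick(rotated))
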