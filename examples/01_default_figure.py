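"""Open a posterior tree sample and render the default figure.

A file with many trees is automatically summarised with a greedy
consensus; the default plot is a rectangular tree with branches, taxon
names at the tips, and branch lengths over the branches.
"""

from phylopipe import (SynthOptions, build_default_pipeline,
                       posterior_sample, run_pipeline, yule_tree)

# Emulate a small Bayesian clock posterior: 100 trees over 10 taxa.
options = SynthOptions(n_leaves=10, n_trees=100, seed=1)
collection = posterior_sample(yule_tree(options), options)

pipeline = build_default_pipeline(collection)
print("transformer:", pipeline.transformer.module_id,
      pipeline.transformer.parameters)
print("plot actions:", [s.module_id for s in pipeline.plot_actions])

result = run_pipeline(collection, pipeline)
with open("default_figure.svg", "w") as handle:
    handle.write(result.svg)
print(f"wrote default_figure.svg ({len(result.svg)} bytes)")

# Support values on the consensus: the fraction of posterior trees
# containing each clade (1.0 = present in every tree).
from phylopipe import traverse
supports = sorted(
    node.attributes["Support"]
    for node in traverse(result.final_tree, "preorder")
    if node.children)
print("clade supports:", [round(s, 3) for s in supports])
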