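"""Save a figure recipe and re-apply it to a different tree file.

Pipelines serialize to a small JSON document (optionally embedded in a
NEXUS comment block that other NEXUS readers ignore). Node selectors
are leaf-name sets, so a recipe survives being applied to a file with
different topology — and selectors that cannot resolve simply skip
their stage with a warning.
"""

from phylopipe import (StageDescriptor, apply_to_other_tree,
                       build_default_pipeline, deserialize_pipeline,
                       parse_newick, read_nexus_pipeline,
                       serialize_pipeline, write_nexus)

origin = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
pipeline = build_default_pipeline(origin)
pipeline.further.append(StageDescriptor(
    "further_transformation", "collapse", {"selector": ["C", "D"]}))

document = serialize_pipeline(pipeline)
print("pipeline document:", len(document), "bytes of JSON")

# Embed the recipe in a NEXUS file next to the trees themselves.
nexus_text = write_nexus(origin, pipeline_json=document)
recovered = read_nexus_pipeline(nexus_text)
print("embedded block recovered byte-exactly:", recovered == document)
reloaded = deserialize_pipeline(recovered)

# Apply to another tree that lacks taxon D: the collapse stage skips.
other = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
result = apply_to_other_tree(reloaded, other)
print("applied to other tree; warnings:", result.warnings)
print("figure still rendered:", result.svg.startswith("<?xml"))
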