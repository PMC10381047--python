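"""Export a model as Graphviz DOT and as a LaTeX methods document."""

import pylphy

ast = pylphy.parse_script(pylphy.example_source("example1.lphy"))
model = pylphy.build_graph(ast, pylphy.default_registry())

print("--- DOT (constants hidden) ---")
print(pylphy.export_dot(model, hide_constants=True))
print("--- narrative (markdown) ---")
print(pylphy.generate_narrative(model))
# export_latex(model) wraps the same narrative in a compilable LaTeX
# document with a bibliography of the cited references.
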