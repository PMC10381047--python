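"""Simulate the coalescent + Jukes-Cantor model end to end.

Parses the bundled 10-taxon script, samples every node of the graphical
model, and reports the dimensions of the simulated alignment and the
population-size draw that generated the tree.
"""

import pylphy

model, values = pylphy.run_script(pylphy.example_source("example1.lphy"), seed=1)

print("node kinds:", {n.name: n.kind for n in model.order})
print(f"sampled population size Θ = {values['Θ']:.3f}")
print(f"tree root age            = {values['ψ'].root_age:.3f}")
print(f"alignment                = {values['D'].n_taxa} taxa x {values['D'].L} sites")
# Θ is the coalescent population size; the alignment is 10 x 200 because the
# script declares taxa = 1:10 and L = 200.
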