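"""Data clamping: condition the model on an observed dated alignment.

Generates the synthetic stand-in for a serially sampled virus data set
(129 dated taxa, codon structure), then runs the phylodynamic script whose
data block reads the NEXUS file, splits it into codon partitions, and
clamps the model-block 'codon' node to the observed partitions.
"""

import os
import tempfile

import pylphy

workdir = tempfile.mkdtemp()
os.chdir(workdir)
pylphy.synthdata.write_rsva_like_nexus("rsva_synthetic.nex")

model, values = pylphy.run_script(pylphy.example_source("example2.lphy"), seed=7)

codon = values["codon"]
print("codon node observed:", model.nodes["codon"].observed)
print("partitions         :", [f"{p.n_taxa} x {p.L}" for p in codon])
print("oldest tip age     :", values["ψ"].oldest_tip_age(), "years before youngest sample")
print(f"sampled clock rate μ = {values['μ']:.2e} subst/site/year")
# The three partitions hold codon positions 1-3; because 'codon' is clamped,
# its value is the observed data, not a fresh simulation, while the tree and
# the parameters above it are still drawn from their priors.
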