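"""The two vectorization mechanisms: replicates and implicit broadcasting.

'replicates=3' stacks IID draws on a new major dimension; passing those
vectors into the scalar-argument hky function broadcasts it element-wise,
yielding a vector of three rate matrices.
"""

import pylphy

model, values = pylphy.run_script(pylphy.example_source("vectorization.lphy"), seed=2)

print("κ (3 IID log-normal draws):", values["κ"].round(3))
print("π shape (major, minor)    :", values["π"].shape)
for i, Q in enumerate(values["Q"]):
    print(f"Q[{i}]: {Q.n_states}x{Q.n_states} rate matrix, "
          f"expected rate {Q.expected_rate():.3f}")
# Each Q is normalized to one expected substitution per site per unit time.
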