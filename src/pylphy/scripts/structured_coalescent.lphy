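// Two-deme structured coalescent: the migration matrix stores population
// sizes on the diagonal and migration rates off the diagonal.
M = migrationMatrix(theta=[0.1, 0.1], m=[1.0, 1.0]);
taxa = taxa(names=["a1", "a2", "b1", "b2"], demes=["A", "A", "B", "B"]);
g ~ StructuredCoalescent(M=M, taxa=taxa);
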