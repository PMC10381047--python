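// Serially sampled constant-population-size coalescent: four taxa
// sampled at ages 0.0, 1.0, 2.0 and 3.0 (0.0 = the present).
taxa = taxa(names=["a", "b", "c", "d"], ages=[0.0, 1.0, 2.0, 3.0]);
ψ ~ Coalescent(theta=0.1, taxa=taxa);
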