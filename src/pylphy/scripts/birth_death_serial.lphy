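// Serially sampled birth-death process: psi and rho are the rates of
// sampling extinct and extant lineages, respectively.
ψ ~ BirthDeathSerialSampling(lambda=2.0, mu=1.0, rho=0.5, psi=0.3, rootAge=3.0);
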