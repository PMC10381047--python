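// HKY substitution model under a strict molecular clock (mu = 0.2).
taxa = 1:10;
ψ ~ Coalescent(theta=0.5, taxa=taxa);
Q = hky(kappa=2.0, freq=[0.25, 0.25, 0.25, 0.25]);
D ~ PhyloCTMC(tree=ψ, Q=Q, L=200, mu=0.2);
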