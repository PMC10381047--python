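// Uncorrelated log-normal relaxed clock: 30 rates drawn independently,
// one per branch of the 16-taxon tree ψ (2n - 2 = 30 branches).
taxa = 1:16;
ψ ~ Coalescent(theta=0.5, taxa=taxa);
branchRates ~ LogNormal(meanlog=-0.25, sdlog=0.5, replicates=30);
D ~ PhyloCTMC(tree=ψ, Q=jukesCantor(), L=200, branchRates=branchRates);
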