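// Phylodynamic analysis of a serially sampled virus alignment:
// three codon-position partitions, HKY substitution model, coalescent
// tree prior, strict clock with a log-normal prior on the clock rate.
// The observed partitioned alignment clamps the model-block 'codon' node.
data {
  D = readNexus(file="rsva_synthetic.nex");
  taxa = D.taxa();
  codon = D.codonPartitions();
  L = codon.nchar();
}
model {
  κ ~ LogNormal(meanlog=1.0, sdlog=0.5);
  π ~ Dirichlet(conc=[2.0, 2.0, 2.0, 2.0]);
  Q = hky(kappa=κ, freq=π);
  μ ~ LogNormal(meanlog=-5.0, sdlog=1.25);
  Θ ~ LogNormal(meanlog=3.0, sdlog=2.0);
  ψ ~ Coalescent(theta=Θ, taxa=taxa);
  codon ~ PhyloCTMC(tree=ψ, Q=Q, L=L, mu=μ);
}
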