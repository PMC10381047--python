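// GT16 substitution model and GT16 error model for diploid single-cell
// nucleotide data: 16 sequences, 200 sites, sequencing/amplification
// error epsilon and allelic dropout delta.
data {
  L = 200;
  n = 16;
}
model {
  π ~ Dirichlet(conc=[3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0]);
  rates ~ Dirichlet(conc=[1.0, 2.0, 1.0, 1.0, 2.0, 1.0]);
  Q = gt16(rates=rates, freq=π);
  Θ ~ LogNormal(meanlog=-2.0, sdlog=1.0);
  ψ ~ Coalescent(theta=Θ, n=n);
  A ~ PhyloCTMC(tree=ψ, Q=Q, L=L, dataType=phasedGenotype());
  delta ~ Beta(alpha=1.5, beta=4.5);
  epsilon ~ Beta(alpha=2, beta=18);
  E ~ ErrorModel(alignment=A, epsilon=epsilon, delta=delta);
}
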