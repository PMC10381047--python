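// Constant-size coalescent tree prior, strict clock, Jukes-Cantor model
// on 10 nucleotide sequences with 200 sites.
data {
  L = 200;
  taxa = 1:10;
}
model {
  Θ ~ LogNormal(meanlog=3.0, sdlog=1.0);
  ψ ~ Coalescent(theta=Θ, taxa=taxa);
  Q = jukesCantor();
  D ~ PhyloCTMC(tree=ψ, Q=Q, L=L);
}
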