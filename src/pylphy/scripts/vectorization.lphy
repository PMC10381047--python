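// Vectorization: 'replicates' draws IID vectors; passing those vectors to
// hky broadcasts the function, producing three rate matrices in Q.
κ ~ LogNormal(meanlog=1.0, sdlog=0.5, replicates=3);
π ~ Dirichlet(conc=[2.0, 2.0, 2.0, 2.0], replicates=3);
Q = hky(kappa=κ, freq=π);
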