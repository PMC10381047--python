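// Skyline coalescent with 10 coalescent intervals (11 taxa) and four
// distinct population sizes: the first four intervals use theta 0.1,
// the next three 0.2, and so on.
taxa = 1:11;
theta = [0.1, 0.2, 0.3, 0.4];
g ~ SkylineCoalescent(theta=theta, groupSizes=[4, 3, 2, 1], taxa=taxa);
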