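// An extinction rate drawn from a log-normal distribution with mean -5
// and standard deviation 1.25 in log space.
μ ~ LogNormal(meanlog=-5.0, sdlog=1.25);
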