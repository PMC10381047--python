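// Reconstructed birth-death tree conditioned on 10 extant tips.
ψ ~ BirthDeath(lambda=2.0, mu=1.0, n=10);
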