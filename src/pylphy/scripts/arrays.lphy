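// Array notation: explicit ranges of consecutive integers.
c = 1:5;
d = 2:10;
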