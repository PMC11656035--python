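# Per-locus coverage levels that differ from the 0.95 default.
2q21.3: 0.6
9q32: 0.7
11q24.3: 0.7
11p15.5: 0.7
14q13.2: 0.8
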