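spiked_mg_per_l,recovery_percent
1000,99
1500,104
1750,115
2000,108
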