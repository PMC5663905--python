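>trLAT truncated LAT construct, wild type
MEEAILVPCVLGLLLLPILAMLMALCVHCHRLPGS
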