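# trLAT fixture annotation. The TMD span 5..27 is a repository convention
# covering the hydrophobic stretch of the construct (the exact span used by
# the original annotation pipeline is not published); it places the two
# palmitoylated cysteines at the cytoplasmic end of / just past the TMD.
id	tmd_start	tmd_end	orientation	compartment
trLAT	5	27	exo_to_cyto	PM
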