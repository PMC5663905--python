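# Default physical parameters for the tripartite raft-partitioning model.
#
#   dG_pred = gamma_conv * ASA + n_palm * dG_palm - 2 * B_LP * (d_TMD - (d_Lo + d_Ld)/2)
#
# delta_gamma: differential interfacial tension felt by a TMD solvated by the
#   liquid-ordered (raft) versus liquid-disordered membrane phase, pN/nm.
#   Experimental estimate from the slope of dG_app versus side-chain ASA for
#   Ala/Leu compositional TMD series.
delta_gamma = 1.1

# dG_palm: free-energy gain per palmitoylated cysteine, kcal/mol.
dG_palm = -0.48

# ----------------------------------------------------------------------------
# PLACEHOLDER mismatch parameters. The mattress-model constant B_LP and the
# hydrophobic thicknesses of the two phases are not pinned by a published
# value in this package's sources; the values below are plausible defaults
# chosen from liquid-ordered / liquid-disordered bilayer literature and from
# the requirement that a 6-residue truncation of a hydrophobic TMD raises
# dG_pred (mismatch penalty exceeding the accompanying ASA loss). Loading
# this file emits a warning; supply your own calibrated values for
# quantitative work.
# ----------------------------------------------------------------------------
# B_LP: hydrophobic mismatch (mattress-model) parameter, kcal/(mol*nm).
B_LP = 1.5
# d_lo: hydrophobic thickness of the liquid-ordered (raft) phase, nm.
d_lo = 3.0
# d_ld: hydrophobic thickness of the liquid-disordered phase, nm.
d_ld = 2.4

# temperature: K. Partitioning measurements are imaged at 10 C, hence 283.15.
temperature = 283.15

# dG_ex: constant offset of the single-term ASA model (Eq-1 mode only),
# kcal/mol. Not used by the tripartite prediction.
dG_ex = 0.0
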