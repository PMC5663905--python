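# Methods

## The model

A single-pass protein equilibrating between the liquid-ordered (raft, L_o)
and liquid-disordered (L_d) phase of a membrane has apparent partitioning
free energy ΔG = −RT ln K_p, with K_p the ordered/disordered concentration
ratio and negative ΔG meaning raft-preferring. `raftpart` predicts ΔG from
sequence as a sum of three independent terms:

ΔG_pred = Δγ·ASA_TMD + n_palm·ΔG_palm − 2·B_LP·(d_TMD − (d_Lo + d_Ld)/2)

Assumptions worth stating explicitly:

* **Additivity and compositionality.** Each term depends only on aggregate
  TMD properties — residue composition (ASA), length, and a cysteine count —
  never on residue order. Scrambling a TMD therefore leaves the prediction
  unchanged, which matches the experimental observation motivating the
  model but means sequence-specific effects (Pro/Gly kinks, interaction
  motifs) are invisible to it.
* **Single-pass only.** Nothing here generalizes to multi-span proteins;
  the pipeline scores exactly one annotated span per record.
* **No oligomerization or extramembrane terms.**

## Parameters

| parameter | units | default | origin |
|---|---|---|---|
| Δγ (`delta_gamma`) | pN/nm | 1.1 | slope of measured ΔG vs ASA for Ala/Leu compositional TMD series |
| ΔG_palm (`dG_palm`) | kcal/mol per site | −0.48 | partitioning shift per palmitoylation measured on isolated plasma membranes |
| B_LP | kcal/(mol·nm) | 1.5 (placeholder) | see below |
| d_Lo / d_Ld | nm | 3.0 / 2.4 (placeholder) | see below |
| temperature | K | 283.15 | partitioning is imaged at 10 °C; used for K_p ↔ ΔG |
| helix rise | Å/residue | 1.5 | canonical α-helix; converts residue count to d_TMD |
| ΔG_ex | kcal/mol | 0.0 | constant offset of the single-term area model only |

**Mismatch placeholders.** No published calibration of B_LP, d_Lo, d_Ld is
available to this package, so hardcoding defaults would invent physics;
they live in the shipped config file (`default_params.cfg`), and loading it
warns. The placeholder thicknesses are typical hydrophobic thicknesses of
ordered versus disordered bilayers; the placeholder B_LP = 1.5 kcal/(mol·nm)
is chosen so that the empirically established direction — truncating a
hydrophobic TMD by six residues *reduces* raft affinity — holds in the full
model: the truncation removes ≈ 1.1–1.3 kcal/mol of ASA penalty, so the
mismatch gain 2·B_LP·0.9 nm must exceed that, i.e. B_LP ≳ 0.75. Quantitative
work should supply measured values via `--params-file`.

**Temperature handling.** kT-based tension units always require an explicit
temperature (the literature comparison value 0.15 kT/nm² ↔ 0.6 pN/nm is
reproduced at 298 K); K_p conversions default to the 283.15 K measurement
temperature. Both are visible config fields, never silent constants.

## Residue scales

ASA summation uses side-chain-only accessible surface areas from the
classical Gly-X-Gly tripeptide reference state (Å²; Gly = 0), shipped as a
commented TSV and pluggable via `ResidueScale.from_tsv`. Any complete
20-residue table can be substituted without code changes; absolute ASA
totals (and hence absolute ΔG) shift with the table, while differences and
rank orders between compositionally related constructs are stable.
Hydropathy uses the standard Kyte-Doolittle index.

The annotated span is scored exactly; flanking residues beyond the span are
excluded from ASA and length.

## Palmitoylation counting

n_palm is the number of Cys in a 15-residue window anchored on the
cytoplasmic terminus of the TMD: 7 residues into the TMD (including the
terminal residue) and the remainder into the juxtamembrane sequence, with
the in-TMD reach never crossing to the exoplasmic half and the window
clamped (logged, not an error) at the sequence terminus. Orientation
resolves which TMD end is cytoplasmic; exoplasmic cysteines are never
counted. A per-record override and a pluggable predictor callable allow
injecting external palmitoylation calls. The window split is a convention:
the source description ("the cytoplasmic end of the TMD and the
membrane-proximal cytoplasmic domain, 15 residues") fixes the total width
but not the exact anchoring; the symmetric split reproduces the known
two-site count for LAT, whose palmitoylated cysteines straddle the TMD
boundary.

## Estimators

* **Δγ fit** — ordinary least squares of measured ΔG on computed ASA
  (`scipy.stats.linregress`), ASA treated as exact and replicates
  unweighted (orthogonal regression would be the alternative if ASA were
  noisy). The slope is converted to pN/nm by the exact factor
  1 pN/nm = 1.4393e-3 kcal/(mol·Å²). Two distinct points return the exact
  interpolating line with no p-value; p and slope SE are otherwise from the
  t distribution.
* **Gaussian mixture** — a small univariate EM written in-package so that
  the per-iteration log-likelihood trajectory is exposed (it is
  non-decreasing by construction and asserted in tests) and initialization
  is strictly seeded: means drawn from the data without replacement,
  uniform weights, pooled SD, variances floored at 1e-6 of the data range
  to prevent component collapse. Components are reported sorted by mean;
  non-convergence after 500 iterations returns the best-so-far fit flagged.
  k is user-specified — no information criterion is applied silently.
* **Compartment comparison** — per-group n/mean/SD and one-way ANOVA
  (`scipy.stats.f_oneway`) for predicted ΔG, ASA, TMD length and n_palm;
  ER and Golgi are pooled into one intracellular comparator by default.
  No outlier handling unless an explicit |ΔG| bound is passed (logged).

## Synthetic data

The generator module emulates the construct families used to dissect the
model, embedded in the trLAT juxtamembrane context (`MEEA` N-flank,
`HCHRLPGS` cytoplasmic flank, whose Cys sits inside the counting window; a
Cys-free variant flank is used for unpalmitoylated populations):

* Ala/Leu compositional series of fixed length and seeded-random Leu
  placement (placement is irrelevant to the model — which is the point the
  scrambles established);
* core scrambles, truncations from either TMD end;
* simulated measurements ΔG_app = ΔG_pred + N(0, σ²), default
  σ = 0.1 kcal/mol, emulating inter-preparation scatter;
* compartment-typical populations: PM-like (length 24 ± 1.5 residues, Leu
  fraction 0.25, palmitoylatable flank) versus ER/Golgi-like
  (20–20.5 ± 1.5, Leu fraction 0.65–0.70, Cys-free flank), so that all
  three feature contrasts run in the directions observed proteome-wide.

What passing tests on these data do **not** show: real measurement noise is
not Gaussian-homoscedastic, real TMD annotations carry boundary
uncertainty, real proteomes have correlated features and non-Ala/Leu
chemistry, and real palmitoylation is enzyme-dependent rather than a pure
Cys count. The synthetic results validate the machinery (recovery,
direction, accounting), not the biology.

## Problem sizes and numerics

The slope-recovery study uses 200 replicates of the 12-construct series;
the compartment contrast uses 200 records per group — both chosen as the
smallest sizes at which the statistical claims are comfortably stable under
reseeding. Tie-breaks: the fallback hydropathy TMD caller (a rough
annotation stand-in, not a topology predictor) takes the most N-terminal of
equally long qualifying runs; mixture components are ordered by mean.
Degenerate inputs fail loudly: zero ASA variance, K_p ≤ 0, windows narrower
than 5, reversed TMD spans and ambiguity codes are all errors rather than
silently scored.

## Known limitations

Absolute ΔG values are only as good as the ASA table and the placeholder
mismatch parameters; the package's well-constrained outputs are
differences, directions and ranks. The Cys-count palmitoylation rule
ignores sequence context scoring. The fallback TMD caller is a single
hydropathy window with a fixed threshold and should not replace curated
annotations.
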