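# Methods

## Setting

The package models a study design in which a small cohort of tumors (default
13) is profiled on a targeted DNA panel (136 genes, ~2998 probes) and the
matched patient-derived cultures are screened once, at a single 1 uM dose,
against a 418-compound kinase-inhibitor library. The scientific question is
whether a gene's copy number predicts cytotoxicity of particular compounds —
a copy-number analogue of mutation-based pharmacogenomics, relevant to tumors
such as high-risk neuroblastoma where point mutations are sparse (~3 per
case) but segmental chromosomal aberrations (SCAs) are near-universal.

## Synthetic cohort generator

No cohort of this kind is publicly deposited, so all calibration runs on
synthetic cohorts whose generative structure mirrors the assumed data:

- **Copy number.** Every gene starts diploid. Arm-level events are
  all-or-none per (sample, arm): 1p loss with probability 0.31, 11q loss
  0.38, 17q gain 0.69 — the frequencies characteristic of the emulated
  cohort. An event shifts every gene on the arm by +/-1 copy (floored at 0).
  A focal amplification (23% of samples) overrides the target gene (*MYCN*)
  with a uniform draw from 10-40 copies. Five designated quiet genes (FASLG,
  NF2, NRAS, SETBP1, SMARCB1) never change copy number; dropping them gives
  the 131-gene analysis panel. Probe log2 ratios are
  `log2(copies/2) + N(0, 0.1)`; 0.1 log2 units is a typical targeted-panel
  probe dispersion, and with ~22 probes per gene the gene-level noise is
  ~0.02 — small against the 0.58 log2 shift of a single-copy gain.
- **Drug response.** Latent cytotoxicity of drug d in sample s is
  `baseline(d) + sum_planted slope * (copies(g,s) - 2) + N(0, 5)`, clipped to
  [-20, 100] (mild growth stimulation is allowed; complete kill caps at
  100%). Baselines are `N(15, 18)` percent: under the normal model this puts
  ~80% of compounds above zero and ~16% above the 33% hit threshold, matching
  the screen-wide activity profile the design assumes. Plates carry
  triplicate compound wells, 8 DMSO wells at full signal and 4 staurosporine
  wells at 4.3% residual viability (=> 95.7% kill), all with 2% multiplicative
  well noise; RLU = `scale * (1 - cyto/100)`.
- **Variants.** Per sample, Poisson(3.1) candidate records over the panel,
  with configurable fractions failing each downstream filter and a 27/71
  population-SNP rate, so the filter logic is always exercised.
- **Determinism.** One root seed; each component (CNV, response, variants,
  FI network, permutations, planting) draws from a fixed labeled child
  stream, so outputs are byte-identical across runs and enlarging one
  component never perturbs another.

Planted gene-drug effects are specified either directly (gene, drug, slope)
or via a target population correlation: for a gene on an arm with event rate
p, sd(copies) = sqrt(p(1-p)), so
`slope = sigma_resp * (r / sqrt(1-r^2)) / sd(copies)` yields population
correlation r between copies and latent response.

What the generator does **not** emulate: sub-arm breakpoints, clonal
heterogeneity, plate-position effects, dose-response curves, and any
mutation-cytotoxicity coupling. Passing tests therefore demonstrate the
statistical machinery under idealized SCA structure, not performance on real
screens.

## Association screen

All gene x drug pairs are tested on pairwise-complete samples (>= 5 required).
Pairs with a constant copy-number or response vector are *undefined*: they are
reported but excluded from the multiplicity count m, never assigned p = 1 —
this is also what shrinks the 136-gene panel to 131 testable genes. The table
records r, Fisher's `z = atanh(r)` (clamped at |r| = 1 - 1e-7 with a flag) and
`z_std = z * sqrt(n-3)`.

**Choice of null test.** The classical large-sample recipe refers `z_std` to
N(0, 1). At n = 13 that normal tail is anticonservative precisely where a
55,000-test BH procedure operates: at p ~ 1e-3 the true null exceedance
probability is ~1.7x the nominal one, which in simulation inflates the
realized false-discovery rate of the q = 0.1 screen to ~0.16. The screen
therefore defaults to the exact Pearson null, `t = r * sqrt(n-2) /
sqrt(1-r^2)` on n-2 df (the same test `scipy.stats.pearsonr` uses), whose
null p-values are uniform at any n; the normal-z convention remains available
as `ScreenConfig(test="normal")` for comparison. This tail behaviour is worth
keeping in mind when interpreting published small-cohort screens that combine
the Fisher transform with aggressive multiplicity corrections.

BH adjustment uses the classic step-up (via statsmodels), significance is
`q <= 0.1` inclusive. Significant pairs are cross-classified against the drug
library's annotated targets (TP/FP/FN/TN always partition the enumerated
universe), and ranked by the signed product `mean cytotoxicity x z`, so
strong negative associations sink to the bottom rather than mixing with the
top.

**False-discovery accounting.** Because arm events are all-or-none, every
non-quiet gene on a planted gene's arm carries *identical* copy-number
variation, hence the same nonzero population correlation with the planted
drug. The calibration experiments count a discovery as false only when its
population correlation is zero (`population_nonnull_pairs`); measuring FDP
against the planted list alone would misclassify genuinely correlated
arm-mates as errors. Under these conditions 20 seeded cohorts give mean FDP
~= 0.098 (SE 0.013) at q = 0.1 with sensitivity ~0.93 — computed, not
asserted, by `analysis/06_fdr_calibration.py` and `scripts/acceptance.py`.

## Drug-screen normalization and QC

The DMSO summary is the median (robust to a single bad vehicle well);
replicate compound wells are averaged at the RLU level before normalizing.
The QC rule — staurosporine cytotoxicity >= 80% and DMSO CV <= 0.2 — is a
declared numeric stand-in for the qualitative "high positive-control kill,
minimal vehicle effect" criterion; both cut-offs are configurable. Failed
plates propagate as missing columns and drop out of correlations pairwise.
Hits are strict: mean cytotoxicity > 33%.

## Pathway model

The functional-interaction (FI) MRF is deliberately the simplest model with
the stated ingredients — continuous CNV observations via empirical
distributions, pairwise potentials on FI edges, permutation null, +/-0.01
selection band:

- Hidden activity `a_g` per gene, standard-normal prior.
- Observation for (gene, sample): the rank-based normal score
  `Phi^-1((rank - 0.5)/n)` of the sample's CNV within the gene's row — the
  "empirical distribution" link; ties get average ranks, so a no-CNV gene
  contributes zero evidence. Observation precision tau = 1.
- Edge potential `-(c/2) (a_g - a_h)^2` with `c = fi_weight x
  coupling_scale` (default 1). The joint is Gaussian with precision
  `J = I + tau * diag(obs) + coupling Laplacian`; J is positive definite, so
  the posterior mean is one Cholesky solve, exact on any topology and
  deterministic.
- Per-(gene, sample) impact = posterior mean of `a_g` (signed, odd in the
  observations, zero when evidence is zero).
- Permutation null: each replicate shuffles sample labels independently
  within every gene's row (preserving each gene's marginal, destroying
  gene-gene alignment), re-infers, and accumulates |impact|; default 100
  replicates.
- Selection: mean |impact| over real samples minus its permutation mean,
  strictly outside [-0.01, +0.01]; no-CNV genes are removed first.

Two aggregation choices deserve explanation. First, the real-vs-permuted
contrast uses the mean *magnitude* of the per-sample impacts: rank-normal
scores sum to ~0 across samples within each gene, so the signed mean is ~0
for real and permuted data alike and would make any threshold vacuous; the
magnitude contrast measures exactly what the permutation destroys —
coordinated CNV among FI neighbors. Second, the +/-0.01 band should be read
as a screening device, not a calibrated test: the real side is a mean over
only 13 samples, whose sampling noise (~0.05-0.1 in score units) exceeds the
band, so on a fully null profile many genes still land outside it. What the
contrast does deliver — and what the tests measure — is (a) null diffs
centered at zero, and (b) near-certain selection of genes on a
high-frequency co-gained arm (the 69% 17q gain is selected in 100% of seeded
replicates), because aligned neighbors reinforce each other under the real
labels and cancel under permutation.

The bundled FI network is a stochastic block model over the panel with
chromosome arms as blocks (within-arm edge probability 0.4, between 0.02,
weights U(0.5, 1)) — a stand-in for a curated pathway network that preserves
the property the model exploits, local neighborhoods of functionally (here:
positionally) coherent genes. A loader for user-supplied edge lists is
provided. Module detection is deterministic greedy modularity; module ids are
ordered by size then anchor gene, and optional hypergeometric enrichment
against user gene sets is BH-corrected.

## Numerical and I/O choices

- All tables are TSV with headers; missing values are empty fields. Floats
  are parsed with round-trip precision so write->read is lossless and
  repeated runs produce byte-identical manifests.
- Variants serialize as minimal VCFv4.2 (INFO: SM, GENE, DP, AF, COSMIC,
  POPFREQ, PSNP) and are read back with cyvcf2.
- Heatmap orderings use complete-linkage Euclidean agglomeration with
  scipy's deterministic tie-breaking; leaf orders and linkage matrices are
  serialized.
- Filter boundaries follow the printed inequalities: coverage strictly
  > 100, allele fraction >= 0.10 inclusive, population frequency strictly
  < 0.01; the selection band is strictly outside +/-0.01.
- The run manifest records the config snapshot, seed, SHA-256 of every
  output, and stage counts; every count is recomputable from the serialized
  stage outputs.

## Problem sizes

Default experiment sizes — 20 cohorts for FDR calibration, 10 replicates x
100 permutations for arm selection, 1000 cohorts for frequency recovery at
reduced panel size — were chosen so each study resolves its target quantity
to a few percent Monte-Carlo error while the whole suite stays interactive
on a single CPU.

## Known limitations

- The MRF is a Gaussian surrogate for factor-graph pathway models
  (PARADIGM-style); it preserves the workflow (continuous observations,
  pairwise potentials, permutation contrast, +/-0.01 selection) but makes no
  claim of numerical equivalence with any specific tool.
- The +/-0.01 selection band is not a calibrated error rate at n = 13 (see
  above).
- With 13 samples the screen has essentially no power below |r| ~ 0.7; the
  calibration plants |r| ~ 0.95 deliberately, and results say nothing about
  weak-effect regimes.
- Arm-level all-or-none events make arm-mates statistically
  indistinguishable; gene-level resolution within an arm is out of reach by
  construction, for the screen and the MRF alike.
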