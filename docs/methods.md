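# Methods

## Codon substitution model

The engine implements the Goldman–Yang codon model on the 61 sense
codons of the standard genetic code.  Off-diagonal rates are

    q_ij = 0                                   if i and j differ at >1 position
    q_ij = pi_j                                synonymous transversion
    q_ij = kappa * pi_j                        synonymous transition
    q_ij = omega * pi_j                        nonsynonymous transversion
    q_ij = omega * kappa * pi_j                nonsynonymous transition

with the diagonal set so rows sum to zero and the generator rescaled so
that one unit of branch length equals one expected codon substitution
under the stationary distribution π.  Branch lengths are therefore in
codon substitutions per codon site.  The chain is reversible, so P(t)
is computed from a single symmetric eigendecomposition per distinct ω
(exact to ~1e-13 of `expm`), which makes mixture models and repeated
branch-length evaluation cheap.

Codon frequencies default to F3x4 (position-specific nucleotide
frequencies renormalized over sense codons, pseudocount 0.5 per
nucleotide per position); F61 (observed codon proportions with
pseudocount) and uniform are available.  Only unambiguously observed
codons are counted.  κ is estimated by ML and shared across branches
and site classes.

### Model families

* Branch models `1w`–`4w-activity`, `free`: one ω per branch class from
  a `BranchPartition`.  Classes with no branch on the input tree are
  dropped from the parameter vector.
* Site models: `M0`; `M1a` (p0 at ω0<1, rest neutral); `M2a` (adds
  p2 at ω2≥1); `M3` with k=3 discrete classes (so the M3-vs-M0 test has
  df 4); `M7` Beta(p,q) in 10 equal-probability categories represented
  by their medians; `M8` = M7 plus a ω_s≥1 class.  The M8
  discretization reuses M7's, so M7 is exactly nested in M8.
* Branch-site Model A: four site classes (p0: ω0 everywhere; p1:
  neutral; p2a: ω0 background / ω2 foreground; p2b: neutral background
  / ω2 foreground) with proportions tied as p2a:p2b = p0:p1.  The null
  fixes ω2=1; ω2 is then not a free parameter and is excluded from K.

### Likelihood and missing data

Felsenstein pruning over compressed column patterns with per-pattern
rescaling.  Alignment cells are sets of sense codons: IUPAC ambiguity
expands to the compatible codon set, and any codon containing a gap
character is treated as fully missing and summed over all 61 states
(columns are retained rather than deleted; a strict `cleandata` flag
drops every column containing a missing cell).  The likelihood is
invariant to the internal rooting; the canonical root is the node
adjacent to the alphabetically smallest leaf, which also fixes the
deterministic branch-id assignment (post-order of the leaf-sorted
traversal).

### Optimization

Bounded L-BFGS-B on the raw parameters (ω, κ in [1e-4, 99]-type boxes;
mixture proportions through stick-breaking coordinates in (0,1); branch
lengths in [1e-5, 20], jointly re-optimized under every model by
default).  `ftol=1e-10` on the scaled objective, up to 1000 iterations,
and `n_starts` seeded multi-starts (jitter is log-normal around the
default initial point).  The pipeline fits model chains in nesting
order and warm-starts each richer model *at* its nested predecessor's
optimum mapped into the richer coordinates (e.g. M8 starts from M7 with
a vanishing positive class at ω_s=1), which both speeds up fitting and
guarantees the nesting inequalities up to optimizer tolerance.  LRT
statistics in [-2e-4, 0) from residual optimizer noise are clamped to
zero; anything lower raises.

K, the parameter count entering BIC, is the number of quantities
actually optimized (branch lengths + κ + model parameters).

### Site posteriors

NEB plugs the MLEs into Bayes' rule per column.  BEB (for M2a and
Model A) averages the class posteriors over a coarse uniform grid on
the mixture parameters — 10 categories each for the stick-broken
proportions, ω0 on (0,1), and ω2 on (1,11) — weighting grid points by
their full-data likelihood with κ and branch lengths held at the MLEs.
Positive-site lists are reported at posterior ≥0.95 and ≥0.99, and the
0.99 list is by construction a subset of the 0.95 list.

## Model comparison

LRT: 2ΔlnL against χ²_df, df from the standard nested-pair table
(1 for successive branch models, 4 for M3-vs-M0 at k=3, 2 for
M2a-vs-M1a and M8-vs-M7).  The branch-site Model A vs. null comparison
defaults to df=2 (the convention used in the published snake-opsin
analysis this package reproduces as a worked example); the df=1
convention can be requested explicitly.  Report formatting rounds
2ΔlnL to the nearest integer when ≥10 (one decimal otherwise) and
prints p<1e-5 as a bound.

BIC = −2ℓ + K·log_b(n) with b=10 by default and n the alignment length
in codons.  Base 10 is what reconciles the published (ℓ, K, BIC) rows
used as desk worked examples (back-solved n ≈ 354 codons for all three
genes); natural log is available by flag.  `infer_sample_size`
back-solves n from printed rows as the Chebyshev center, because
print-rounded ℓ (±0.05 → ±0.1 in −2ℓ) makes the per-row estimates of
log n disagree slightly; with that n, recomputed BIC values match the
published rows to ≈0.1 for two of the three genes, while the published
LWS table is internally inconsistent at the 0.1 level (its 3ω and
free-model rows bound log₁₀ n to disjoint intervals), leaving a best
achievable discrepancy of 0.115 there.

## Spectral tuning

Numbering uses global pairwise alignment to bovine rhodopsin (348 aa)
under BLOSUM62 with affine gaps (open −11, extend −1) and a
deterministic tie-break, so reference mapping is bit-reproducible.  An
alignment score below a configurable floor (default 0) rejects
non-opsin queries.

Rule tables per opsin class hold a base genotype and λmax, measured
combination entries, additive single-substitution shifts, and
qualitative rules:

* LWS: base S164/H181/Y261/T269/A292 → 560 nm; combinations S164A →
  553, S164A+Y261F → 545, S164A+T269A → 537; shifts −7/−28/−8/−15/−27
  for S164A/H181Y/Y261F/T269A/A292S.
* RH1: base D83/A292/S299 → 500 nm; combinations D83N+S299A → 493,
  D83N+A292S+S299A → 483; shifts −6/−10/−2.
* SWS1: F86 → 360 nm (UVS); F86V → qualitative "violet-shifted" (VS)
  with no numeric claim — no magnitude is established for snakes.
  Accessory sites (46…265) and RH1 sites without established shifts
  are extracted and reported but carry no Δλ.

Combination entries take precedence over the additive sum because the
measured combinations deviate from strict additivity by ~1 nm in three
cases (537 vs 538, 493 vs 492, 483 vs 482); both conventions remain
available (the additive path is what runs when no combination matches).
Heterozygous profiles are resolved by Cartesian product over
multi-residue sites (capped, default 16 combinations), one prediction
per resolved haplotype.  Unknown sites assume the base residue and are
flagged; substitutions with no rule contribute 0 nm and are flagged
`unscored` rather than suppressing the prediction.

## Synthetic data

`simulate_alignment` draws root codons from π and evolves each branch
with the transition matrix of its class ω; for site mixtures the
site's class is drawn once at the root and is global, with the class's
foreground ω applying only on foreground branches (Model A semantics).
The truth record carries all generative parameters and per-site class
labels.  One master seed drives everything through named child streams
(`numpy.random.SeedSequence`), so outputs are bit-identical across
runs and processes.

`make_opsin_fixture` plants requested residues at bovine-numbered
sites in the rhodopsin backbone (after imposing the class's base
genotype at its canonical sites), back-translates with alphabetically
first codons (or highest-π when π is supplied), and encodes
heterozygous sites as the single minimal IUPAC codon whose expansion
translates to exactly the requested residue set.  Optional N-terminal
extensions and deletions exercise the numbering machinery.

What the simulator does *not* emulate: indel evolution, sequencing
error, chromatogram-level heterozygote calling, selection regimes
outside the fitted model families, and non-equilibrium base
composition.  Passing recovery tests therefore demonstrate the
estimator's correctness under its own assumptions, not robustness to
real-data misspecification.

## Study conditions for the validation experiments

* Engine oracle: pruning vs. brute-force enumeration over all
  internal-state assignments, random trees ≤4 taxa, ≤3 sites,
  tolerance 1e-8.
* One-ratio recovery: 6-taxon tree, ω=0.2, κ=2, L=2000 codons; the M0
  estimate is required within ±0.05.
* Activity-contrast recovery: 8-taxon tree (outgroup, henophidian, a
  three-species diurnal and a three-species nocturnal colubrid clade),
  truth ω = 0.094/0.148/0.161/0.391 (the published rod-opsin
  activity-model estimates), L=2000, 20 replicates; the diurnal <
  nocturnal ordering must be recovered in ≥90% of replicates.
* Null LRT calibration: 6-taxon tree, one-ratio truth ω=0.2, L=500,
  200 replicates; the 2ω-vs-1ω rejection rate at α=0.05 must fall in
  the central 95% binomial interval.
* Site detection: 16-taxon balanced tree with 0.4-substitution
  branches, 8% of sites at ω=10 — with fewer/shallower taxa no site can
  reach posterior 0.95 even at the true parameters, so the deeper tree
  is what makes the 0.95/0.99 thresholds meaningful.  Branch lengths
  are held at truth in that fixture.

These sizes were chosen so each study is informative for the quantity
it measures while staying desk-runnable; they are fixed as the
package's reference conditions and reused verbatim by
`scripts/acceptance.py`.

## Known limitations

* BEB uses a coarse 10-point grid per dimension and MLE-plug-in κ and
  branch lengths; posteriors on small datasets are conservative.
* The free-ratio model on large trees is slow (2N−2 extra parameters
  with numerical gradients) and is intended for small trees.
* No counting-based dN/dS estimators, amino-acid/nucleotide models,
  tree search, or alignment construction — trees and alignments are
  inputs.
* The df=2 default for Model A vs. its null reproduces the published
  analysis's convention and is not an endorsement; the χ²₀/χ²₁
  boundary mixture is the statistically conservative alternative.
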