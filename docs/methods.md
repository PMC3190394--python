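# Methods

This note documents the models and procedures implemented in `coevoscan`,
the design choices made where several reasonable options existed, and what
the synthetic-data experiments do and do not demonstrate.

## Likelihood core

Sequence likelihoods use Felsenstein pruning over all sites at once, with
time-reversible models only.  Matrix exponentials are computed from the
eigendecomposition of the π-symmetrized generator
`B = diag(√π) Q diag(1/√π)`; reversibility guarantees a real spectrum, so
the decomposition is exact and cheap to reuse across branch lengths.
Transition-matrix rows are clipped at zero and renormalized to protect the
samplers against rounding at extreme branch lengths.

* **Amino-acid models**: WAG and LG exchangeabilities with their published
  frequencies, shipped as plain-text tables in the conventional lower-
  triangle layout and verified against the published values.
* **Codon models**: GY94-style over the 61 sense codons of the universal
  code (stop codons excluded from the state space): single-nucleotide
  changes have rate π_target, multiplied by κ for transitions and ω for
  nonsynonymous changes.  Default codon frequencies are F3x4 from the
  alignment; F61 and uniform are options.
* **Rate heterogeneity**: discrete Γ with K equal-probability categories
  represented by bin means (computed from regularized incomplete gamma
  functions), mean rate exactly 1.  K = 4 by default; the shape α is fitted
  by one-dimensional ML where requested.
* **Gaps and ambiguity codes** are fully missing data (all-ones leaf
  partials).
* **Branch lengths** are optimized coordinate-wise: per sweep, inside
  vectors are computed once, outside vectors are propagated in preorder,
  and each branch is maximized with bounded Brent on a cheap edge-local
  likelihood.  Three sweeps, tolerance 1e-6 on the log-likelihood; the
  optimizer never returns a tree worse than its input.  On simulated data
  the recovered lengths track truth (median relative error well under 15%
  at 2000 sites).

## Substitution mapping

Joint substitution histories are drawn from the exact posterior given tip
data: (a) the rate category per site is drawn from its posterior; (b)
ancestral states are sampled backward from the root (prior π times inside
vectors), then each child conditional on its parent; (c) each branch path
is sampled endpoint-conditioned by uniformization with rate bound
μ = max_i |Q_ii| · r_k — the number of uniformized jumps is drawn from its
exact conditional distribution (Poisson weights times powers of the
uniformized kernel), then the intermediate chain is sampled step by step.
Monte-Carlo means agree with spectral closed-form conditional expectations
within three standard errors at 10^4 draws (2-state and 20-state checks in
the test suite).

Per-site, per-branch **weighted vectors** accumulate |Δ property| per
event (correlated mode), the signed Δ (compensatory mode), or the Grantham
matrix entry, averaged over 100 posterior draws by default.

**Site variability N.**  N is the posterior-mean count of
*property-changing* events, not of all substitutions.  This matters: a
site may substitute freely yet never change charge; under the plain count
such sites enter the clustering with near-zero vectors whose single
posterior spikes generate exact ρ = 1 ties against each other in every
variability class, and those ties saturate the achievable p-values.  With
the property-relevant count they are screened out by the variability floor
(N ≥ 1).  For the Grantham weighting every amino-acid replacement has
positive weight, so the two definitions coincide.

## Candidate groups and significance

Complete-linkage clustering on d = 1 − ρ (Pearson, across branches) or on
the compensation distance d(i,j) = ‖v_i + v_j‖ / (‖v_i‖ + ‖v_j‖) for
signed vectors.  Every dendrogram node is a candidate group with
ρ = 1 − (worst within-group pairwise distance) and N_min = the smallest
member N.  Exact distance ties are frequent at low variability (all events
of two sites pinned to one shared branch); the merge order among ties is
broken deterministically in favor of higher-variability pairs so that an
informative pair becomes a candidate of its own rather than being absorbed
into a mixed low-variability clique.  Reported ρ always comes from the raw
distances.

**Parametric bootstrap.**  Replicate alignments are simulated under the
fitted model (branch lengths, Γ categories redrawn per site) and pushed
through the same sampling → weighting → clustering chain; every replicate
candidate contributes an (N_min, ρ) pair to the null.  The candidate
p-value is `(1 + #{null ρ ≥ ρ_obs}) / (1 + #bin)` within the N_min
conditioning bin.  Ties count against the candidate (≥, not >): the
statistic is discrete in the sparse-history regime and a strict inequality
would hand a common null outcome a vanishing p-value.

**Conditioning bins** start from integer-rounded N_min with everything
≥ 10 pooled; sparse bins are merged downward until each holds at least 50
null entries, so the +1-pseudocount floor stays meaningfully small at
desk-scale bootstrap sizes (the rule reduces to fixed integer bins at 1000
replicates).

**Multiple testing.**  For a threshold α, the expected count of false
significant candidates per dataset E_fp(α) is estimated from the same
bootstrap replicates (each replicate's candidates are assigned p-values
against the pooled null, and counted).  The threshold is tightened until
E_fp(α)/max(1, #observed discoveries at α) ≤ 0.05 — an empirical FDR
step-up.  Under the global null this leaves the family-wise rate of any
significant group near the nominal 0.05 by mass balance, which the
acceptance suite verifies (observed 2/30 null datasets flagged).

## Positive selection

Site models M0, M1a, M2a, M3 (3 classes), M7, M8 (10 beta categories by
bin means plus the ω_s ≥ 1 class).  Class rate matrices share one joint
normalization (one branch-length unit = one expected substitution per site
averaged over classes), so high-ω classes genuinely evolve faster.
Branch lengths are estimated under M0, then held fixed up to a free
tree-scale factor for the richer models.  Free parameters are transformed
to the real line (log κ, log scale, stick-breaking proportions, logit for
ω < 1 classes, 1 + exp for ω ≥ 1 classes) and optimized by L-BFGS-B from
three ω-pattern starts (0.1 / 1 / 3), short exploration then a polish of
the best; when several models are fitted together, each alternative also
starts from its fitted null embedded in the larger parameter space, which
enforces the nested-likelihood ordering in practice.  Site patterns are
compressed before fitting.  LRT p-values use the χ² upper tail with
df 4 (M0–M3) or 2 (M1a–M2a, M7–M8); the boundary null makes the tests
conservative, which the type-I check reflects.  NEB posteriors are
prior-weighted class likelihoods normalized per site; calls require
posterior ≥ 0.95 (the threshold is inclusive) *and* a significant LRT.
BEB is deliberately not implemented.
Externally computed site lists (TSV, 1-based) are accepted in place of
fitting, e.g. for switching-model analyses produced by other software.

## Synthetic data generator

* **Trees**: Yule topologies with the exponential inter-event times of the
  pure-birth process, rescaled so the mean root-to-tip path equals
  `tree_height` exactly.  Default height 0.8 expected substitutions per
  site: at that depth a variable site accumulates roughly two to five
  property-changing events, which is the regime in which a co-substitution
  statistic carries information — with a single event per site, any
  co-occurrence is indistinguishable from coincidence.  Real rbcL
  alignments spanning major land-plant lineages reach comparable depths;
  shallower families would need correspondingly more sequences.
* **Background sites** evolve independently under GY94(κ = 2, ω = 0.2 —
  strong but not absolute purifying selection, rbcL-like); planted
  positively selected sites use their own ω; the site-ω mixture shares a
  joint rate normalization exactly as in the fitted models.  Uniform codon
  frequencies by default.
* **Planted coevolving pairs** follow a concerted-compensation coupling.
  Whenever one site substitutes with a change of the coupled property, the
  partner immediately makes one compensating substitution with probability
  1 − 1/λ, drawn from its own rates restricted to moves toward the
  *complement* of the partner's new amino acid (opposite charge sign;
  conserved polarity/volume sum fixed at pair creation; smaller Grantham
  distance to the partner).  Between such events each site's moves away
  from the complement are damped by 1/λ.  λ = 1 reduces exactly to
  independent evolution.  Charge pairs are created in oppositely charged
  root states — the K–D / R–E see-saw the detector is meant to find.  A
  pure rate-multiplier coupling was implemented first and rejected after
  measurement: with realistic branch lengths the compensating response
  almost never lands on the branch of the driver substitution, so even the
  true simulated histories carry almost no per-branch correlation, and no
  co-substitution detector could see the planted signal at any strength.
  Pair sites default to marginal ω = 1 (`pair_omega`) so that the
  coupling, not purifying selection, dominates their dynamics.
* **Toy structures**: single-chain PDB text; residues are 3–8-atom
  clusters centred on a self-avoiding 3.8 Å random walk; planted close
  pairs are placed within 8 Å center-of-mass distance.  No physics beyond
  that is attempted: these fixtures exercise parsing, mass-weighted
  centers, distance summaries and the proximity test, nothing about real
  protein geometry.
* **Secondary structure**: i.i.d. H/E/C labels, default proportions
  43.5/26.4/30.1% (helix-rich, strand, coil), matching the background
  composition reported for the Rubisco large subunit.

## Structure analysis

PDB ATOM records are parsed with Biopython; one chain per model, highest-
occupancy altloc conformer, heteroatoms/waters/hydrogens excluded.
Residue centers are mass-weighted over all remaining atoms (standard
atomic masses by element), so the residue is treated as a whole molecule
rather than represented by Cα/Cβ; an optional Cα/Cβ contact metric exists
but is off by default.  Distance summaries are Euclidean; minima over
conformational states use the intersection of pair sets.  The proximity
test is the one-sample Z-test
`Z = (mean_subset − mean_background) / (sd_background / √n_subset)`, with
the one-sided p for "subset closer" and the difference reported as
mean_background − mean_subset (positive when the subset is closer).
Neighborhoods are all residues whose center lies within the radius; the
query residue itself is excluded by default (an inclusion flag exists, as
published neighborhood tables sometimes list the residue itself).

## Composition statistics

Compositions pool residues over sequences and datasets at the given
sites; gaps are never counted.  The χ² test of independence runs on the
2×20 contingency table with the rarest categories pooled until all
expected counts reach 5.  The pairing matrix counts one unordered
amino-acid pair per sequence per site pair (groups expanded to all
pairwise combinations; gap-containing pairs skipped); an alternative
counting unit (one modal pair per dataset) can be obtained by passing
single-sequence alignments.  Secondary-structure enrichment uses the
two-proportion z-test with pooled variance; with a subset drawn from the
background the test is approximate but conservative for the
subset-vs-whole comparisons reported here.

## Problem sizes used by the tests and the acceptance script

All statistical checks run on one CPU with sizes chosen for that budget;
they are stated here as the package's own experimental design:

* coevolution type-I: 30 null datasets (15 taxa × 50 codons, 150
  bootstrap replicates, 20 posterior draws), family-wise rate compared to
  the central 95% binomial interval around 0.05;
* coevolution power: 12 datasets (40 taxa × 50 codons, two charge-coupled
  pairs at λ = 10, 200 bootstrap replicates), planted-pair recovery tested
  one-sided against a conservative upper bound on the unplanted
  false-pair rate;
* selection: power over 10 replicates (12 taxa × 150 codons, 10% of sites
  at ω = 4, 20% neutral) requiring a significant M1a–M2a LRT in ≥ 8/10 and
  NEB posterior separation (paired Wilcoxon p < 0.01); type-I over 25
  nearly neutral replicates allowing at most 2 rejections at α = 0.05
  (the 7% bound at this granularity);
* substitution-mapping calibration at 10^4 draws; likelihood oracles on
  3–4-taxon fixtures at 1e-8.

Passing these checks demonstrates internal statistical correctness and
calibration of the implementation under its own generative model.  It does
not demonstrate that real rbcL datasets contain coevolving residues, nor
that the concerted-compensation coupling is how real residue pairs
coevolve; on real data the usual caveats about model misspecification
(no indels, stationarity, one tree per dataset, i.i.d. background sites)
apply.

## Known limitations

* Reversible models only; no covarion/switching processes — externally
  computed site lists stand in for those analyses.
* NEB, not BEB: parameter uncertainty is ignored in site posteriors.
* The compensation statistic for groups larger than two is a frozen
  interpretation (vector-cancellation distance); other definitions exist.
* The bootstrap null conditions on N_min only; residual heterogeneity
  within a bin (branch-length placement of events) is not conditioned on.
* mmCIF, assemblies and DSSP are out of scope for the structure stage.
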