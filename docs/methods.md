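# Methods

`orthosel` re-implements, as one tested pipeline, the comparative
molecular-evolution workflow used to study multi-genome gene families such
as the 11S seed-storage globulins: ortholog-family detection by reciprocal
best hits, neighbor-joining phylogenetics on JTT protein distances, and
Goldman–Yang (GY94) codon-model inference of selective pressure (branch
models, branch-site Model A, pairwise dN/dS).  This note records the models,
the conventions and numerical choices behind them, and what the synthetic
data do and do not establish.

## Ortholog detection (COG procedure)

Genes from distant genomes belong to one orthologous family when they are
more similar to each other than to any other gene of the same genomes.  The
implementation follows the classic clusters-of-orthologous-groups recipe:

1. **All-against-all similarity.** Smith–Waterman local alignment scores
   (Bio.Align, BLOSUM62, affine gaps, open 11 / extend 1).  Only score
   *rankings* enter later stages, so no bit-score or E-value calibration is
   performed.  The default similarity threshold is taken from a
   shuffled-sequence background: score a sample of residue-permuted pairs
   and keep hits above the 99th percentile.
2. **Best hits (BeTs).** For every gene and every other genome, the
   top-scoring gene there (ties broken lexicographically — determinism).
   An edge is *symmetric* when reciprocal, otherwise *asymmetric*.
3. **Paralog collapsing.** "Obvious paralogs" are taken to be same-genome
   genes that score higher with each other than either does with any
   foreign gene (mutual within-genome dominance); groups are connected
   components of that relation and are represented by their
   highest-scoring member.
4. **Seed expansion.** From a query gene, repeatedly add all BeTs of
   current members and their collapsed paralogs until a fixed point; the
   closure is independent of which family member seeds it.
5. **Cluster formation.** Keep BeT edges lying in at least one triangle
   whose three genes come from three distinct genomes; merge triangles
   sharing an edge; clusters are the connected components of the retained
   edges.
6. **Diagnostics instead of manual curation.** A per-cluster table (genome
   coverage, within-cluster score range) replaces case-by-case curation,
   which is not algorithmic; nothing is deleted automatically.

## Protein phylogeny

Pairwise distances are maximum-likelihood estimates under the JTT
replacement model (exchangeabilities and frequencies bundled as package
data; generator normalized to one expected substitution per site).  Sites
gapped or ambiguous in either sequence are excluded pair by pair
(pairwise deletion).  Each distance is a bounded one-dimensional likelihood
maximization on t ∈ [0, 10]; estimates at the cap raise a saturation
warning.  Trees are Saitou–Nei neighbor joining with the Q-criterion,
lexicographic tie-breaking and negative branch lengths clamped to zero —
exact on additive matrices.  Bootstrap support resamples alignment columns
with replacement (default 1000 replicates, configurable; seeded) and
reports, per original-tree split, the fraction of replicate trees
containing it.

## Codon models

The GY94 Markov model on the 61 sense codons (universal code; stops
excluded) has off-diagonal rates q_ij = 0 for multi-nucleotide changes and
otherwise π_j, scaled by κ for transitions and ω for nonsynonymous changes.
Equilibrium frequencies default to F3x4 (positional nucleotide
frequencies, floored at 1e-8 and renormalized so every sense codon stays
reachable); F61 is available.  Transition probabilities come from the
eigendecomposition of the π-symmetrized generator.  Likelihoods use
Felsenstein pruning over compressed site patterns with per-node scaling;
eigendecompositions are cached per (κ, ω).  By reversibility the root
placement is irrelevant (verified to 1e-8 by rerooting tests).

**Branch lengths and rate scaling.** For one-ratio and branch-specific
models every branch-class generator is normalized to one expected
substitution per codon, so branch lengths are expected substitutions per
codon under the branch's own ω.  For branch-site Model A the four site
classes share **one** rate scale, anchored so that the expected rate on
background branches, averaged over site classes at the current mixture
weights, is one — positively selected sites therefore evolve
proportionally faster on the foreground.  This is the convention of the
standard codeml implementation, and it carries most of the detectable
signal: under per-class normalization an ω2 = 8 class differs from neutral
only in its nonsynonymous fraction and branch-site power collapses.  The
simulator exposes both conventions (`SimRegime.scaling`), and simulation
and inference always use matching ones in the tests.

**Optimization.** Bounded L-BFGS-B on (branch lengths, κ, ω vector), with
multi-start jitter (default 3 starts; simulation studies use 1).
Convergence tolerance 1e-6 on the log-likelihood; ω is bounded at 999,
mirroring the boundary estimates such analyses print.  Model A defaults to
branch lengths (and optionally κ) fixed at one-ratio (M0) estimates — the
fast mode — with joint re-optimization available; the alternative fit is
seeded from the null optimum at two ω2 starting points and is floored at
the null likelihood (the models are nested), so LRT statistics cannot go
negative through optimizer failure.

**Pairwise dN/dS.** (t, κ, ω) fitted by ML on the two-sequence tree.
Synonymous/nonsynonymous site fractions are computed from the κ/π
mutational opportunity (the matrix at ω = 1), which makes dN/dS = ω an
exact identity.  Pairs with dS > 2 are flagged `retained = False`
(saturation filter).  Near stationarity the three parameters are jointly
unidentifiable and a bounded optimizer can land on an ω-inflated,
dS-deflated corner that would evade the filter; a saturation guard
therefore reports the ω = 1 profile fit whenever the full fit is within 10
log-likelihood units of the infinite-divergence model *and* the profile
already implies dS > 2.  The margin was calibrated on simulated saturated
pairs (observed overfitting gains up to ≈ 8.6 units; informative pairs sit
hundreds of units above stationarity).

## Selection tests

Branch-specific models assign one ω per branch class; the LRT against the
one-ratio model uses df equal to the difference in ω-class counts (the
standard nested-parameter count).  Branch-site Model A mixes four site
classes — conserved (ω0 < 1), neutral (ω1 = 1), and two classes whose
foreground ω2 ≥ 1 — with proportions p0, p1 and p2a/p2b derived
proportionally; the null fixes ω2 = 1 and the test uses χ²(1), which is
conservative relative to the 50:50 boundary mixture.  Per-site posteriors
of the selected classes are computed naively at the MLEs (NEB) or by Bayes
empirical Bayes (BEB): a uniform discrete prior over a 10-level triangle
grid on (p0, p1), 10 midpoint levels of ω0 on (0, 1) and of ω2 on (1, 11),
other parameters at their MLEs, with the rate scale fixed at the MLE
mixture.

Worked-example reproduction: the package ships the published −lnL tables
of the 11S-globulin branch-model and branch-site analyses
(`orthosel.reference`); feeding them through `lrt` reproduces all nine
published significance verdicts, including the two-vs-one statistic 9.00
(p ≈ 0.0027) and the branch-A branch-site statistic 15.40 (p ≈ 8.7e-5).
The published parameter estimates themselves are not reproducible without
the original ten proteomes, which are out of scope.

## Synthetic data

The simulator provides ground truth at two levels.

*Codon alignments* evolve site-independently on a labeled tree: root codon
from π, then exact endpoint sampling from P(t) = exp(Qt) rows per branch —
distributionally identical to event-level simulation and much faster.
Site classes (proportion + per-branch-class ω map) express one-ratio,
branch, and branch-site regimes.  No indels are simulated, so alignments
are exact by construction; the upstream aligner of real analyses is
outside the package.

*Genomes* evolve one gene family per independent random root sequence on a
species tree (default balanced, configurable lengths), with Poisson
duplications and exponential losses per branch and a replayable event log.
Decoy families guarantee background-level cross-family similarity without
tuning.  All randomness descends from one seed; per-family child seeds are
`(seed * 1_000_003 + index) % 2**31`.

What passing tests show — and what they do not: recovery, calibration and
power results hold for indel-free, stationarily-composed, site-independent
data with correct alignments and uniform codon frequencies.  Real data add
alignment error, composition heterogeneity, recombination and among-site
rate correlation, none of which are modeled; the COG stage similarly sees
decoys with background similarity, not genuinely homologous subfamilies.

## Simulation study designs

Problem sizes were chosen to make each property measurable at desk scale:

- **Branch-model recovery**: 8 taxa, 500 codons, ω0 = 0.2 vs ω1 = 0.4 on a
  fully labeled clade, 20 replicates; medians recover both ω within ±0.05
  and the ordering in 100% of replicates.
- **Branch-site calibration**: 5 taxa, 100 codons, 200 replicates under
  ω2 = 1; empirical size ≤ 1% at α = 5% (the χ²(1) reference is
  conservative at the boundary, as expected).
- **Branch-site power**: 8 taxa, 500 codons, ω2 = 8 on ~10% of sites, the
  foreground being a long (0.4 subs/codon) post-duplication stem branch —
  the kind of lineage-origin branch such tests target; power ≈ 95% over 20
  replicates.  Shorter foregrounds (0.2) give ≈ 77%: branch-site power is
  strongly length-limited, which is worth remembering when interpreting
  single-branch results on real families.
- **End-to-end pipeline**: 4 genomes, target family of 250 codons with
  episodic foreground selection (ω2 = 20 on 10% of sites — conservative
  against the 56–999 range such analyses report — plus a two-fold relaxed
  conserved class), 2 decoy families.  The planted clade's branch-site
  test is significant in 10/10 pilot seeds; testing an unselected control
  clade on the same data is non-significant in 10/10.

## Known limitations

- No indel simulation or alignment inference; gap handling is limited to
  column deletion of supplied alignments.
- The branch-site LRT uses χ²(1), not the boundary mixture; p-values are
  conservative.
- BEB integrates over mixture parameters only; κ and branch lengths are
  plugged in at their MLEs, as in the original construction.
- Pairwise estimates at or near saturation are reported via the neutral
  profile and flagged for discarding; they should never be interpreted
  quantitatively.
- The COG stage assumes proteome-scale inputs are already reduced to
  manageable gene sets; the all-against-all scorer is quadratic in total
  gene count.
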