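# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `haloadapt`, and what its synthetic-data tests do
and do not establish about real data.

## Sequence handling and translation

Sequences are plain FASTA; group metadata (adaptation class, taxonomic
clade, sampling season) comes from an optional TSV sidecar keyed by id.
Translation uses the standard genetic code only, embedded as a fixed table:
stop codons render as `*`, codons containing N as `X`, all-gap codons as
`-`, and incomplete trailing codons are dropped. Best-frame selection
minimizes the count of internal stops over the six frames, breaking ties in
the order +1, +2, +3, −1, −2, −3; a nonzero minimum raises a flag. A
homology-search confirmation of the chosen frame is deliberately out of
scope — the stop-count criterion is the whole contract.

Redundancy filtering is a greedy longest-first identity clustering: each
sequence joins the first cluster whose representative it matches at or above
the threshold (identity = identical columns / alignment length of a global
pairwise alignment scored +1 match, 0 mismatch, −1 per gap position).
CD-HIT's word-size prefiltering heuristics are *not* reproduced: at desk
scale (tens to hundreds of sequences) exact all-pairs alignment is
affordable and easier to reason about. At threshold 1.0 the scheme reduces
to exact deduplication. Typical usage follows the two-pass convention: a
90% pass to collapse near-redundant phylotypes, then a 100% pass.

## Masks and catalytic sites

Conserved-block selection (GBLOCKS-style) is consumed, never computed: a
mask is an explicit strictly-increasing list of 1-based amino-acid columns.
The codon mask keeps nucleotide columns {3i−2, 3i−1, 3i} for each kept aa
column i, so amino-acid and nucleotide analyses always refer to the same
region. Amino-acid and nucleotide masks are treated as independent inputs
rather than forced to agree, since published column counts for the two
levels of the same fragment need not match once indel columns are handled
differently. Catalytic-site checks report the fraction of sequences
carrying the expected residue at a named masked column; a gap counts as
non-conserved.

## Composition indicators

Composition is percent of counted residues, excluding gaps, `X` and `*`
from numerator and denominator. Categories are fixed: hydrophobic
{G,L,V,I,F,M,A,W,P}, polar {S,T,C,Y,Q,N}, basic {H,R,K}, acidic {E,D}.
PAB = (Asx+Glx) − (Arg+Lys) and AB = (Asp+Glu):(His+Arg+Lys) use the
percentage scale; since sequence residues are unambiguous, Asx = Asn + Asp
and Glx = Gln + Glu are simple sums. AB is reported missing (not infinite)
when a fragment has no basic residues. Group summaries use the sample SD
(n−1 denominator), 0 for singletons. By default composition is computed on
the masked alignment region (the region that also underlies the phylogeny);
full-fragment mode is available by omitting the mask. Published
bulk-proteome rows (E. coli, H. salinarum, H. elongata) are shipped as
context constants for reports, not recomputed.

## Codon statistics

GC% excludes gaps and N from both numerator and denominator; positional GC
requires in-frame input. RSCU divides each codon's pooled count by the mean
count of its synonymous family, so family totals sum to the family size and
the no-bias value is 1.00; zero-count families are reported missing rather
than zero, which keeps downstream correspondence analysis well defined.
Met/Trp are 1.0 whenever observed. Stop codons are excluded by default; a
flag adds a 3-codon stop family for display parity with codon-usage charts
that include them. Group-level RSCU pools codon counts across a group's
sequences rather than averaging per-sequence RSCU values — pooling is the
natural choice when groups are compared as datasets, and it is the
documented default.

Correspondence analysis of the groups × codons RSCU matrix drops codons
with missing values, then performs the standard SVD of the standardized
residuals of the profile matrix (delegated to scikit-bio's `ca`); total
inertia equals the table's χ² statistic divided by its grand total, which
the tests verify against a direct χ² oracle.

## Tajima's D

Complete deletion removes every column containing a gap or ambiguous base
(per-site pairwise deletion is available behind a flag). S counts
segregating sites once regardless of allele number; π̂ is the mean over all
sequence pairs of per-pair mismatch counts. The constants a₁, a₂, b₁, b₂,
c₁, c₂, e₁, e₂ are the standard ones; D is undefined (reported missing) when
S = 0. The implementation is cross-validated against tskit's `Tajimas_D` on
identical genotype matrices. Significance lookup tables and coalescent
confidence intervals are out of scope; D is reported as a point statistic.

## Protein distances and trees

The JTT empirical exchangeabilities and equilibrium frequencies are
embedded as published constants, with the rate matrix normalized to one
expected substitution per site per unit time, so distances are in
substitutions/site. The pairwise distance maximizes the likelihood
Σ N_ab log(π_a P_ab(t)) over comparable (pairwise-ungapped) columns, with
bounded scalar search on t ∈ [0, 10] to 1e-6. Rate variation among sites
uses the continuous-gamma eigenvalue transform
P(t) = U diag((1 − λₖ t/α)^(−α)) U⁻¹ rather than a discrete-category
approximation — exact for distance-matrix usage and one line to swap later.
Marker-specific shape parameters are required inputs with defaults 0.9
(*aprA*) and 0.8 (*mcrA*); the package does not estimate α.

Neighbor joining follows Saitou–Nei with the Q-criterion, ties broken on
the smallest index pair in current node order, negative branch estimates
clamped to zero, and the final three nodes resolved by the three-point
formulas (unrooted, trifurcating). Bootstrap resamples alignment columns
with replacement under a seeded generator; the majority-rule (>50%)
consensus carries percentage supports and mean branch lengths over
replicates containing each branch, and internal branches below the collapse
threshold (default 60%) become polytomies. The default replicate count is
100, configurable. Maximum-parsimony and ML tree search are out of scope;
NJ is the topology engine.

## DGGE fingerprints

Bands are qualitative presence/absence calls; no intensity model. Lane
distance is Jaccard, 1 − |A∩B|/|A∪B|. Clustering is NJ by default or UPGMA
by flag. This binary-distance clustering is a deliberate, clearly labeled
stand-in for restriction-site maximum-likelihood clustering of band
patterns: it preserves the inputs (binary band calls) and the output (a
lane dendrogram) while avoiding an unpublishable likelihood on band
characters. Seasonal structure is tested by permutation: the statistic is
mean between-season minus mean within-season distance, labels are permuted
uniformly (999 by default, seeded), and the p-value uses add-one smoothing
with ties counted as exceedances. On perfectly separated groups the
attainable minimum is 1/(permutations+1), reached whenever no sampled
permutation happens to recreate the original partition.

## Synthetic-data generators

All generators are pure functions of their parameters and a seed.

*Coding sets.* Codons are drawn i.i.d. from a 61-codon distribution built
from independent per-position GC weights times per-amino-acid tilt factors
on the PAB-relevant residues (N,D,Q,E up; R,K down). The weights are solved
jointly by root finding so that the distribution's *expected* positional GC
and PAB hit the targets exactly; infeasible combinations raise an error
naming the conflicting constraints. Realized values then scatter with
binomial sampling error (about 0.9 GC3 points for 20 × 125 codons). The
defaults mirror a realistic marker-fragment study design: 20 sequences of
125 codons, with group targets such as GC3 = 0.76 / PAB = 2.87 for a
strongly GC3-biased group. Because codons are i.i.d., these sets carry no
phylogenetic autocorrelation — recovery tests validate the estimators, not
the field sampling design.

*Evolution on trees.* Root states are drawn from JTT equilibrium; each site
evolves independently down branches by P(t) sampling, optionally with
Gamma(α, 1/α) per-site rate multipliers. No indels.

*Coalescent.* Kingman genealogies with Exp(k(k−1)/2) epoch times, mutation
count Poisson(θ/2 × total branch length), each mutation on its own column
(infinite sites), binary A/G encoding — which makes E[S] = θ·a₁ exact and
keeps the Tajima's D null distribution faithful. Replicates that overflow
the column budget are redrawn (or error, by flag).

*Band tables.* A Bernoulli(½) archetype per band for season one; season two
flips each band with probability `between_shift`; lanes flip their season's
archetype with probability `within_noise`; all-zero lanes get one band
switched on.

What passing tests show: estimator correctness and calibration under the
stated generative models at the stated sizes. What they do not show:
robustness to alignment error, indels, within-gene recombination,
phylogenetic non-independence of the composition groups, or PCR/DGGE
artifacts in real fingerprints.

## Problem sizes and determinism

The test suite uses desk-scale sizes chosen to keep Monte-Carlo error
meaningful: 100 random trees (≤10 leaves) for NJ recovery, 100 replicates
of 500 sites for distance recovery at t = 0.5, 200 coalescent replicates
(n = 10, θ = 5, 200 sites) for the neutrality null, 20 × 125 codons for
composition recovery, and 999 label permutations for the DGGE test. Every
stochastic stage takes an explicit seed; rerunning the pipeline with the
same config and seeds reproduces byte-identical outputs.

## Known limitations

- Frame selection ignores homology evidence; a fragment whose true frame is
  interrupted by sequencing error will be flagged but not rescued.
- Greedy identity clustering depends on input (length) order at borderline
  identities, as does any CD-HIT-style scheme.
- Under strong amino-acid constraints the positional-GC/PAB solve can be
  infeasible; the generator refuses rather than approximating silently.
- Tajima's D has a slightly negative finite-sample mean under neutrality;
  the null tests bound the deviation by Monte-Carlo error rather than
  asserting exact zero.
- The ML distance is capped at 10 substitutions/site; saturated pairs hit
  the cap instead of diverging.
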