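# Methods

`mlstpg` implements the population-genetic analysis of a bacterial strain
collection typed by multi-locus sequence typing (MLST), with *Lactobacillus
delbrueckii* subsp. *bulgaricus* — the principal yogurt starter — as the
model system.  The default locus panel is the eight-gene scheme used for that
organism (clpX 508 bp, dnaA 598 bp, groEL 470 bp, murE 477 bp, pheS 491 bp,
pyrG 563 bp, recA 551 bp, rpoB 603 bp; 4,261 bp concatenated), but every
function is generic over the panel.

## Typing model

Each locus fragment is validated (exact length, A/C/G/T alphabet, no stop
codon among the complete codons of its declared frame; ambiguity codes are
rejected rather than resolved, since finished Sanger consensus sequences are
assumed).  Every distinct sequence at a locus is an allele, numbered in
first-occurrence order of the input stream; every distinct 8-vector of allele
numbers is a sequence type (ST), numbered the same way.  Numbering is
therefore deterministic given a manifest-sorted input and idempotent on
re-runs; permuting the input permutes labels but never merges or splits
classes.  Novel alleles during lookup are reported (query mode) or registered
(extend mode); query is the default so that a frozen database cannot grow by
accident.

## Diversity statistics

All statistics are available per locus and for the concatenation, over an
arbitrary isolate subset.

* **Polymorphic sites** — columns with ≥ 2 observed bases.
* **G+C content** — percentage over all sequences of the subset.
* **π (nucleotide diversity)** — mean pairwise differences per site,
  `Σ_{i<j} d_ij / C(n,2) / L`, computed over *isolates* (not unique STs) and
  without multiple-hit correction, matching the plain average-pairwise
  definition.  The concatenated π is algebraically the length-weighted mean
  of per-locus π; the test suite asserts this identity to 1e-12.
* **sSNP/nSNP classification** — a polymorphic site inside a complete codon
  is nonsynonymous iff some pair of codons observed at its codon position
  changes the amino acid through that site (the site's base swapped in either
  codon background); a site with both synonymous and nonsynonymous pairs is
  counted once, as nonsynonymous, so the two counts are disjoint.  Sites in a
  trailing incomplete codon are excluded.
* **dN/dS** — Nei–Gojobori (1986) counting.  Per codon, each position
  contributes (synonymous one-base changes)/3 to the synonymous site count,
  with changes into stop codons counted as nonsynonymous.  Between two codons
  the substitutions are averaged with equal weight over the minimal
  mutational pathways that avoid stop-codon intermediates (all pathways if
  none avoids a stop).  Per-site proportions get the Jukes–Cantor correction
  `d = −(3/4) ln(1 − 4p/3)`, undefined (NaN, flagged) when p ≥ 3/4; raw
  proportions are reported alongside.  Pair values are averaged over all
  pairs and the ratio taken on the averages; the ratio is 0 when dN = 0 and
  flagged undefined when dS = 0 with dN > 0.  dN/dS and the allele/SNP counts
  operate on the distinct sequences of the subset (the allele set), as
  summary tools in this field do; π deliberately does not.

## eBURST clustering

STs are nodes; single-locus variants (profiles differing at exactly one of
the eight loci) are edges.  Connected components are the clonal groups:
clonal complex (CC) at ≥ 3 STs, doubleton at 2, singleton at 1 — the
three-way breakdown used for MLST population snapshots.  The CC founder
maximises SLV degree, with a deterministic tie-break chain — more
double-locus variants, then more isolates, then the smaller ST number —
replacing eBURST's bootstrap support for reproducibility.  Subgroup founders
are non-founder members with ≥ 2 SLV links besides a direct link to the
founder.  Snapshots are exported as GraphML and DOT with node size equal to
the isolate count.

## Recombination inference

**PHI (pairwise homoplasy index).**  For each pair of parsimony-informative
sites the refined incompatibility score counts the extra mutations needed to
fit both sites on a single genealogy: with the observed states as the
vertices of a bipartite graph and observed joint states as edges, the score
is `edges − vertices + components` (0 iff compatible).  Because there are at
most 4 DNA states per site, every pair's joint-state set is a 16-bit mask
and all 65,536 scores are tabulated once, making the all-pairs matrix cheap.
PHI is the mean score over nearby informative-site pairs: the window
(default 100 alignment sites) is converted to a rank distance
`k = round(window · s / L)` on the informative-site subalignment.
Significance comes from site-order permutations of the precomputed matrix,
`p = (r + 1)/(N + 1)` with `r` the permutations whose statistic is ≤ the
observed; under clonality site order is exchangeable and p is uniform, while
recombination makes nearby pairs more compatible than distant ones and
pushes p down.  Fewer than two informative sites yield a flagged
"not computable" result with p = 1.  The p-value is exact only when the
statistic is effectively continuous; on nearly homoplasy-free alignments
ties make it conservative (p near 1), which is the test's documented
behaviour, not an error.

**I_A^S (standardized index of association).**  On allele profiles (unique
STs by default, since linkage analyses of MLST data are conventionally run
on STs; per-isolate input is just another profile list), the mismatch count
`d` over `l` loci is computed for every pair.  `V_D` is the population
variance (denominator C(n,2)) of that distribution and
`V_e = Σ_j h_j (1 − h_j)` its linkage-equilibrium expectation, with
`h_j = (n/(n−1))(1 − Σ_k p_jk²)` the unbiased mismatch probability at locus
j — algebraically exactly the observed fraction of mismatching pairs.
`I_A^S = (V_D/V_e − 1)/(l − 1)` is ~0 under free recombination, 1 when all
loci are perfectly associated (the population-variance convention makes this
exact), and its p-value is the Monte-Carlo fraction of datasets with
independent within-locus allele permutations reaching the observed value,
plus-one corrected.  Only the Monte-Carlo mode is provided; a parametric
approximation would add an unverifiable null without adding power.

## Subspecies classification

*L. delbrueckii* comprises six named subspecies anchored by type strains.
Each locus votes for the subspecies whose type-strain sequence is nearest by
p-distance; exact ties give an unresolved vote.  The final call is the
strict plurality (unresolved on a tie, never random), and isolates whose
resolved votes split across subspecies are flagged as mosaics — at MLST
resolution these are candidates for inter-subspecies homologous
recombination.  Neighbor-joining trees on the p-distance matrix (scikit-bio's
NJ, negative branch lengths clamped to zero) provide the per-locus
visualisation; classification itself is nearest-reference, so a
maximum-likelihood tree would decorate but not change the calls.

## Synthetic populations

The generator emulates the structure of a naturally fermented dairy strain
collection.  Defaults: the eight-locus panel; K = 6 ancestral lineages with
per-site divergence 0.005 between ancestors (between-lineage scale within a
subspecies); 251 isolates; 12 transmission generations; per-site mutation
probability mu = 5e-5 per transmission, placing within-lineage diversity
near 1e-3, the order observed in this organism; and whole-locus
recombination probability rho = 0.02 per transmission.  Each lineage expands
clonally from its own ancestor to an equal share of the population (so no
lineage is lost to drift), parents are drawn within lineages, and
recombination donors are drawn population-wide, allowing cross-lineage
imports.  Recombination is whole-locus replacement by default — at MLST
resolution imports appear as allele replacements — with an intragenic
segment-import mode (geometric lengths, junction codons restored if a stop
would form) for sequence-level recombination tests.  Mutations avoid stop
codons by rejection sampling, mirroring the organism's stop-free amplicons.
Every event is logged; `replay()` rebuilds every final sequence byte-exactly
from the ancestors and the event log, which is how the generator is tested.
Seeds are mandatory; nothing is wall-clock seeded.

What the generator does **not** emulate: coalescent-exact genealogies,
selection, demographic structure beyond the equal lineage split, sequencing
error, and indels.  Passing tests therefore demonstrate correctness of the
statistics and their calibration on tree-like clonal data with known events,
not robustness to real-world artefacts.

## Test calibration choices

Statistical tests run at desk scale, with regimes chosen so the statistics
are non-degenerate:

* PHI type-I error: 200 clonal replicates (single lineage, one 1,500 bp
  locus, 15 isolates, mu = 0.01) — a high-homoplasy regime in which the
  permutation statistic is effectively continuous — with 199 permutations;
  the rejection rate at α = 0.05 must fall inside the binomial 95% CI.
* PHI power: 100 replicates of two lineages (divergence 0.1) mixed by
  segment imports (rho = 1.0, mean 400 bp, 20 isolates); rejection ≥ 90%.
  Note that per-column shuffling *across* sequences is not a usable power
  construction: it makes columns exchangeable, and a site-order permutation
  test has exactly nominal rejection under exchangeability.  The shuffling
  operation is instead verified for its conservation properties.
* I_A^S equilibrium: 50 replicates of 500 profiles with independent uniform
  alleles; the mean must sit within ±3 standard errors of 0.
* Lineage recovery: single-linkage clustering on profile Hamming distance
  must reproduce the simulator's lineage labels exactly (ARI = 1) at default
  sizes with rho = 0 and ancestor divergence 0.05.

## Numerical and degenerate-input conventions

All permutation/resampling p-values use the (r+1)/(N+1) correction, so no
p-value is ever 0.  π requires ≥ 2 sequences; I_A^S requires ≥ 3 profiles,
≥ 2 loci and at least one polymorphic locus (V_e = 0 is a typed error); PHI
requires ≥ 4 sequences.  A single-isolate diversity subset reports NaN for π
rather than 0.  JC-uncorrectable proportions (p ≥ 3/4) propagate NaN with
the raw proportions still reported.  Ragged alignments, non-ACGT characters,
arity mismatches, duplicate ST identifiers and missing loci are typed
errors naming the offending isolate or locus.

## Known limitations

Sequence-level lineage inference (Bayesian admixture models), composite-
likelihood rho/theta estimation, split-decomposition networks and
maximum-likelihood phylogenies are out of scope; lineage labels, where
needed, are accepted as an input membership table.  eBURST founder
confidence is deterministic rather than bootstrap-based.  The O(n²) SLV
graph construction is adequate for thousands of STs but not for national
surveillance databases.
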