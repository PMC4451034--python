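# Methods

`transpoly` re-implements, as a tested pipeline, the analysis of
trans-species polymorphism in a multi-gene clone library: cathelicidin
genes PCR-amplified with a single primer pair from Atlantic cod
(*Gadus morhua*) and four related gadids, cloned, Sanger-sequenced, and
analyzed for balancing-selection signatures.  This note records the
models, the decisions taken where the procedure was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Clone-library screening

PCR polymerase errors appear in cloned amplicons predominantly as
singleton substitutions private to one clone.  The screen works within
*groups* — the clones of one individual assigned to one cluster
(paralog) — and evaluates every column where a group is variable:

* **Singleton candidate**: exactly one clone of a ≥3-clone group
  differs from the otherwise uniform rest.  In a 2-clone group any
  disagreement makes both variants candidates.
* **Recurrence** (evidence the variant is real): the variant base
  occurs in a clone of at least one *other* individual of the same
  cluster at that column, or another individual's clones are themselves
  variable there.  Recurrent candidates are retained as real SNPs;
  non-recurrent candidates are masked to the group-majority base.
* 2-clone disagreements where exactly one variant recurs mask the
  non-recurrent clone; where neither recurs, the cluster-wide majority
  base decides, and a tie masks neither (flagged `unresolved`).
* Groups of size 1 carry no within-individual evidence and are never
  masked.
* Indel characters act as a fifth state, so a one-clone gap is a
  maskable artifact.

Two design points deserve emphasis.  First, recurrence is evaluated
against the *pooled* clones of the other individuals, not only within
single individuals: an allele fixed in another individual is evidence
that a singleton carrying the same base is real.  Without this, the
allele-class differences of a heterozygous individual sequenced at only
two clones would be systematically erased.  Second, all decisions are
computed simultaneously on the input alignment and then applied, which
makes the screen idempotent (retained singletons always retain their
evidence, because mutual variability implies mutual retention).

Masked singletons are *replaced* by the majority base rather than the
column being dropped, and every decision (clone, column, decision,
evidence individuals) is written to the decisions table so the
alternative treatment can be reconstructed.

Representative selection: within each individual×cluster group,
identical corrected sequences collapse to a single record.  A group
with one form and several clones emits a consensus id
`<barcode>-cons.<species>.<locality>` — but only when that id is unique
for the individual (an individual with collapsible groups in two
clusters would collide); otherwise the lowest-numbered member clone
stands for the form under its own id.  A single clone that alone
represents a cluster for its individual is always included.

## Clustering

Paralog clusters are single-linkage agglomerations of gap-excluded
pairwise p-distance cut at 0.10 divergence (default).  At that cut the
clusters equal the connected components of the ≤0.10-distance graph,
which is independent of merge order, so the assignment is deterministic.
Cluster labels C1..Ck follow input order; user-supplied labels (e.g.
Cath1/Cath2/Cath3-A/Cath3-B) are accepted as a TSV.

## Diversity statistics

Per window (default 100 bp with 25 bp step, the profile used for the
published sliding-window figures) and per region the package reports
segregating sites S, nucleotide diversity π (mean pairwise differences
per site), Watterson's θ_W = S/(a₁·sites) with a₁ = Σ_{i<n} 1/i, and
Tajima's D with the standard variance coefficients; D is undefined at
S = 0.  Gap handling is complete deletion per window: any column with a
gap or N in any sequence is dropped, and the retained count is reported
as `n_sites_used`.  Windows with fewer than 10 usable columns are
flagged low-confidence (indel-rich intron 3 would otherwise yield
unstable estimates), and |D| > 2 is flagged as significant, matching
the reporting convention of the original analysis.

Linkage disequilibrium is the classical D′ on haploid clone sequences
with a *count* MAF threshold (e.g. 2 of 22, 3 of 36 haplotypes),
computed over all pairs of strictly biallelic gap-free columns;
sequences with missing data at either site of a pair are dropped
pairwise.  The four-gamete listing reports every biallelic pair showing
all four haplotypes (recombination or recurrent mutation).

## Counting-based codon selection test

A SLAC-style counting test, applied separately to exon 4 (the active
antimicrobial peptide) and exons 1–3 (the conserved cathelin domain):

1. Codons containing a gap/N or stop in any sequence are excluded
   region-wide, so codon 1 is the first *analyzable* codon and every
   retained codon is scored on all sequences.
2. Ancestral codons by Fitch parsimony over the 61 sense codons on the
   supplied tree (NJ by default, external Newick accepted).  Ties take
   the first codon in lexicographic order; the choice is deterministic.
3. Per branch, synonymous/non-synonymous changes are counted by
   Nei–Gojobori pathway averaging over all orderings of the differing
   positions, excluding pathways through stops; s + n equals the
   Hamming distance whenever a legal pathway exists.
4. Expected site counts ES/EN classify each codon's nine single-base
   neighbors (stop neighbors excluded from the numerator and the
   denominator stays 9, so ES + EN ≤ 3), averaged over the codons at
   all nodes, observed and reconstructed, with equal weight.
5. One-tailed probabilities compare n_obs against
   Binomial(n_obs+s_obs, EN/(EN+ES)); the regularized incomplete beta
   function extends the tails to the fractional counts pathway
   averaging produces, preserving p_pos + p_neg ≥ 1.

Flags are emitted at p < 0.05 and at the looser reporting threshold
p < 0.2 used for the published site tables.  Parsimony reconstruction
(rather than ML) is a deliberate simplification: branch lengths from NJ
are approximate anyway, and the counting test is robust to the
reconstruction method at the divergence levels involved.  Because the
binomial tails are discrete and exact, the test is conservative: under
neutral simulation the realized false-positive rate at p < 0.05 sits
at 2–3%, approaching the nominal level as substitution counts per codon
grow; it never exceeds it.

## Trans-species test

The claim "variation clusters by alleles and not by species" is made
quantitative with a permutation test on the Fitch parsimony score of
the *species* labels over the tree.  With a cluster map (the default),
the score is computed on each cluster's subtree and summed; this
matters because paralog clades alone would force species labels to
repeat and masquerade as intermixing.  The emitted quantities:

* `observed_score` and `min_possible` (= Σ per cluster of
  n_species − 1, attained exactly when species are monophyletic within
  every cluster);
* `p_value` = P(null ≤ observed) under label permutation stratified
  within clusters — *small* p means species cluster more than random
  labels, i.e. no trans-species signal;
* the **intermixing index** (observed − min)/(E[null] − min): 0 for
  species monophyly, ≈1 when species labels are as intermingled as
  random, with a bootstrap CI from the permutation draws.

Known limitation: parsimony counts state *changes*, so the most common
species acts as the background state and can span allele classes at no
cost.  Under the study's sampling design (19 of 27 individuals are
Atlantic cod) the index is therefore conservative — balanced data sets
score roughly 0.2–0.7, and a seed where only the majority species
crosses classes can score 0.  The per-cluster species-sharing table
(n_species ≥ 2 flags a cluster as trans-species) complements the index
and matches generator truth exactly in the recovery experiments.

DAPC follows the standard recipe: PCA of the centered one-hot genotype
matrix (one indicator column per site×allele over polymorphic sites),
then linear discriminant analysis on the retained components; the
reproduction profile keeps 10 PCs and 3 discriminant functions.  The
operational contrast is reassignment accuracy: allele-defined groups
separate cleanly (accuracy ≈ 1) while species-defined groups overlap.

## Trees

Neighbor joining (Saitou–Nei, Studier–Keppler Q) on p-distance, with
lexicographic tie-breaking for determinism and negative branch lengths
clamped to zero with a warning; it recovers additive matrices exactly.
Bootstrap support resamples alignment columns (default 100 replicates)
and annotates bipartition frequencies on the point-estimate tree.
External ML trees can be supplied as Newick anywhere a tree is
consumed.

## Synthetic-data generator

The generator encodes the study conditions as defaults:

| parameter | default | rationale |
|---|---|---|
| paralogs G | 3 | three cathelicidin clusters |
| allele classes K | 2 | two deep clades within Cath3 (A/B pattern) |
| species design | 19 Gmo + 2 each Bsa/Gog/Gma/Gch | the published sampling table |
| clones per individual | resampled from the printed column {3,3,3,8,12,…} | published design |
| Ne | 10,000 | stated effective size for Atlantic cod |
| generation time | 5 yr | stated |
| ingroup splits | 8×10⁵ generations (≈4 mya); Gch 7.6×10⁵; Gog–Gma 2×10⁵ | stated divergence times |
| class origin T_anc | 1.6×10⁶ generations | predates every ingroup split (balancing regime ≫ 20·Ne) but postdates the Bsa split, so the outgroup carries private lineages — matching the five a-priori DAPC groups |
| paralog divergence | 1.2×10⁷ generations | yields ~15% between paralogs |
| μ | 6.25×10⁻⁹ /site/generation | chosen so within-class cross-species divergence ≈1% and class divergence ≈2%, the observed 1–3% within-cluster range; no rate is stated for the real genes |
| PCR error rate e | 10⁻³ /site/clone | ≈1.3 singletons per 1.3-kb clone, the magnitude the screening strategy targets |
| paralog dropout | 0.4 /individual | many real individuals show a single gene |
| indels | p=0.4 per class lineage, 5–40 bp, intron 3 only | length variation concentrates in intron 3 |

Sequences evolve by Jukes–Cantor substitution (Poisson counts per
branch) along: duplication → paralog lineages → (outgroup split) →
class origins → the species tree; individuals draw two allele copies
per amplifiable paralog, clones copy one allele and receive Poisson(eL)
uniform errors.  Substitutions in the coding frame that would create a
stop codon are redrawn (functional-gene assumption); PCR errors are
unconstrained.  PCR errors use a dedicated RNG stream so the underlying
library is invariant across error-rate settings, which is what makes
the singleton-count monotonicity experiment well-posed.  The neutral
control reuses the machinery with class origins 5×10⁴ generations ago,
well inside the youngest split, so no class spans species.

What the generator does **not** emulate: recombination and gene
conversion (the real data showed conversion signatures; a tract option
is reserved but off), chimeric PCR artifacts, coalescent variance
within species beyond a single private-mutation draw per allele copy,
multiple-merger genealogies, and alignment error (sequences share a
fixed coordinate frame, so "alignment" is exact by construction).
Passing recovery tests therefore demonstrates the pipeline's logic
under the intended data-generating model, not robustness to alignment
or conversion artifacts in real libraries.

The codon-level generator is separate: codon sequences evolved on a
balanced 64-taxon tree (branch length 0.08 substitutions/site) with
relative non-synonymous rate ω, stop codons rejected; ω > 1 thins
synonymous events by 1/ω.  The depth gives ~14 substitutions per codon
— enough information for the counting test to hold its size (type-I
2–3% at nominal 5%) and to recover 70–90% of ω=5 codons at p < 0.2.

## Numerical choices and degenerate inputs

* All internal coordinates are 0-based half-open; user-facing tables
  are 1-based inclusive.
* Deterministic tie-breaks throughout: lexicographic label pairs (NJ),
  first-in-sorted-order states (Fitch), alphabetical major allele at
  frequency ties (D′), first-appearance cluster naming.
* D′ at D = 0 is defined as 0; p-distance pairs with no comparable
  columns raise, except inside bootstrap replicates where the pair gets
  the replicate's maximum distance to keep the replicate usable.
* Tajima's D is NaN at S = 0 and flagged, never silently zero.
* Annotation projection assigns insertion columns to the region of the
  preceding reference base (leading insertions to the first region).

## Problem sizes

The test suite and the acceptance script run the full library pipeline
at the study scale (27 individuals, ~100 clones, 1.3 kb), 20 seeds for
the recovery experiment, 499–999 permutations for the trans-species
test, and 200-codon scans for the selection-test calibration; one full
pipeline pass takes a few seconds on one CPU.
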