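# transpoly

Analysis of **trans-species polymorphism** in PCR-cloned gene-family
sequence data, built around the cathelicidin antimicrobial-peptide
genes of Atlantic cod (*Gadus morhua*) and its sister gadids.  When a
single primer pair amplifies several paralogs and deeply diverged
allelic classes, the raw clone library mixes paralogy, allelic
variation and PCR error; the hallmark of long-term balancing selection
is that, within each paralog, sequences cluster by *allele* rather than
by *species* — allelic lineages older than the speciation events,
as in human/chimpanzee MHC.

The package is for population geneticists working with clone libraries
(or any small haploid alignment) who need that whole chain as tested,
scriptable pieces:

1. **seqio** — aligned FASTA with structured clone ids
   (`<barcode>-<clone>.<species>.<locality>`, e.g. `105746-3.Gmo.Gre`),
   exon/intron annotations projected onto alignment columns.
2. **screen** — the singleton PCR-error screen: a variant private to
   one clone of an individual is masked unless it recurs in another
   individual's clones of the same cluster; identical corrected
   sequences collapse to one representative per individual×cluster.
3. **trees** — p-distance, deterministic neighbor joining, bootstrap
   support, Fitch parsimony, Newick I/O (dendropy containers).
4. **popgen** — π, Watterson's θ_W and Tajima's D
   (D = (π − S/a₁)/√(e₁S + e₂S(S−1))) in 100-bp/25-bp sliding
   windows, plus the four-gamete test.
5. **ld** — pairwise D′ (D normalized by its frequency bound) with
   count-based MAF filters (2/22-, 3/36-style).
6. **codon** — SLAC-style counting test per codon: Fitch ancestral
   codons, Nei–Gojobori pathway counts (s, n), expected sites (ES, EN),
   dN − dS with one-tailed binomial probabilities.
7. **transpecies** — the quantitative allele-vs-species test: species-
   label parsimony vs a within-cluster permutation null (intermixing
   index: 0 = species-monophyletic, ≈1 = fully intermixed), per-cluster
   species sharing, and DAPC (PCA + LDA, 10 PCs / 3 discriminant
   functions) contrasting allele- vs species-defined groups.
8. **simulate** — a generator with known truth: G paralogs, K balanced
   allele classes predating the species splits, the published sampling
   design (27 individuals, clone counts resampled from the printed
   table), intron-3 indels and per-clone Poisson PCR errors; plus a
   neutral control and a codon-level ω simulator.

## Worked example

Simulate a balanced clone library and run the whole pipeline:

```bash
transpoly simulate --seed 7 --out demo/sim
transpoly run-all --aln demo/sim/clones.fasta \
    --annotation demo/sim/annotation.tsv --out-dir demo/run --seed 7
```

Output (abridged `summary.json`):

```json
{
 "n_clones_in": 91,
 "n_representatives": 52,
 "n_clusters": 3,
 "n_masked": 109,
 "n_retained_snps": 341,
 "transpecies": {
  "observed_score": 13,
  "min_possible": 9,
  "p_species_clustered": 0.001,
  "intermixing_index": 0.529
 },
 "dapc": {
  "accuracy_alleles": 1.0,
  "accuracy_species": 0.923
 }
}
```

Reading it: the 91 clones fall into 3 clusters (the paralogs); 109
clone×column singletons were masked as PCR errors and 341 retained as
recurrent real SNPs, leaving 52 representative forms.  The species-
parsimony score (13) exceeds its species-monophyletic minimum (9) —
species labels are intermingled within allele clades (intermixing index
0.53) — and DAPC reassigns every sequence correctly when groups are
allele clusters but misplaces 8% when groups are species: variation
clusters by allele, not by species.  `windows.tsv` holds the sliding
π/θ/D profiles per cluster (the deep-class cluster peaks at
Tajima's D > 2 in exon 4, the balancing-selection signature);
`ld.tsv` and `codon_exon4.tsv`/`codon_exons123.tsv` hold the D′ pairs
and the per-codon selection table.

Every stage is also a library call (`transpoly.screen.screen_singletons`,
`transpoly.popgen.sliding_windows`, …) and a subcommand
(`transpoly {simulate,screen,popgen,ld,selection,transpecies,dapc,run-all}`),
all seeded.

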