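# Methods

This note documents the models, parameters and numerical choices behind
`radintro`, in the order data flows through the package.

## 1. Synthetic ddRAD data (`radintro.simulate`)

**Model.** A rooted, ultrametric species tree with branch durations in
coalescent units (2N generations); per-branch population-size variation is
absorbed into durations, so within every branch each pair of lineages
coalesces at rate 1. Sampling is diploid: a species with s individuals
contributes 2s haploid lineages. Gene trees are simulated per locus by an
event-driven structured coalescent: populations (one per active species
branch) coalesce independently between events; at a species-tree node the
children's surviving lineages merge into the parent branch; at an
admixture pulse (donor, recipient, time t, proportion γ) each lineage
present in the recipient at t independently reassigns to the donor branch
with probability γ. This instantaneous-pulse semantics matches the
discrete introgression events the D-statistic targets, as opposed to
continuous migration. A gene tree is flagged *introgressed* when at least
one lineage reassigned; the flag is the per-locus ground truth used by the
binning experiment.

Diploidy matters for pulse interpretation: a recipient species with one
individual carries two lineages, so the fraction of loci with introgressed
provenance is 1 − (1 − γ)² (≈ 0.51 at γ = 0.3) when the pulse is very
recent, falling toward γ as the pulse moves rootward past the within-
individual coalescence.

**Sequences.** Jukes–Cantor, simulated exactly per branch: a site changes
with probability (3/4)(1 − e^(−4θt/3)) over a branch of duration t, where
θ is the expected number of substitutions per site per coalescent unit
(default 0.01). Root composition is uniform. Loci are 87 bp by default —
the post-barcode fragment length of single-end ddRAD reads — and
heterozygous sites arise naturally when an individual's two haplotypes
differ. Optional single-column gap events (rate per locus) exist solely to
exercise the indel filter.

**Missingness.** Each (individual, locus) cell survives with probability
(1 − p₀) · e^(−r·d), where p₀ is a uniform per-individual dropout, r the
divergence-dropout rate and d the true-tree path distance between the
individual and a reference individual — gene-tree distance per locus when
available (so locus loss varies across the genome), species-tree distance
otherwise. No quantitative missingness model exists for restriction-site
loss at this scale; the exponential-in-distance form is this package's
choice, designed to reproduce the qualitative signature that missingness
rises with phylogenetic distance from the reference. What passing tests
show is therefore that the pipeline is robust to *this* structure of
missingness, not to every real-data artifact (batch effects, allele
dropout within loci, and coverage-dependent genotyping error are not
modeled).

**Seeding.** One master seed; per-locus RNG streams are spawned
deterministically (`SeedSequence([seed, stage])`), so identical seeds give
byte-identical datasets and downstream outputs, and gene-tree and sequence
randomness never alias.

## 2. Locus filtering (`radintro.filtering`)

Rules run sequentially, each seeing the previous rule's survivors, with
per-rule removal counts: (i) any individual consensus with more than 10
heterozygous sites (paralog signature), (ii) more than 2 haplotypes per
individual (only possible for malformed input under the diploid
representation; kept as a validation hook), (iii) any site heterozygous in
more than 75% of the individuals with data there (missing individuals are
excluded from the denominator), (iv) fewer than `min_polymorphic_sites`
polymorphic sites and/or indel-containing loci (both default off; 2 and on
for the stricter "s2" runs), (v) locus present in fewer than 50% of
individuals, then individuals missing more than 80% of surviving loci are
dropped. Read-depth filtering belongs to assembly and is out of scope.
The order of rules is a declared package convention (it affects only the
attribution of removals, not the surviving set, except that the individual
rule runs last); filtering is idempotent and monotone in each threshold,
and both properties are tested.

Unlinked-SNP extraction takes exactly one site per locus among sites with
exactly two called alleles (multi-allelic sites are never eligible, as
downstream pattern and quartet methods assume biallelic input), first or
seeded-random; heterozygotes are written as IUPAC ambiguity codes.

## 3. Patterson's D (`radintro.dstat`)

D = (ABBA − BABA)/(ABBA + BABA) with the outgroup allele defining the
ancestral state. Two counting modes:

* `sampled` (default): one allele per taxon per site, drawn uniformly from
  the haplotypes of the taxon's individuals present at the locus; a site
  counts only if all four draws are called and form an ABBA or BABA
  pattern (biallelic by construction). Batteries permute single
  individuals per taxon, so within a battery the draw reduces to picking
  one of the chosen individual's two haplotypes.
* `frequency`: per site, weights (1−p₁)p₂p₃(1−p₄) and p₁(1−p₂)p₃(1−p₄)
  with p the derived-allele frequency per taxon; sites with more than two
  alleles across the four taxa are skipped. This mode is exactly
  antisymmetric under P1↔P2 (tested).

`nloci` counts loci contributing at least one ABBA or BABA site. The
bootstrap resamples those informative loci with replacement (n = 1000 by
default), recomputing D from resampled totals; Z = |D_obs|/SD(bootstrap),
p from the two-sided normal tail. A degenerate bootstrap (SD = 0) maps to
Z = 0 when D_obs = 0 and Z = ∞ (p = 0) otherwise; fewer than two
informative loci is an uninformative result, excluded from battery
summaries and from nSig/ntest (but counted). Holm–Bonferroni (α = 0.01)
is applied per battery — the family is the set of permutations of one
hypothesized event, not the global collection of batteries.

`split_by_geography` reports per-region mean/variance of per-individual D
and flags a recommended split when the variance of region means exceeds
2× the mean within-region variance (configurable); the split decision
stays with the analyst, since no principled threshold exists for
"elevated" variance.

## 4. Tree inference (`radintro.trees`)

Concatenation is represented by neighbor joining on uncorrected
p-distances of the pooled diploid-consensus alignment; MSC inference by
dominant-quartet assembly over per-locus (or per-bin) trees. These
stand-ins are deliberate: the package studies the contrast between
inference families (pooled sites vs per-locus votes), and simple
deterministic engines make every stage exactly testable. Likelihood/MCMC
engines would change support values, not the direction of the contrast.

Details: p-distance counts a heterozygote against a matching homozygote as
half a difference (IUPAC sets: equal → 0, overlapping → 0.5, disjoint →
1), excluding N and gaps pairwise and raising on pairs with no comparable
site. NJ uses the classical Q-criterion with ties broken toward the
lexicographically smallest cluster-representative pair and negative branch
lengths clamped to zero with the deficit moved to the sister branch
(consistency on additive matrices is property-tested, and topologies are
cross-checked against scikit-bio's NJ). Quartet assembly tallies each
species quartet's induced resolution across gene trees, takes the
dominant resolution, and searches topologies exhaustively up to 8 species
(greedy pair-joining beyond); node support is the mean frequency of the
tree's own induced resolution over the quartets spanning that edge, in
percent. Bootstrap support for concatenation resamples sites or whole
loci; for binned runs, bins ("genes") are resampled and the quartet
assembly redone (n = 128 by default). Robinson–Foulds distance is the
symmetric difference of canonical bipartition sets (cross-checked against
dendropy).

## 5. Naïve binning (`radintro.binning`)

Loci are partitioned uniformly at random (seeded) into bins of size k from
the grid {1, 2, 3, 5, 10, 20, 50, 100}; a remainder forms one final
smaller bin (or is discarded by flag — the choice is immaterial to the
statistics and the default keeps all data). Each bin's concatenated
alignment gets an NJ tree; the trees vote in the quartet assembly. k = 1
reproduces the unbinned per-locus pipeline bit-for-bit given the same
seed.

**The canonical bias experiment** uses ((X,(A,(B,C))),O) with heights
(coalescent units) B∨C = 1, A joins at 6, X at 9, the root with O at 13,
a pulse X→A at t = 2.0, and θ = 0.05. The geometry is chosen so that
(a) non-introgressed loci resolve A with (B,C) reliably at the per-locus
level (the species-side internal branch of 3 units carries ~13 expected
supporting mutations per 87 bp locus), and (b) introgressed loci share a
~6.5-unit stem with X (~28 supporting mutations), so a mixed supergene is
dragged toward the A+X grouping. The pulse depth lets the recipient's two
lineages usually coalesce before the pulse, making loci all-or-none
introgressed; with a very recent pulse, "half-introgressed" diploid
consensus rows vote for A+X even at k = 1 and the species-side majority
collapses. At γ = 0.3 the recovered topology is the species tree at k = 1
and the introgressed tree from k = 5 upward (all seeds tested); the
package asserts only this monotone directionality, not a particular
switch point, which is data-dependent. Reported per-class mutation counts
are sites whose derived allele (vs O) is carried by exactly {A, X} or
exactly {A, B, C}.

## 6. Formats and configuration (`radintro.io`, `radintro.config`)

`.loci` blocks (name + IUPAC consensus per individual, `//` separators
with trailing markers tolerated), relaxed Phylip with a `.partitions`
sidecar so locus boundaries and missingness round-trip losslessly, and
per-locus FASTA (two records per individual — the only phase-preserving
dialect; `.loci`/Phylip round-trip at genotype level, since consensus
coding discards phase). Site indices are 0-based half-open internally,
1-based in reports; gaps ('-') are distinct from missing ('N'); loci are
unanchored and strand is not modeled. Run configuration is a flat YAML
mapping validated against a closed key set, with package defaults
α = 0.01, n_boot = 1000, θ = 0.01, locus_length = 87, the k-grid above and
the filter defaults of §2; every run can log its resolved configuration
and seed for replay.

## 7. Problem sizes in the shipped checks

The test suite runs the pipeline at sizes chosen as the smallest that make
each property statistically decisive: 12,000 gene trees for the
(1/3)e^(−T) discordance law (3 Monte-Carlo SE), 10⁵ sites for the JC
p-distance law, 1,000 loci / ~200 permuted tests / 200 bootstrap
replicates for type-I calibration (bound 0.01 + 3 binomial SE), 2,000 loci
for power and for each of 10 seeds of the binning scan, and ≥100 random
fixtures per brute-force oracle comparison.

## 8. Known limitations

Jukes–Cantor only (no rate variation or richer substitution models);
instantaneous pulses only (no continuous migration); NJ/quartet stand-ins
rather than likelihood engines; quartet assembly expects one tip per
species per gene tree (individuals are mapped to species before
tallying); no VCF/BAM input; no read-level simulation (coverage,
duplicates, restriction digestion); partitioned-D / D_FOIL-style
directionality tests are out of scope.
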