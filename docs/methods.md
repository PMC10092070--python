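# Methods

## The problem

Microbial model strains are traditionally the species' *type strains* —
the first deposited isolates — which need not be genomically or
ecologically representative of the strains an environment actually
carries. `strainref` implements an alternative, data-driven designation
for a metagenome collection (the motivating setting is bifidobacteria in
the infant gut): pick, per species, the strain that is simultaneously
genomically central within its clade and prevalent across the collection,
then find the closest usable stand-in inside a local biobank.

## Strain databases from canonical k-mers

Every genome is reduced to the set of its canonical k-mers (default
k = 23, odd so that no k-mer equals its own reverse complement; the
canonical form is the lexicographic minimum of a k-mer and its reverse
complement, and windows containing N are skipped). Genome quality gates
precede profiling: coverage strictly above 30× when a coverage estimate
exists (MAGs without one are not penalized) and strictly fewer than 100
contigs.

Redundancy between assemblies is measured by Jaccard similarity of the
k-mer sets. Deduplication is a greedy pass in a deterministic priority
order — fewest contigs, then largest total length, then strain id — that
drops a genome when its Jaccard similarity to an already-kept genome
reaches 0.99. The survivors are grouped by single-linkage connected
components over edges with Jaccard > 0.90, and the same contiguity
priority picks each cluster's representative. Both thresholds refer to
Jaccard similarity; a containment variant (fraction of the candidate's
k-mers present in the kept genome) is available through
`deduplicate(mode="containment")` for collections with very uneven genome
sizes. Interpretation note: under the substitution-only model below, a
per-base divergence d leaves an expected shared-k-mer fraction of about
(1−d)^k, so the 0.99 dedup cutoff corresponds to well under 0.05%
divergence at k = 23 — only near-identical assemblies collapse.

## Strain detection and prevalence

A metagenomic sample is likewise reduced to a canonical k-mer set. The
detector is a deliberately simple greedy set-cover: each round scores
every database strain by the fraction of its k-mers present in the
*remaining* sample set, reports the best strain if that fraction is at
least 0.90, removes its k-mers, and repeats (at most 5 rounds, ties by
strain id). This stands in for fingerprint-based strain trackers: it is
fully specified, deterministic and testable, but it shares their
limitation that after subtraction a second, closely related strain in the
same sample loses the shared fraction of its k-mers and can fall below
the threshold. Co-detection therefore requires strains sharing less than
about 10% of their k-mers (given the 0.90 threshold).

Prevalence of a strain is the fraction of all collection samples with at
least one detection; strains at or below 0.1% prevalence are dropped
(strict inequality, as are all cutoffs in this package whose definition
is "greater than"). Collection-level helpers implement the ecological
filters: core species (detected in >10% of samples and mean relative
abundance >0.5%, means taken over all samples including zeros),
genus-rich sample selection (genus relative abundance >10%), and the
per-cohort summary table with percentages rounded to two decimals.

## Fragment ANI

ANI follows the fragment (ANIb-style) convention, fully specified so a
global-alignment oracle can reproduce it: the query is cut into
non-overlapping 1,000-bp windows; each window is anchored on the target
by exact 15-mer seeds (sampled every 10 bp, modal offset wins, repeat
seeds capped at 8 target positions) and aligned locally against the
anchored target window plus a 60-bp margin, with match +1, mismatch −1,
gap open −5, gap extend −2 (Biopython convention: the first gap position
costs the open score). A fragment is accepted when its alignment identity
(identities over alignment columns, gaps included) is ≥ 70% across ≥ 70%
of the fragment length. The directional ANI is the mean identity of
accepted fragments; the reported ANI averages the two directions, using a
single direction if only one accepts fragments and NA if neither does —
NA is the expected outcome for genomes from different species-level
clades, not an error.

## Hierarchical clustering of the ANI matrix

The per-species ANI matrix is clustered agglomeratively with complete
linkage by default (scipy), on one of two distances: 1 − Pearson
correlation between the strains' ANI-profile rows (default; rows with
zero variance fall back to 0 for identical rows, else the maximal
distance 2), or the direct complement (100 − ANI)/100. Leaves are sorted
lexicographically before clustering so ties resolve deterministically. NA
pairs are imputed to the minimum observed off-diagonal ANI, with a
logged warning — adequate when NAs are rare within a species, misleading
if the matrix mixes clades, which is why the pipeline builds one matrix
per species. Trees serialize to newick with branch lengths equal to
height differences; cutting at height h groups strains whose cophenetic
distance is ≤ h, with cluster ids ordered by the smallest member strain
id. The default cut height of 0.05 correlation distance is a pragmatic
choice exposed as a parameter; no canonical value exists for it.

## The A×P index and designation

For each strain, `cluster_mean_ani` is the mean ANI (as a fraction)
between the strain and the other members of its cluster; a singleton
cluster scores 1.0 so that isolated but prevalent strains remain
scoreable. An all-pairs cluster mean is available as an option since the
phrase "average ANI of the cluster" admits both readings. The A×P index
is cluster-mean-ANI × prevalence × 100 with both operands as fractions,
so it lives on a 0–100 scale; percent-scale prevalence inputs can be
divided down on ingest. Per species, the strain with the highest A×P is
designated the in-silico reference (ties by strain id), and a flagged
type strain's score can be surfaced alongside for comparison.

## Biobank screening (ANI × Average_PPOS)

A local candidate is compared to its species' designated reference by
ANI (percent) and by proteome similarity. Protein pairs are aligned
locally under BLOSUM62 with BLAST-style gap costs 11/1 (a gap of length L
costs 11 + L, i.e. open −12 / extend −1 in Biopython's convention). PPOS
of one alignment is 100 × (identical pairs + positive-scoring
non-identical pairs) / alignment columns. Average_PPOS averages PPOS over
bidirectional best hits by alignment score (ties by protein id) — the
standard symmetric orthology proxy; averaging over one-directional or
all hits is deliberately not offered because BBH is the only symmetric
choice. The final score is ANI × Average_PPOS with a default pass
threshold of 9600. The threshold is kept at 9600 even though 98 × 98 =
9604; it is exposed as a parameter rather than resolved. Proteins can be
supplied as FASTA (preferred, e.g. from a real annotation pipeline) or
called naively: maximal ATG-to-stop ORFs of ≥ 300 nt on all six frames —
a deliberately simple caller that ignores alternative starts, operon
structure and genetic-code variants, sufficient for similarity screening
between close strains.

## Transcriptome response summary

RPKM = numReads / (geneLength/1000 × totalNumReads/1e6). Fold change per
gene is (RPKM_test + c) / (RPKM_control + c) with pseudocount c = 0.01
RPKM (configurable); genes with zero counts in both conditions are
excluded, and the pseudocount keeps zero-control genes finite. Responses
are binned as >3, >5 (strict) and <0.25 (strict), ≤0.5 (inclusive,
matching the published table's headers), so the up bins nest (>5 ⊂ >3)
as do the down bins. The up/down ratio is n(>5)/n(<0.25), reported to
four decimals, 0 when nothing is up-regulated, NA when the denominator is
zero. No differential-expression statistics are attempted — the summary
reproduces threshold counts, not hypothesis tests.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of parameters + seed (numpy
`default_rng`). Genomes are i.i.d. single-contig sequences with a
specified GC content; derived strains apply independent per-base
substitutions (to a different base), so the true identity to the
ancestor is exactly 1 − realized substitutions / length — this is what
makes the ±0.3 ANI-recovery check an oracle rather than a regression
test. No indels, rearrangements, gene gain/loss or repeat structure are
simulated; real assemblies would add alignment gaps, fragment rejections
and repeat-induced seed ambiguity that these tests do not exercise.

Samples are unions of the present strains' k-mer sets plus uniformly
random decoy canonical k-mers (5% of the union by default) — decoys only
add k-mers, so planted strains always retain match fraction 1.0;
sequencing error, coverage dropout and abundance-dependent k-mer loss
are not modeled. The planted collection uses 3 species × 4 strains at
divergences 0.005/0.02/0.03/0.05 from each species ancestor with planted
prevalences 0.60/0.15/0.10/0.05 across 50 samples, at most one strain
per species per sample (the locally dominant strain, matching how the
detector and MAG-based collections behave); the first strain is both
genomically central and most prevalent, so it is the expected
designation. Count tables draw Poisson counts around a base mean of 500
with planted fold factors; library totals are the column sums, so
realized fold changes carry the resulting global normalization factor —
planted effects (8× up, 0.1× down) are chosen far enough from the bin
edges that recovery is exact at this depth.

Problem sizes used by the recovery suites: 50-kb genomes with 10
replicates per divergence for ANI recovery; 15-kb genomes, 12 strains,
50 samples and 20 seeds for the end-to-end designation rate. These sizes
keep the pairwise-alignment load modest while leaving every statistical
conclusion unchanged in kind.

## Numerical and degenerate-input choices

- All "greater than" thresholds are strict; boundary values (coverage
  exactly 30×, 100 contigs, prevalence exactly 10%, fold change exactly
  5) fall on the excluded side, except ≤0.5 which is inclusive by its
  definition.
- Jaccard of two empty profiles and PPOS of a zero-length alignment are
  errors, not 0; an empty detection list and an empty ORF set are valid
  results.
- Dedup/representative priority and all ranking ties are resolved by
  strain id, making every pipeline output deterministic for a fixed
  input order-independently.
- The 2-leaf correlation-distance tree is degenerate (a 2×2 ANI matrix
  has perfectly anticorrelated rows); use the `ani_complement` distance
  for tiny matrices.

## Known limitations

- The greedy detector understates co-occurring near-identical strains
  (see above); its defaults make no claim to reproduce fingerprint-based
  tools' strain lists.
- ANI seed-and-extend assumes collinear, substitution-dominated
  divergence; heavily rearranged genomes would lose fragments to
  anchoring failures before alignment quality mattered.
- The published designations for the real infant-gut collection depend
  on 1664 external metagenomes and private biobank genomes and are out
  of reach of this package's test data; the package reproduces the
  arithmetic and the method, not those designations.
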