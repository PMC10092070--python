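# strainref

Data-driven selection of microbial reference strains from strain-level
metagenomics.

Type strains — the first deposited isolates that carry a species' name —
are often poor stand-ins for the strains that actually dominate an
environment. `strainref` implements an ecology- and genomics-driven
alternative for a genome collection profiled against a metagenome
collection (the motivating setting is *Bifidobacterium* in the infant
gut, but nothing is genus-specific):

1. **k-mer strain databases** (`kmerdb`): genomes pass quality gates
   (coverage > 30×, < 100 contigs), are reduced to canonical k-mer sets
   (k = 23), deduplicated at Jaccard ≥ 0.99 and grouped into
   single-linkage clusters at Jaccard > 0.90 with one representative
   each.
2. **Strain profiling** (`strain_profiler`): greedy iterative detection
   of database strains in sample k-mer sets (match fraction ≥ 0.90),
   prevalence across the collection (> 0.1% retained), plus the
   collection-level filters: core species (prevalence > 10% and mean
   abundance > 0.5%), genus-rich sample selection (> 10%), cohort
   summary tables.
3. **ANI and hierarchical clustering** (`ani_phylo`): fragment ANI
   (1,000-bp windows, 70%/70% identity/coverage acceptance,
   bidirectional mean) and agglomerative clustering of the per-species
   ANI matrix (complete linkage on correlation or ANI-complement
   distance), cut into clusters ("HCLs").
4. **A×P designation** (`axp_selector`): per strain,

   A×P = (mean ANI to the strain's HCL co-members, as a fraction)
   × (collection prevalence, as a fraction) × 100,

   and per species the strain with the highest A×P becomes the
   in-silico reference strain (RefBif-IS).
5. **Biobank screening** (`local_selector`, the RefBifSelector method):
   a local candidate versus its species' reference scores
   ANI × Average_PPOS, where PPOS = 100 × (identical + positive-scoring
   matches)/alignment length under BLOSUM62 (gap 11/1) and Average_PPOS
   averages over bidirectional best hits; candidates with score ≥ 9600
   pass, and the best passing one is the in vitro stand-in.
6. **Transcriptome response** (`transcriptome`): RPKM
   (= reads/(length/1000 × total/1e6)) fold-change bins (>3, >5, <0.25,
   ≤0.5) and the up/down ratio n(>5)/n(<0.25).
7. **Synthetic data** (`synthetic`): seeded generators for every input —
   genomes, derived strains at known divergence, metagenome k-mer
   samples with planted prevalences, count tables with planted
   regulation — so the whole pipeline runs and is tested with no
   downloads.

## Worked example

Simulate a collection with a planted answer (3 species × 4 strains at
0.5–5% divergence from each species ancestor, planted prevalences
0.60/0.15/0.10/0.05 across 50 samples) and run the full designation:

```python
from strainref import simulate_collection, designate_reference_strains

coll = simulate_collection(seed=7)
result = designate_reference_strains(
    coll.genomes, coll.samples, distance="ani_complement", cut_height=0.06
)
print(result.report.designated)
for s in result.report.rankings["species1"]:
    print(s.strain_id, s.cluster_id, round(s.cluster_mean_ani, 4),
          s.prevalence, round(s.axp, 3))
```

prints

```
{'species1': 'sp1_s1', 'species2': 'sp2_s1', 'species3': 'sp3_s1'}
sp1_s1 species1:HCL1 0.9688 0.64 62.001
sp1_s3 species1:HCL1 0.9568 0.14 13.395
sp1_s2 species1:HCL1 0.9617 0.1 9.617
sp1_s4 species1:HCL2 1.0 0.0 0.0
```

Reading the ranking: `sp1_s1` sits in the main cluster with a 96.88%
mean ANI to its co-members and was detected in 64% of the samples, so
A×P = 0.9688 × 0.64 × 100 ≈ 62.0 — the top score, and indeed the planted
central, prevalent strain. The divergent outlier `sp1_s4` forms a
singleton cluster (mean ANI 1.0 by the self-identity convention) but was
detected in no sample, so its A×P is 0.

The same flow is available from the shell:

```sh
strainref simulate collection --seed 7 --out sim/
strainref build-db --genomes sim/genomes --metadata sim/genomes/metadata.tsv --out db.txt
strainref profile --db db.txt --samples sim/samples --out detections.tsv
strainref ani --genomes sim/genomes --metadata sim/genomes/metadata.tsv --out ani.tsv
strainref hcl --matrix ani.tsv --distance ani_complement --cut 0.06 \
          --newick tree.nwk --clusters clusters.tsv
strainref axp --matrix ani.tsv --clusters clusters.tsv \
          --prevalence detections.tsv.prevalence.tsv \
          --metadata sim/genomes/metadata.tsv --out report.tsv
```

plus `select-local` (biobank screening) and `transcriptome` (response
summaries).

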