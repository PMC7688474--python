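# ribotax

Species-level taxonomic assignment from 16S rRNA amplicon data.

16S hypervariable regions often cannot tell closely related species apart.
`ribotax` makes that limitation explicit instead of guessing: it re-annotates
heterogeneous reference lineages against a canonical taxonomy, builds a
per-species consensus model of each hypervariable region, links species whose
consensus sequences share ≥ 99% identity into **homologous species groups**
(connected components of the similarity graph), and reports reads that land in
such a group under the group label (top-strain member's name suffixed `+`)
rather than an arbitrary member species. Genus-level calls come from a
from-scratch naive Bayesian 8-mer classifier with bootstrap confidence;
species-level calls from a nearest-neighbor search against the consensus
database gated by strict >97% identity and an e-value surrogate.

A synthetic-data module generates everything the pipeline consumes (toy
taxdump, references with planted homologous groups, rank-abundance
communities, error-bearing paired reads with ground truth), so the whole
pipeline runs and is tested without any downloads.

## Layout

| module | role |
|---|---|
| `ribotax.taxonomy` | taxdump loading, lowest-rank lineage re-annotation, Escherichia/Shigella merge |
| `ribotax.reference_io` | FASTA/GFF3 I/O, 16S extraction from genomes, length/ambiguity QC |
| `ribotax.amplicon_regions` | degenerate-primer matching (edit distance, 20% budget), region extraction |
| `ribotax.read_preprocess` | paired-end merging by overlap (min 20 / max 300 bp), merged-read QC |
| `ribotax.consensus_groups` | Needleman–Wunsch scorer (affine gaps, free end gaps), star MSA, plurality consensus, ≥99% similarity graph, homologous species groups |
| `ribotax.nb_classifier` | naive Bayes 8-mer genus classifier, bootstrap confidence, JSON model |
| `ribotax.otu_cluster` | greedy 99%-identity OTU clustering, OTU tables, taxonomic separability |
| `ribotax.species_assign` | k-NN (k=1) species assignment with identity/e-value gates and group labels |
| `ribotax.pipeline` | end-to-end orchestration and composition profiles |
| `ribotax.synthetic_data` | seeded generators for all inputs + ground truth |

## CLI

Every stage is a subcommand of `ribotax` (also `python -m ribotax.cli`):

```bash
# generate a complete synthetic dataset with ground truth
ribotax simulate --out-dir data --seed 1 --n-reads 2000

# reference preparation
ribotax reannotate --nodes data/nodes.dmp --names data/names.dmp \
    --lineages data/lineages.tsv --fasta data/references.fasta \
    --out reannotated.tsv
ribotax extract-region --fasta data/references.fasta --out regions.fasta
ribotax build-consensus --fasta regions.fasta --lineages reannotated.tsv \
    --out consensus.fasta
ribotax build-groups --consensus consensus.fasta \
    --out-groups groups.tsv --out-edges edges.tsv
ribotax train --fasta data/references.fasta --lineages reannotated.tsv \
    --out model.json

# profile paired-end samples
ribotax profile --sample s1:data/reads_R1.fastq:data/reads_R2.fastq \
    --model model.json --consensus consensus.fasta --groups groups.tsv \
    --region-mean 400 --region-sd 5 --out-dir results/

# extract 16S genes from an annotated genome; measure separability
ribotax extract-16s --gff genome.gff --genome genome.fasta --out sixteens.fasta
ribotax separability --fasta regions.fasta --lineages reannotated.tsv --rank species
```

Defaults follow the published pipeline settings: V3–V4 primers
337F `CCTACGGGAGGCWGCAG` / 806R `GACTACHVGGGTMTCTAAT` at a 20% primer error
budget, merge overlap 20–300 bp, merged-read stats 421 ± 11 nt, OTU threshold
0.99, grouping threshold 99%, species gate >97% identity and e-value < 1e-10,
bootstrap confidence threshold 0.8.

## Notes on determinism

All randomness flows through explicit seeds (`--seed` on the CLI, `seed=`
arguments in the API); fixed seeds give byte-identical outputs. Alignment
tie-breaking is deterministic: among score-optimal alignments the one with the
most identical columns (then fewest columns) is reported.
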