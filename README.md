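# phyloconflict

A post-assembly phylogenomics toolkit for target-enrichment (HybSeq)
datasets: sequence- and gene-level quality filters, protein-guided codon
alignment processing, gene-tree sanitation, gene-tree/species-tree
concordance and conflict tallies, quartet-frequency and monophyly analysis,
partitioned supermatrix construction, and a multispecies-coalescent (MSC)
gene-tree simulator for generating test data with known structure.

Alignment (MAFFT) and tree inference (RAxML/IQ-TREE/ASTRAL) are deliberate
external hand-off points: the package consumes aligned proteins, unaligned
CDS, and pre-built newick trees, and never shells out to inference binaries.

## Modules

| module | what it does |
|---|---|
| `treemodel` | newick I/O, outgroup rooting, clade/bipartition machinery, tree depth |
| `seq_qc` | recovery matrix, short-sequence filter (< 25% of target), sparse-gene filter (< 15 sequences), chimeric reference targets |
| `codon_align` | stop-codon masking (`*` → `X`), codon threading of CDS onto protein alignments, occupancy-based column trimming (< 50%, codon-atomic) |
| `genetree_qc` | branch-length outlier flags (25% / 50% / 75% of tree depth for terminal / internal / outgroup branches), support collapse (< 33%), leaf pruning, outgroup-rooting filter |
| `concordance` | per-node four-way tallies (concordant / top alternative / other conflict / uninformative) of rooted gene trees against a rooted species tree |
| `quartet_analysis` | relative quartet-topology frequencies around focal branches, polytomy flagging, per-group monophyly categories |
| `supermatrix` | concatenation with per-gene × codon-position partitions, RAxML partition files, variable-site and gap statistics |
| `synthetic_data` | MSC gene-tree simulator (taxon dropout, support models, anomaly-zone scenarios) and toy codon fixtures with exactly planted filter targets |
| `pipeline` | config-driven driver chaining the stages, with per-decision logging and a consolidated JSON report |
| `plotting` | optional matplotlib pies/bars for the concordance and quartet outputs |

## CLI

Every stage is a subcommand of `phyloconflict`:

```bash
# simulate 500 MSC gene trees on a species tree in coalescent units
phyloconflict simulate --species-tree "((A:1,B:1):0.5,(C:1,D:1):0.5);" \
    --n-trees 500 --dropout 0.1 --seed 7 --out genetrees.nwk

# filters and alignment processing
phyloconflict qc-seqs --proteins proteins/ --targets targets.tsv --out qc/
phyloconflict thread --proteins gene1.faa --cds gene1.fna --out gene1.codon.fna
phyloconflict trim --alignment gene1.codon.fna --out gene1.trimmed.fna

# gene-tree QC, rooting, conflict analysis
phyloconflict tree-qc --trees genetrees.nwk --collapse 33 --out collapsed.nwk
phyloconflict root --trees collapsed.nwk --outgroups O1,O2 --out rooted.nwk
phyloconflict concord --species-tree species.nwk --trees rooted.nwk \
    --min-support 50 --out concordance.tsv
phyloconflict quartets --trees rooted.nwk --groups quartet.json --out freqs.tsv
phyloconflict monophyly --trees rooted.nwk --groups genera.json --out mono.tsv

# supermatrix
phyloconflict supermatrix --alignments trimmed/ --out matrix/

# everything from one YAML config
phyloconflict run --config run.yaml
```

`run.yaml` keys mirror `pipeline.RunConfig` (paths, thresholds, outgroups,
seed); see its docstring for the full schema.

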