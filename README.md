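# isoswitch

Splicing-aware analysis of time-course transcriptomics data: detection and
scoring of isoform-switch (IS) events, total-isoform-usage clustering,
splicing-factor co-expression and PSSM motif enrichment, plus a
ground-truthed count simulator and a precision/recall benchmarking harness.

An IS event is a change of a gene's predominant isoform over time, visible as
a crossing of two isoforms' relative-abundance curves. The detector finds
crossing intervals supported by enough replicates, scores each candidate with
a switching probability, the difference of relative abundance across the
switch, an *event importance* (abundance of the switching pair relative to
the gene's most abundant isoform — prioritizing switches among highly
expressed isoforms) and a dissimilarity coefficient, tests significance with
a Mann-Whitney U-test (or a time-permutation test for single-replicate data),
and corrects for multiple testing (BH / Holm / Bonferroni).

## Layout

| module | contents |
| --- | --- |
| `isoswitch.core_data` | expression matrix / gene map / domain map I-O, TPM filtering, relative abundance |
| `isoswitch.simulator` | Markov-chain gene states, Dirichlet isoform fractions (Models 1 and 2), gamma-variance noisy counts, ground-truth tables |
| `isoswitch.switch_detection` | switch points, the six event metrics, significance tests, multiple-testing correction, domain gain/loss |
| `isoswitch.usage_clustering` | change of total isoform usage (L1 on the per-gene fraction simplex), clustering (ward / k-means / k-medoids / DBSCAN / OPTICS; euclidean / pearson / DTW), median prototypes |
| `isoswitch.sf_motifs` | splicing-factor co-expression filter, PWM/MEME readers, log-odds scanning, FPR-calibrated thresholds, lost/gained/unregulated exon-flank enrichment |
| `isoswitch.evaluation` | gene-level precision/recall vs. simulated truth, threshold sweeps |
| `isoswitch.cli` | `isoswitch` command-line entry point |

## CLI

```sh
# simulate a ground-truthed dataset (Model 1, 1000 genes, 10 TPs x 3 reps)
isoswitch simulate --model 1 --genes 1000 --noise 10 --seed 1 --out-dir sim/

# detect isoform switches
isoswitch detect --expression sim/expression.tsv --gene-map sim/gene_map.tsv \
    --timepoints t0,t1,t2,t3,t4,t5,t6,t7,t8,t9 --replicates 3 \
    --min-diff 0.2 --min-importance 0.3 --out events.tsv

# cluster IS genes by change of total isoform usage
isoswitch cluster --expression sim/expression.tsv --gene-map sim/gene_map.tsv \
    --timepoints t0,t1,t2,t3,t4,t5,t6,t7,t8,t9 --replicates 3 \
    --genes events.tsv --method agglomerative-ward --k 4 --out clusters.tsv

# motif enrichment around lost/gained exon boundaries
isoswitch motifs --events events.tsv --gtf anno.gtf --fasta genome.fa \
    --pwms pwm_dir/ --flank 50 --fpr 0.01 --out motif_enrichment.tsv

# precision/recall sweep on simulated data
isoswitch evaluate --model 1 --genes 1000 --noise 10 --seeds 0,1,2,3,4 \
    --thresholds 0.05,0.1,0.2,0.3 --out pr.tsv

# small end-to-end pipeline
isoswitch run --genes 200 --seed 7 --out-dir run_out/
```

Every command writes a `<stage>.provenance.json` (parameters + version) next
to its outputs; identical seeds reproduce identical outputs.

## File formats

Expression: TSV/CSV, header row, transcript ids in the first column, sample
columns time-major and replicate-minor. Gene map: two-column TSV
(transcript, gene) or GTF. Domain map: two-column TSV (transcript, domain).
Motifs: tab-delimited PWM (A/C/G/T columns, one row per position) or MEME
minimal format. Exon structures: GTF or BED12; sequences: FASTA.
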