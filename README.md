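# circscape

Downstream characterisation of circular RNAs (circRNAs) from detector call
tables: back-spliced junction (BSJ) catalog construction across multiple
detection programmes, circ/linear differential-expression concordance
statistics, exon-class variant burden analysis, RNA-binding-protein motif
scanning with exact p-values, inverted-Alu / flanking-intron-length
classification, and circRNA:miRNA:mRNA axis construction. A seeded
synthetic-data module generates every input with planted, recoverable
effects, so the full pipeline runs and is tested without any external
downloads.

## Layout

| module | purpose |
|---|---|
| `circscape.intervals` | 0-based half-open coordinate model, interval arithmetic, closest-feature search |
| `circscape.io` | GTF / BED / FASTA / RepeatMasker / TSV readers and writers |
| `circscape.catalog` | multi-detector BSJ merging, expression and detector-support filters, splice-status annotation, host-gene summary |
| `circscape.concordance` | DE classification, circ/linear LFC correlation, exon-bin aggregation, hypergeometric ORA, two-sample Z-test, Wilcoxon |
| `circscape.burden` | circ/nonCirc and BSJ/nonBSJ exon classification, per-Kb variant densities, burden comparisons |
| `circscape.motifs` | consensus and PPM motif scanning (exact DP p-values), Fisher enrichment, positional profiles |
| `circscape.introns` | flanking-intron extraction, 50%-overlap Alu filtering, inverted-Alu classification, median splits |
| `circscape.axes` | seed matching and same-direction circRNA:miRNA:mRNA axis construction |
| `circscape.simulate` | seeded generators for all inputs, with truth tables |
| `circscape.pipeline` / `circscape.cli` | YAML-configured end-to-end orchestration and the `circscape` CLI |

## CLI

Generate a synthetic bundle and run the whole pipeline on it:

```bash
circscape simulate --seed 1 --outdir sim/
cat > config.yaml <<EOF
outdir: out
gtf: sim/annotation.gtf
genome: sim/genome.fa
detector_tables:
  - {path: sim/bsj_circexplorer2.tsv, detector_id: circexplorer2}
  - {path: sim/bsj_ciri2.tsv, detector_id: ciri2}
  - {path: sim/bsj_mapsplice.tsv, detector_id: mapsplice}
sample_columns: [sample_1, sample_2, sample_3, sample_4,
                 sample_5, sample_6, sample_7, sample_8]
de_circ: sim/de_circ.tsv
de_linear: sim/de_linear.tsv
variants: sim/variants.tsv
repeats: sim/repeats.tsv
mirna_sites: sim/mirna_sites.tsv
EOF
circscape run --config config.yaml
```

Individual stages are exposed as subcommands: `circscape catalog`,
`circscape concordance`, `circscape splicing`, `circscape burden`,
`circscape motifs scan|enrich`, `circscape axes`. See `--help` on each.

## Conventions

Internal coordinates are 0-based half-open; GTF and user-facing circRNA IDs
(`HOSTGENE_chrom:start-end`) are 1-based inclusive, converted only at the
I/O boundary. Distances to junction anchors are measured bedtools-closest
style: a feature overlapping or abutting the anchor is at distance 0.
Median splits for intron classes are strict (`<`); values at the median fall
on the Long / non-proximal side. Merged per-sample counts take the
per-detector maximum by default (configurable to mean).
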