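# neoenhancer

Tools for analysing and designing fusion-oncoprotein neo-enhancer systems:

- **msat** — maximal GGAA-microsatellite scanning (both strands, BED6 output,
  minimum 4 consecutive repeat units by default).
- **annotate** — ChIP-peak overlap flagging, strand-aware promoter-window
  (−1,000/+100 bp) classification against a gene model, TSS intervals, and a
  census summary of bound microsatellites.
- **motifs** — IUPAC consensus matching (default `ATTWGTCACGGT`), mismatch
  scanning, and minimal-edit repair of near-matches.
- **cassette** — synthetic expression-cassette assembly: GGAA-repeat
  enhancers (e.g. 17/21/25 repeats, 0-repeat control) or repaired/
  multimerized consensus-motif enhancers, upstream of a minimal promoter and
  P2A-linked payload ORFs, with junction guards and frame validation.
- **screen** — tumor-vs-every-normal-tissue overexpression screen
  (one-sided Welch t or Mann-Whitney per tissue, Benjamini–Hochberg across
  the full gene×tissue family, all-tissue veto, fold-change gate) plus
  surface-protein candidate filtering.
- **doseresponse** — three-parameter log-logistic (upper asymptote, slope,
  ED50) fitting with bootstrap confidence intervals, censoring of no-kill
  curves, and geometric-mean ED50 fold-change between groups.
- **synthetic** — seeded generators for every input (genome FASTA with
  planted runs, GFF3 gene models with context pinning, peak BED with exact
  bound fractions, expression matrices with planted effects, dose-response
  tables), each with machine-readable ground truth.

## Command line

```sh
neoenhancer simulate genome --config genome.toml --seed 1 --out sim/
neoenhancer simulate peaks --genome-truth sim/genome.truth.json --bound-fraction 0.5 --seed 2 --out sim/
neoenhancer scan --fasta sim/genome.fa --unit GGAA --min-repeats 4 --out hits.bed
neoenhancer annotate --hits hits.bed --peaks sim/peaks.bed --gff sim/genes.gff3 \
    --out annotated.tsv --summary summary.json
neoenhancer motif scan --seq enhancer.fa --consensus ATTWGTCACGGT --max-mismatch 2 --out matches.tsv
neoenhancer design ggaa --repeats 25 --out cassette.gb --report report.json
neoenhancer design p3f1 --base alk_se.fa --repair --extra-motifs 5 --out cassette.gb
neoenhancer screen --matrix expr.tsv --labels labels.tsv --alpha 0.05 --min-delta 1 --out screen.tsv
neoenhancer fit-dr --data dr.tsv --boot 1000 --seed 1 --out fits.tsv
```

Coordinates are 0-based half-open internally and in BED output; GFF3 is
converted at the boundary. All generators are deterministic given a config
and a single integer seed.

## Notes

The shipped minimal promoter, Kozak context and payload ORFs are labelled
placeholder sequences (the engine is sequence-agnostic and every part is
overridable); only the P2A linker is the standard nucleotide sequence.
Multi-TSS genes must be flattened to one record per TSS before annotation.
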