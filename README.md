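# denovotx

Tools for characterizing candidate de novo protein-coding genes against
their non-coding orthologs: parsimony dating of loci and ORFs on a
species tree, ORF-disabler screening of pairwise codon alignments,
birth-versus-loss discrimination through shared ancestral disablers,
RPKM-based transcription calling with a Monte-Carlo intergenic
background, cross-species tissue-expression profile correlation with an
ortholog-shuffle permutation null, splice-junction support
classification, and pooled Nei–Gojobori dN/dS — plus ground-truthed
simulators for every input, so the whole chain is testable end to end
without external data.

## Layout

| module | purpose |
| --- | --- |
| `denovotx.phylo` | rooted species tree with stable leaf-set branch ids |
| `denovotx.dating` | single-gain / zero-loss origination-branch assignment |
| `denovotx.orf_screen` | disabler detection, reliability/truncation/paralog/peptide filters |
| `denovotx.expression` | representative regions, RPKM, transcription calls, context classes, QC |
| `denovotx.comparative` | profile correlations, shuffle null, clustering, tissue-pair matrices |
| `denovotx.splicing` | junction support classes, coordinate mapping, splice-site motifs |
| `denovotx.evolution` | pooled Nei–Gojobori dN/dS with Jukes–Cantor correction |
| `denovotx.synthetic` | seeded generators with recorded ground truth |
| `denovotx.pipeline` / `denovotx.cli` | manifest-driven orchestration and CLI |

## CLI

```bash
denovotx simulate --out bundle/ --n-genes 20 --rho 0.9 --amplification 2 --seed 1
denovotx validate bundle/manifest.yaml
denovotx run bundle/manifest.yaml --out run1/ --seed 1
denovotx report run1/
```

`simulate` writes a complete synthetic bundle (Newick tree, gapped-FASTA
alignment pairs, RPKM/library-size tables, junction table, ground-truth
JSON and a YAML manifest).  `run` executes the full stage chain and
writes `report.tsv` (one row per gene with every intermediate decision)
and `summary.json` (the filter funnel, class counts and the shuffle-null
result).  Exit codes: 0 ok, 1 validation error, 2 runtime error.

All thresholds (alignment coverage/identity gates, the 70%/50%
truncation rule, the BLAST E-value cutoff, RPKM cutoffs, correlation
cutoff, permutation count, significance level) live in
`denovotx.pipeline.Params` with the published defaults and can be set
per run (e.g. `denovotx run ... --threshold 0.50` for the stricter
truncation rule).

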