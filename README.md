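# lnckit

Discovery of long non-coding RNAs (lncRNAs) in de novo transcriptomes and
conserved-region-gated lncRNA–mRNA target prediction, as a tested,
desk-scale pipeline.

The package implements:

- **seqcore** — FASTA I/O, stop-to-stop ORF finding (no start-codon
  requirement), and a k-mer (k = 1..5) log-odds coding-potential
  classifier with an adapter for precomputed coding/noncoding call tables.
- **evidence** — 12-column tabular similarity-hit parsing, the
  reciprocal >50%-coverage symbiont-contamination rule (e < 1e-3), the
  protein/domain/signal-peptide coding-evidence tracks (protein e ≤ 1e-4),
  and a fixture-grade local aligner.
- **discovery** — the stepwise filtering cascade (contamination → coding
  evidence → length ≥ 300 nt → longest ORF ≤ 75 aa → housekeeping RNA →
  ≥ 10 raw counts → k-mer call) with a complete per-transcript audit
  trail; the surviving set is order-independent by construction.
- **expression** — FPKM, the Audic–Claverie two-library count test,
  Benjamini–Hochberg adjustment, and up/down calling at |log2 FC| ≥ 1 and
  5% FDR ("up" = higher in the second sample).
- **enrichment** — the upper-tail hypergeometric pathway statistic
  (evaluated in log space) with Bonferroni correction.
- **interaction** — conserved-region detection from reference-lncRNA hits
  (strict e ≤ 1e-3 or loose e ≤ 10 mode), an interaction-only duplex
  energy minimizer (nearest-neighbor stacks, affine interior/bulge loops,
  temperature rescaling; default 25 °C), and the three-way gate: site in a
  conserved region, energy ≤ −20 kcal/mol, paired fraction ≥ 0.9.
- **stats_compare** — two-sample Kolmogorov–Smirnov test and the
  cross-species shared-lncRNA rule (matching region longer than half of
  both partners).
- **synthetic** — a seeded generator for transcriptomes, evidence tables,
  two-condition counts, pathway maps, and planted interaction
  truths/decoys, with a ground-truth manifest.

## CLI

```sh
lnckit simulate --seed 42 --out-dir run/
lnckit discover --fasta run/transcripts.fasta \
    --symbiont-hits run/symbiont_hits.tsv --protein-hits run/protein_hits.tsv \
    --domain-hits run/domain_hits.tsv --signal-calls run/signal_calls.tsv \
    --housekeeping-hits run/housekeeping_hits.tsv --counts run/counts.tsv \
    --plek-calls run/plek_calls.tsv --out-dir run/
lnckit de --counts run/counts.tsv --fasta run/transcripts.fasta --out run/de_results.tsv
lnckit enrich --de-results run/de_results.tsv --annotation run/pathways.tsv \
    --out run/enrichment.tsv
lnckit interact --lncrna-fasta run/discovered_lncrna.fasta --mrna-fasta run/mrna.fasta \
    --noncode-hits run/noncode_hits.tsv --out-dir run/
lnckit report --run-dir run/
```

Thresholds are flags (`--min-length`, `--max-orf-aa`, `--min-counts`,
`--energy-cutoff`, `--conserved-evalue`, ...); defaults equal the
published values. A YAML config file (`lnckit --config conf.yaml ...`,
one section per subcommand) supplies defaults that flags override.

## Notes

- Energy parameters ship as editable TSVs in `src/lnckit/data/`
  (`stacks_default.tsv`: Turner-style stack ΔG/ΔH values; `stacks_toy.tsv`:
  the exactly-enumerable model used by the oracle tests).
- An adapter (`interaction.parse_rnaplex_output`) ingests native RNAplex
  result lines for production use; the in-repo folding engine exists so
  the gating logic is testable without external binaries.
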