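# symscreen

A tested, reusable implementation of a multi-stage computational screen for
symbiosis-relevant genes in a two-organism (fungal/algal) coculture system.
The pipeline covers:

- **`synthetic_data`** — deterministic fixture generators with planted ground
  truth: a genome with a low-GC island terminated by a tandem repeat array,
  negative-binomial read counts with planted induced/repressed genes,
  three-predictor secretion call tables, pairwise homology hit tables with
  planted reciprocal pairs and clustered homologs, and protein alignments
  evolved on triplets with rate-multiplied focal branches.
- **`expression_screen`** — RPKM (plug-in and multinomial-bootstrap),
  coculture/monoculture ratio classification with organism-specific
  thresholds (induce ≥ 2 / repress ≤ 0.5 for the fungus, ≥ 1.3 / ≤ 0.77 for
  the alga), and a log2 ±0.6 up/down classifier.
- **`secretome`** — three-predictor consensus secretion calls with the
  N-terminal transmembrane exception, subset size summaries, and
  secreted-among-induced contingency reports.
- **`enrichment`** — exact log-space hypergeometric upper-tail p values,
  similarity-search background construction, and subgroup enrichment tables
  with enrichment factors.
- **`genome_composition`** — sliding-window GC tracks, robust low-GC region
  detection (two-pass median/MAD baseline), terminal tandem-repeat discovery
  and scaffold joining with one retained unit copy, and per-region
  affinity/intron composition reports.
- **`gene_clusters`** — homolog retention filtering (≥ 45 % similarity,
  50–150 % coverage) and cluster chaining across at most 6 intervening gene
  models, with flank-interval reporting.
- **`orthology_sets`** — reciprocal-best-hit pairing (e < 1e-5),
  presence/absence matrices over a motility-annotated taxon panel,
  motile-only family selection, and set-overlap reports.
- **`rate_screen`** — per-triplet relative-rate chi-square tests, a
  bootstrap-supported Poisson-corrected distance method, ≥ 90 % triplet
  consensus calling, and a ≥ 2-method intersection for final slow/fast
  candidates.

## Command line

Every stage is exposed under one `symscreen` entry point:

```sh
symscreen simulate --config config.yaml --out fixture/
symscreen express --counts fixture/counts.tsv --gff fixture/genes.gff3 \
    --library-sizes fixture/library_sizes.json --organism fungus --out expr.tsv
symscreen secretome --calls fixture/secretion_calls.tsv --tm-window 60 --out sec.tsv
symscreen enrich --induced induced.txt --subgroups subgroups.tsv \
    --hits hits.tsv --genome-size 11388 --out enrich.tsv
symscreen gcscan --fasta fixture/genome.fasta --gff fixture/genes.gff3 \
    --out-prefix scan
symscreen cluster --hits fixture/cluster_hits.tsv --gff fixture/genes.gff3 \
    --max-intervening 6 --min-similarity 45 --cov 0.5:1.5 --out clusters.tsv
symscreen ortho rbh --ab a_vs_b.tsv --ba b_vs_a.tsv --out pairs.tsv
symscreen rates --alignments fixture/alignments --triplets fixture/triplets.tsv \
    --alpha 0.05 --consensus 0.9 --min-methods 2 --out-prefix rates
```

`symscreen simulate` emits only plain-text formats (FASTA, GFF3, TSV, JSON,
YAML) plus a `ground_truth.json` recording every planted signal, so each
downstream stage can be validated against known answers.

## Testing notes

`tests/test_acceptance.py` holds one test per acceptance criterion: the
worked-example percentages above plus property suites (hypergeometric tail
vs. exact enumeration, planted-island boundary recovery over 20 seeds,
relative-rate type-I calibration over 1000 null orthogroups, planted
differential-expression and rate-shift sensitivity ≥ 0.9, RBH symmetry,
brute-force equivalence for motile-only selection and cluster chaining).
The remaining files test each module against independent oracles
(enumeration, union-find, direct counting) and spec invariants via
hypothesis.
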