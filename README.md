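# isocover

Toolkit for deep multi-protease proteomics downstream analysis, exercisable
end to end on synthetic data:

- **`isocover.digest`** — multi-protease in silico digestion (trypsin, LysC,
  LysN, AspN, GluC, chymotrypsin) with missed cleavages and a 7–35 aa
  detectability window; theoretical residue-coverage accounting.
- **`isocover.coverage`** — observed sequence coverage from peptide evidence
  tables (all-occurrence matching, enzyme-agnostic), protease-combination
  scans, and transmembrane-segment coverage profiles.
- **`isocover.variants`** — SAP calling from VCF-like pileups
  (depth ≥ 10, alt ≥ 5, frequency ≥ 15 %, base/mapping quality ≥ 13, no
  multimapping), variant-proteome construction, Mutated = No/Yes/Mixed
  peptide classification, and the two-sided rank-sum deleteriousness-shift
  test.
- **`isocover.splicing`** — exon-boundary splice graphs, minimal-bubble AS
  event enumeration with type and frame classification, peptide-to-genome
  projection, junction-spanning peptide support, PSI quantification, and
  the equal-efficiency PSI-optimum model (balance at PSI = 1/3).
- **`isocover.assembly`** — reverse translation with a nondegenerate codon
  map, deterministic de Bruijn unitig assembly (k = 23, min contig 100 nt),
  and brute-force scaffold matching.
- **`isocover.detect`** — gradient-boosted detectability classifier for AS
  events with stratified 7-fold CV and permutation importance.
- **`isocover.synth`** — seeded generator for genomes, gene models with
  cassette exons at controlled PSI, nonsynonymous variants with controlled
  depth/allele fraction, junction reads, and abundance-dependent peptide
  evidence.

## CLI

```bash
isocover synth --out data/ --seed 1                      # synthetic bundle
isocover digest --fasta proteome.fa --proteases trypsin,gluc --out peps.tsv
isocover digest --fasta proteome.fa --proteases trypsin --coverage
isocover coverage --evidence ev.tsv --fasta proteome.fa --out cov.tsv
isocover coverage --evidence ev.tsv --fasta proteome.fa --combinations 2..5
isocover splice --gtf models.gtf --evidence ev.tsv \
    --junction-reads jr.tsv --out splice/
isocover variants call --pileup pileup.tsv --out passing.tsv
isocover variants apply --gtf models.gtf --genome genome.fa \
    --calls passing.tsv --out mutated.fa
isocover assemble --evidence ev.tsv --fasta proteome.fa --out asm/
isocover classify --features f.tsv --labels l.tsv --seed 7
```

## Conventions

Coordinates are 0-based half-open internally and 1-based inclusive in all
TSV/GTF/FASTA interfaces. Synthetic output is byte-identical for a fixed
seed. I/L are distinct in all matching. The proline cleavage exception is
applied to trypsin, LysC, GluC and chymotrypsin by default and is
togglable per rule (`ProteaseRule.without_proline_rule()`).
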