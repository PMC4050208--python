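# cugscribe

Predict whether a yeast genome translates the **CUG codon** as **leucine**
(standard genetic code) or as **serine** (Alternative Yeast Codon Usage,
AYCU).

Most *Saccharomycetes*, including *Saccharomyces cerevisiae*, read CUG as
leucine.  A large group of yeasts — many but not all of the species called
"*Candida*" — read the same codon as serine, decoded by a mutant
ser-tRNA_CAG.  The reassignment cannot be guessed from a species name, and
public taxonomy databases label the genetic code of several species wrongly.
Getting it wrong corrupts every downstream protein sequence, so anyone
annotating a new yeast genome or transcriptome needs the decoding scheme
*before* running a gene predictor.

`cugscribe` answers the question from sequence data alone.  It is aimed at
genome-annotation and comparative-genomics workflows: give it assembly
contigs and a bundle of reference protein-family alignments whose
CUG-encoded residues are annotated, and it returns a genome-wide verdict
with per-gene, per-codon evidence.

## How it works

1. **Homolog search** — contigs are translated in all six frames and scanned
   with exact protein k-mers from every reference sequence (a translated
   BLAST-style seed search with diagonal-banded two-hit clustering).  Seed
   clusters are extended by ±500 nt, and the best local alignment
   (Smith-Waterman, BLOSUM62) of the region against its best-matching
   reference yields one single-exon gene model per family.  CUG codons are
   rendered as 'L' during the search so homology detection stays agnostic to
   the question being asked.
2. **Column mapping** — each predicted protein is aligned to its family's
   alignment (occupancy-weighted profile DP with affine gaps; or pairwise
   against a single reference via Needleman-Wunsch, Gotoh, Smith-Waterman or
   LCS), giving the alignment column of every residue.
3. **Per-site verdicts** — every CUG codon is scored on two features at its
   column:
   * *amino-acid composition*: hydrophobic residues H = {L, I, V, M, F}
     indicate leucine/standard; small polar residues P = {S, T, C, A}
     indicate serine/AYCU.  With h = Σcounts(H), p = Σcounts(P) and n the
     column occupancy, the site is `standard` if h > p and h > n − h − p,
     `aycu` symmetrically, otherwise `ambiguous`.
   * *CUG-position conservation*: among completely assembled reference genes
     with a CUG annotated at the same column, the majority of their species'
     decoding labels wins; no match or a tie is `ambiguous`.
4. **Aggregation** — a simple majority over the non-ambiguous site verdicts,
   per feature, per protein and genome-wide; the combined verdict requires
   the two features to agree.  A query with no CUG codons returns the
   distinct state `no-evidence`.
5. **tRNA_CAG identity** — independently, candidate tRNA sequences are
   classified as leu-type, ser-type or other by best Smith-Waterman score
   against labelled reference sets, with the score margin reported.

A seeded synthetic-data generator (`cugscribe simulate`) emulates the whole
reference-bundle structure with known ground truth, so every stage is
testable without downloads.

## Worked example

Simulate a small AYCU genome with its reference bundle, then predict:

```bash
cugscribe simulate --out bundle --seed 42 --config cfg.yaml --query-decoding aycu
cugscribe predict --genome bundle/query_genome.fasta --reference bundle --flank 200
```

```
CUG decoding prediction
=======================

Summary
-------
combined verdict:      aycu
composition feature:   aycu (standard 0, aycu 14, ambiguous 0)
conservation feature:  aycu (standard 0, aycu 14, ambiguous 0)
CUG sites analysed:    14

Per-family detail
-----------------
fam00: contig000:412-768 (+) score 316 | composition aycu, conservation aycu, combined aycu
    CUG at residue 12 -> column 12: H=1 P=18 cug-leu=0 cug-ser=8 [aycu/aycu]
    CUG at residue 38 -> column 39: H=0 P=19 cug-leu=0 cug-ser=7 [aycu/aycu]
    ...
```

Reading the first site line: the predicted fam00 gene carries a CUG at
residue 12, which maps to alignment column 12 of the reference family; that
column holds 18 small polar residues versus 1 hydrophobic (composition →
aycu), and 8 completely assembled reference genes from serine-decoding
species carry a CUG at exactly that column versus 0 from leucine-decoding
species (conservation → aycu).  Both features agree for all 14 sites, so the
genome-wide combined verdict is `aycu`: this genome reads CUG as serine.

Single sequences work too:

```bash
$ cugscribe translate genes.fa --code aycu
>gene1
MSSRL
$ cugscribe check --protein MSLRL --cdna ATGTCTCTGAGATTG --code aycu
{
  "is_consistent": false,
  "cug_positions": [3],
  "mismatches": [[3, "L", "S"]],
  "corrected": "MSSRL"
}
```

The `check` output says: residue 3 of the given protein is CUG-encoded and
was translated as leucine, but under this species' code it is serine; the
corrected protein is `MSSRL`.

## Layout

```
src/cugscribe/
  genetic_codes.py    codon tables, translate, translation check
  pairwise_align.py   Needleman-Wunsch, Gotoh, Smith-Waterman, LCS
  homolog_finder.py   six-frame translation, seeded search, gene extraction
  profile_mapping.py  profile construction and column mapping
  cug_classifier.py   per-site verdicts, aggregation, the pipeline
  trna_classifier.py  tRNA_CAG identity by nearest reference
  synthetic_data.py   seeded generator for bundles, genomes, tRNA sets
  io_reports.py       FASTA/TSV/JSON I/O, bundle validation, reports
  cli.py              cugscribe predict|translate|check|classify-trna|simulate
docs/methods.md       model, parameters, and design notes
```
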