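# Methods

## The decoding problem

A yeast species reads the codon CUG either as leucine (standard code) or as
serine (Alternative Yeast Codon Usage, AYCU).  Because the reassignment went
through near-complete loss of ancestral CUG codons, the CUG positions of
extant genomes are highly diagnostic: in species that kept the standard
code, CUGs sit at positions where homologous proteins carry large
hydrophobic residues; in serine-decoders they sit at positions carrying
small polar residues.  `cugscribe` turns this observation into a classifier
over a reference collection of annotated protein-family alignments.

## Pipeline

### Homolog search

Contigs are translated in all six frames; every residue keeps a pointer to
its codon's forward-strand coordinates, so downstream analysis can always
recover the underlying triplet on either strand.  The search seeds on exact
protein k-mers shared with any reference sequence of any family (default
k = 5 for the all-rows pipeline search; the single-reference search
primitive defaults to k = 4, minimum two word hits).  Hits are grouped per
family into diagonal bands of 32 residues and clustered along the contig;
clusters below the minimum hit count are discarded — without the diagonal
constraint, chance k-mer matches chain across whole contigs.  Cluster
intervals are extended by a flank (default 500 nt, so gene extraction sees
intergenic context) and overlapping intervals on one contig and strand are
merged.  Each merged region remembers the reference row that seeded it best;
gene extraction aligns the region's three same-strand frame translations
against that row by Smith-Waterman (BLOSUM62, gap open 10 / extend 1) and
emits the best-scoring aligned stretch as a single-exon gene model (minimum
score 50, configurable).  One gene represents each family: the best-scoring
region wins.

The predicted protein renders every CTG codon as 'L' regardless of the
organism's actual decoding; the decision about CUG identity is made only
downstream, never during the search.

### Column mapping

The reference alignment of a family is summarised as a per-column profile:
counts of the 20 canonical residues (gaps and non-canonical letters
excluded), occupancy, and occupancy fraction.  The query is aligned to the
columns by a three-state affine DP in which

* the match score of residue *r* against column *c* is
  `occ_frac(c) * Σ_a freq(c, a) · S(r, a)` with S = BLOSUM62 — sparse
  columns neither attract nor repel strongly;
* skipping column *c* costs affine penalties scaled by `occ_frac(c)`, so an
  all-gap column is free to skip, and columns skipped before the first or
  after the last query residue are free (predicted genes are locally trimmed
  fragments of full-length families; the query itself is aligned end to
  end);
* query insertions cost plain affine penalties (open 10, extend 1).

CUG-encoded residues are special-cased during mapping: they score as the
better of leucine and serine against each column.  Their identity is exactly
one of the two, and scoring them as the 'L' they are displayed as would bias
placement away from serine-type columns.  The reference alignment is never
modified, and the resulting residue→column map is strictly monotone.

A pairwise fallback maps the query through a single reference row with any
of the four pairwise algorithms, transferring columns through that row's gap
pattern; CUG residues are masked to 'X' there (pairwise matrices have no
leucine-or-serine code).

### Per-site evidence and aggregation

For every CUG codon that maps to a column, two verdicts are computed.
*Composition* counts the column's residues over all reference rows —
including incompletely assembled genes — and applies the majority rule over
the hydrophobic class {L, I, V, M, F}, the polar-small class {S, T, C, A},
and everything else; a column with fewer than 5 residues (configurable
`min_occupancy`) is ambiguous, as are ties.  *Conservation* counts, among
completely assembled reference genes only, those carrying a CUG annotation
at the same column, split by their species' decoding label; the majority
wins, with zero matches or ties ambiguous.  CUG codons falling in query-only
insertions are reported with a null column and both verdicts ambiguous.

Aggregation at protein and genome level is a majority vote per feature over
the site verdicts; the combined call is the shared label when both features
agree and `ambiguous` otherwise.  A query without CUG codons yields
`no-evidence`, which is deliberately distinct from `ambiguous`: the former
means the data cannot bear on the question, the latter that it bears on it
inconclusively.  Both feature verdicts and all tallies are always reported
alongside the combined call.

### tRNA_CAG classification

The amino-acid identity of the tRNA with a CAG anticodon independently fixes
the code.  Queries are compared by Smith-Waterman score (nucleotide +5/−4,
affine 10/1) against three labelled reference sets; the arg-max class wins,
ties and scores below `min_score` (default 100) give `none`, and the margin
over the runner-up class is reported as a confidence measure.  The anticodon
is located purely positionally (a CAG starting at positions 32–38 of a
70–95 nt sequence, both configurable); secondary-structure prediction,
pseudogene scoring and intron splicing are out of scope, so genome-wide
tRNA scanning should be done with a dedicated tool before classification.

## Pairwise aligners

Needleman-Wunsch (global, linear gaps), Gotoh (global, affine), Smith-
Waterman (local, affine — with open = 0 it reduces to the linear textbook
form) and longest common subsequence are implemented as integer DPs with
numba-compiled kernels.  Conventions: gap penalties are magnitudes;
Needleman-Wunsch charges `gap_extend` per gap column, so
`gotoh(open=0)` equals `needleman_wunsch(gap=extend)` exactly; traceback
ties break diagonal > up > left, and a local alignment may be empty at
score 0.  Scores stay integral whenever the scheme is integral.  Defaults:
BLOSUM62 with 10/1 for proteins, +5/−4 with 10/1 for nucleotides — standard
practice, since no canonical parameter set exists for this task — and all
are overridable.

## Synthetic data

The generator emulates the structure of a curated reference collection with
known ground truth.  Per family it draws a consensus (default 10 families,
300–400 aa), per-column substitution rates (uniform in 0.05–0.4), and rows
for two clades of species (15 standard-decoding, 15 AYCU).  A small fraction
of columns (5%) are gap-prone (each row gapped with probability 0.3), and
10% of rows are truncated at one end and flagged incomplete.  Designated CUG
columns come in two kinds, mirroring how CUG positions behave in real
families — class-consistent across *both* clades:

* *ser-type* columns hold S with probability `purity` (default 0.9, else a
  random residue) in every row; AYCU-clade rows whose residue is S carry a
  CUG annotation;
* *leu-type* columns hold L the same way; standard-clade rows with L are
  annotated with probability 0.8.

Query genomes back-translate mutated copies of clade rows (identity 0.7 at
non-planted positions, indel rate 0.02) under the chosen code, planting CTG
with probability `purity` at annotated columns where the source residue
fits, and never elsewhere — every CTG in a simulated gene is a recorded
ground-truth site.  Genes are packed five per contig with ≥ 2 × flank
random spacers, on the minus strand with probability 0.5.  tRNA sets
(51 leu / 22 ser / 34 other) derive from two class consensuses diverged at
40% of non-anticodon positions plus an unrelated consensus for the "other"
class, with per-reference noise (default 5%).

Everything is a pure function of the integer seed through
`numpy.random.default_rng`; same seed, byte-identical output.

What the generator does **not** model: phylogenetic correlation between rows
(substitutions are independent given the consensus), codon-usage bias
(synonymous codons are uniform, CTG excluded outside planted sites),
introns, and spatial correlation of conservation — in real families the
neighbourhood of a conserved CUG position is itself conserved, whereas here
a hot column can sit right next to a planted site.  Passing tests therefore
demonstrate the classifier's contract under honest sequence divergence, not
performance on real genomes; conversely the last simplification makes
column mapping *harder* than in real data (see below).

## Measured behaviour and known limitations

* On default-condition simulations (seeds 1–20, both decodings, 40 runs)
  the combined genome verdict is correct in 40/40 runs, with each run
  analysing 10 genes and ~30 CUG sites.
* Per-site, ~2% of planted CUG sites receive a wrong or ambiguous verdict.
  Essentially all failures are alignment-column misplacements by 1–5
  columns next to a query indel or inside a weakly conserved stretch.  This
  is intrinsic ambiguity of the mapping problem at 70% identity, not a
  defect of the profile DP: spot-checking a failing site with MAFFT
  `--add` reproduces the misplacement, and an ensemble of profile and
  nearest-row pairwise maps makes the same errors.  Real reference
  alignments, with conserved neighbourhoods around CUG positions, should
  misplace less often.
* The gene model is single-exon; intron-containing genes will be truncated
  at the strongest exon.  Yeasts are intron-poor, and the simulated data is
  intron-free.
* One gene per family is analysed; paralogs beyond the best-scoring copy
  are ignored, matching the one-gene-per-family design of the reporting.
* Transcriptome input works but cross-assignment within multi-gene families
  (e.g. only actin present, aligned against actin-related families) can
  dilute the evidence, so per-family detail should be inspected.

## Numerical and degenerate-input choices

Stop codons translate to `*` and do not truncate (a `--trim-at-stop` flag
exists); codons containing ambiguity codes give `X`, and `X` never counts
as a translation-check mismatch.  Empty sequences align as pure gap runs
rather than erroring.  All internal coordinates are 0-based half-open on
the forward strand; every report uses 1-based residue and column indices.
Profile DP runs in float64; pairwise DP cells are int64.  Ties anywhere in
verdict logic resolve to `ambiguous`, never to a decoding.
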