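"""Synthetic reference bundles, query genomes, and tRNA sets with ground truth.

The curated reference data the decoding pipeline was designed around — large
protein-family alignments annotated with CUG-encoded residues across dozens
of yeast species — is not something a test suite can download.  This module
generates structurally equivalent data with known ground truth:

* **Reference bundles** — per-family alignments over a standard-decoding and
  an AYCU-decoding clade.  Each family carries two kinds of designated CUG
  columns, mirroring how CUG positions behave in real families: *ser-type*
  columns hold serine (with probability ``purity``, else a random residue)
  in both clades and are CUG-annotated in AYCU rows (their serine is
  CUG-encoded); *leu-type* columns hold leucine the same way and are
  CUG-annotated in a configurable fraction of standard-code rows.  A
  configurable fraction of rows is truncated and flagged incomplete.
* **Query genomes** — mutated copies of clade rows, back-translated under the
  chosen decoding with CTG planted at annotated columns, packed onto contigs
  with intergenic spacers on either strand.
* **tRNA reference sets** — leu/ser/other collections around divergent class
  consensus sequences with the CAG anticodon planted in the anticodon loop.

Every output is a pure function of the integer seed: generation uses only
``numpy.random.default_rng`` draws in a fixed order, so bundles are
byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .cug_classifier import AYCU_LABEL, DECODING_LABELS, ReferenceFamily, STANDARD_LABEL
from .genetic_codes import AMINO_ACIDS, AYCU, GeneticCode, STANDARD
from .homolog_finder import reverse_complement
from .pairwise_align import GAP
from .trna_classifier import TrnaReferenceSet

__all__ = [
    "SimulationConfig",
    "PlantedGene",
    "QueryGroundTruth",
    "BundleGroundTruth",
    "ReferenceBundle",
    "simulate_reference_bundle",
    "simulate_query_genome",
    "simulate_trna_refs",
]

_HYDRO = "LIVMF"
_POLAR = "STCA"
_DNA = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the conditions the tests assume.

    ``conservation`` is the per-column substitution-probability range for
    non-CUG columns; ``purity`` is both the probability that a reference
    residue at a CUG column is class-consistent and the probability that a
    query residue at an annotated column is actually CUG-encoded.
    ``query_identity`` applies to non-planted residues of a query gene.
    """

    seed: int = 1
    n_families: int = 10
    family_length: tuple[int, int] = (300, 400)
    n_standard_species: int = 15
    n_aycu_species: int = 15
    conservation: tuple[float, float] = (0.05, 0.4)
    n_cug_columns: int = 8
    purity: float = 0.9
    cug_annotation_rate_standard: float = 0.8
    gap_column_rate: float = 0.05
    gap_row_prob: float = 0.3
    fraction_incomplete: float = 0.1
    query_identity: float = 0.7
    indel_rate: float = 0.02
    flank: int = 500
    genes_per_contig: int = 5
    n_query_genes_per_family: int = 5
    minus_strand_fraction: float = 0.5
    trna_sizes: tuple[int, int, int] = (51, 22, 34)
    trna_noise: float = 0.05
    trna_length: int = 76

    def __post_init__(self) -> None:
        for name in (
            "purity",
            "cug_annotation_rate_standard",
            "gap_column_rate",
            "gap_row_prob",
            "fraction_incomplete",
            "query_identity",
            "indel_rate",
            "minus_strand_fraction",
            "trna_noise",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ReferenceBundle:
    """Families plus the species decoding table and optional tRNA references."""

    families: tuple[ReferenceFamily, ...]
    decoding: dict[str, str]
    trna: Optional[TrnaReferenceSet] = None

    def validate(self) -> list[str]:
        errors: list[str] = []
        for fam in self.families:
            errors.extend(fam.validate())
        return errors


@dataclass(frozen=True)
class BundleGroundTruth:
    """Designated CUG columns (0-based) per family, by type."""

    ser_columns: dict[str, tuple[int, ...]]
    leu_columns: dict[str, tuple[int, ...]]


@dataclass(frozen=True)
class PlantedGene:
    """One simulated query gene with its planted CUG sites.

    ``protein`` holds the true residues; ``protein_cug_as_leu`` renders the
    CUG-encoded residues as 'L', matching how the gene predictor reports
    proteins.  ``cug_sites`` pairs 1-based residue indices with 1-based
    reference alignment columns.  Coordinates are 0-based half-open on the
    forward strand of ``contig_id``.
    """

    family_id: str
    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    protein: str
    protein_cug_as_leu: str
    cds: str
    cug_sites: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class QueryGroundTruth:
    decoding: str
    genes: tuple[PlantedGene, ...]

    def to_dict(self) -> dict:
        return {"decoding": self.decoding, "genes": [asdict(g) for g in self.genes]}


def _random_aa(rng: np.random.Generator) -> str:
    return AMINO_ACIDS[rng.integers(20)]


def _mutated_aa(rng: np.random.Generator, original: str) -> str:
    choices = AMINO_ACIDS.replace(original, "")
    return choices[rng.integers(len(choices))]


def _class_residue(rng: np.random.Generator, primary: str, cfg: SimulationConfig) -> str:
    """The column's diagnostic residue (S or L) with probability ``purity``."""
    if rng.random() < cfg.purity:
        return primary
    return _random_aa(rng)


def simulate_reference_bundle(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ReferenceBundle, BundleGroundTruth]:
    """Generate a reference bundle with designated CUG columns.

    Species are split into a standard-decoding and an AYCU clade.  Rows are
    drawn from a family consensus with column-specific substitution rates;
    ser-/leu-type CUG columns carry class residues as described in the module
    docstring.  A configured fraction of rows is truncated (head or tail
    replaced by gaps) and flagged incomplete; their annotations in the
    truncated part are dropped.
    """
    rng = np.random.default_rng(config.seed)
    std_species = [f"std_sp{i:02d}" for i in range(config.n_standard_species)]
    alt_species = [f"alt_sp{i:02d}" for i in range(config.n_aycu_species)]
    decoding = {sp: STANDARD_LABEL for sp in std_species}
    decoding.update({sp: AYCU_LABEL for sp in alt_species})

    families: list[ReferenceFamily] = []
    ser_cols_gt: dict[str, tuple[int, ...]] = {}
    leu_cols_gt: dict[str, tuple[int, ...]] = {}
    for fi in range(config.n_families):
        fid = f"fam{fi:02d}"
        lo, hi = config.family_length
        L = int(rng.integers(lo, hi + 1))
        consensus = "".join(_random_aa(rng) for _ in range(L))
        col_rate = rng.uniform(config.conservation[0], config.conservation[1], size=L)
        cug_cols = np.sort(rng.choice(L, size=min(config.n_cug_columns, L), replace=False))
        half = len(cug_cols) // 2
        ser_cols = frozenset(int(c) for c in cug_cols[:half])
        leu_cols = frozenset(int(c) for c in cug_cols[half:])
        gap_cols = frozenset(
            int(c)
            for c in range(L)
            if c not in ser_cols and c not in leu_cols and rng.random() < config.gap_column_rate
        )
        rows: dict[str, str] = {}
        species_of: dict[str, str] = {}
        complete: dict[str, bool] = {}
        annotations: dict[str, frozenset[int]] = {}
        for sp in std_species + alt_species:
            sid = f"{fid}_{sp}"
            is_aycu = decoding[sp] == AYCU_LABEL
            chars: list[str] = []
            annotated: set[int] = set()
            for c in range(L):
                if c in ser_cols:
                    ch = _class_residue(rng, "S", config)
                    if is_aycu and ch == "S":
                        annotated.add(c)
                elif c in leu_cols:
                    ch = _class_residue(rng, "L", config)
                    if (
                        not is_aycu
                        and ch == "L"
                        and rng.random() < config.cug_annotation_rate_standard
                    ):
                        annotated.add(c)
                else:
                    ch = consensus[c]
                    if rng.random() < col_rate[c]:
                        ch = _mutated_aa(rng, ch)
                    if c in gap_cols and rng.random() < config.gap_row_prob:
                        ch = GAP
                chars.append(ch)
            is_complete = rng.random() >= config.fraction_incomplete
            if not is_complete:
                cut = int(L * rng.uniform(0.2, 0.4))
                if rng.random() < 0.5:
                    lo_cut, hi_cut = 0, cut
                else:
                    lo_cut, hi_cut = L - cut, L
                for c in range(lo_cut, hi_cut):
                    chars[c] = GAP
                annotated = {c for c in annotated if not (lo_cut <= c < hi_cut)}
            rows[sid] = "".join(chars)
            species_of[sid] = sp
            complete[sid] = bool(is_complete)
            annotations[sid] = frozenset(annotated)
        families.append(
            ReferenceFamily(fid, rows, species_of, complete, annotations, dict(decoding))
        )
        ser_cols_gt[fid] = tuple(sorted(ser_cols))
        leu_cols_gt[fid] = tuple(sorted(leu_cols))

    bundle = ReferenceBundle(tuple(families), decoding)
    return bundle, BundleGroundTruth(ser_cols_gt, leu_cols_gt)


def annotated_columns_by_type(family: ReferenceFamily) -> tuple[frozenset[int], frozenset[int]]:
    """(ser-type, leu-type) CUG columns, inferred from the family's annotations.

    A column annotated in any AYCU-decoding row is ser-type; one annotated in
    any standard-decoding row is leu-type.
    """
    ser: set[int] = set()
    leu: set[int] = set()
    for sid, cols in family.cug_columns.items():
        label = family.decoding[family.species[sid]]
        target = ser if label == AYCU_LABEL else leu
        target.update(cols)
    return frozenset(ser), frozenset(leu)


def _back_table(code: GeneticCode) -> dict[str, list[str]]:
    """aa -> codons under *code*, with CTG excluded (planted explicitly)."""
    table: dict[str, list[str]] = {}
    for aa in AMINO_ACIDS:
        table[aa] = [c for c in code.codons_for(aa) if c != "CTG"]
    return table


def simulate_query_genome(
    bundle: ReferenceBundle,
    decoding_label: str,
    config: SimulationConfig = SimulationConfig(),
    seed: Optional[int] = None,
) -> tuple[dict[str, str], QueryGroundTruth]:
    """Simulate contigs of a genome decoding CUG per *decoding_label*.

    For each family, mutated copies of rows from the matching clade are
    back-translated under the corresponding code.  At each annotated CUG
    column of the matching type where the source residue fits (S for AYCU,
    L for standard), the codon CTG is emitted with probability ``purity``;
    all other codons are drawn uniformly among synonyms excluding CTG, so
    every CTG in a gene is a planted, recorded site.  Genes are packed onto
    contigs with >= 2 x flank intergenic spacers, on the minus strand with
    probability ``minus_strand_fraction``.
    """
    if decoding_label not in DECODING_LABELS:
        raise ValueError(f"unknown decoding label {decoding_label!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    code = AYCU if decoding_label == AYCU_LABEL else STANDARD
    back = _back_table(code)
    planted_residue = "S" if decoding_label == AYCU_LABEL else "L"

    gene_records: list[dict] = []
    for fam in bundle.families:
        ser_cols, leu_cols = annotated_columns_by_type(fam)
        target_cols = ser_cols if decoding_label == AYCU_LABEL else leu_cols
        clade_rows = sorted(
            sid
            for sid in fam.rows
            if fam.decoding[fam.species[sid]] == decoding_label and fam.complete[sid]
        )
        if not clade_rows:
            continue
        for g in range(config.n_query_genes_per_family):
            sid = clade_rows[int(rng.integers(len(clade_rows)))]
            row = fam.rows[sid]
            items: list[tuple[str, Optional[int], bool]] = []  # (aa, column, is_cug)
            for col, ch in enumerate(row):
                if ch == GAP:
                    continue
                is_cug = (
                    col in target_cols
                    and ch == planted_residue
                    and rng.random() < config.purity
                )
                aa = ch
                if not is_cug and rng.random() > config.query_identity:
                    aa = _mutated_aa(rng, aa)
                items.append((aa, col, is_cug))
            # indels (never touching a planted CUG residue)
            edited: list[tuple[str, Optional[int], bool]] = []
            for item in items:
                r = rng.random()
                if r < config.indel_rate / 2 and not item[2]:
                    continue  # deletion
                edited.append(item)
                if r > 1 - config.indel_rate / 2:
                    edited.append((_random_aa(rng), None, False))  # insertion
            codons: list[str] = []
            sites: list[tuple[int, int]] = []
            for idx, (aa, col, is_cug) in enumerate(edited):
                if is_cug:
                    codons.append("CTG")
                    sites.append((idx + 1, col + 1))
                else:
                    syn = back[aa]
                    codons.append(syn[int(rng.integers(len(syn)))])
            gene_records.append(
                {
                    "family_id": fam.family_id,
                    "gene_id": f"{fam.family_id}_q{g:02d}",
                    "protein": "".join(aa for aa, _, _ in edited),
                    "protein_cug_as_leu": "".join(
                        "L" if is_cug else aa for aa, _, is_cug in edited
                    ),
                    "cds": "".join(codons),
                    "cug_sites": tuple(sites),
                }
            )

    def spacer() -> str:
        n = 2 * config.flank + int(rng.integers(0, 201))
        return "".join(_DNA[i] for i in rng.integers(0, 4, size=n))

    contigs: dict[str, str] = {}
    planted: list[PlantedGene] = []
    per_contig = max(1, config.genes_per_contig)
    for ci in range(0, len(gene_records), per_contig):
        contig_id = f"contig{ci // per_contig:03d}"
        parts: list[str] = [spacer()]
        offset = len(parts[0])
        for rec in gene_records[ci : ci + per_contig]:
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            cds = rec["cds"]
            placed = reverse_complement(cds) if strand == "-" else cds
            start = offset
            end = start + len(placed)
            parts.append(placed)
            sp = spacer()
            parts.append(sp)
            offset = end + len(sp)
            planted.append(
                PlantedGene(
                    family_id=rec["family_id"],
                    gene_id=rec["gene_id"],
                    contig_id=contig_id,
                    strand=strand,
                    start=start,
                    end=end,
                    protein=rec["protein"],
                    protein_cug_as_leu=rec["protein_cug_as_leu"],
                    cds=cds,
                    cug_sites=rec["cug_sites"],
                )
            )
        contigs[contig_id] = "".join(parts)
    return contigs, QueryGroundTruth(decoding_label, tuple(planted))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[i] for i in rng.integers(0, 4, size=n))


def _mutate_dna(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    chars = list(seq)
    for p in positions:
        alt = _DNA.replace(chars[p], "")
        chars[p] = alt[int(rng.integers(3))]
    return "".join(chars)


def simulate_trna_refs(
    config: SimulationConfig = SimulationConfig(),
    seed: Optional[int] = None,
) -> tuple[TrnaReferenceSet, dict[str, str]]:
    """Generate leu/ser/other tRNA reference sets (defaults 51/22/34).

    The leu and ser class consensus sequences diverge at >= 25% of non-
    anticodon positions; both carry CAG at anticodon positions 33-35
    (1-based).  Each reference adds per-position noise outside the anticodon.
    The "other" set derives from an unrelated consensus with a random
    non-CAG anticodon per reference.  Returns the set plus an id -> label map.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.trna_length
    anticodon = range(32, 35)  # 0-based slice of the CAG triplet
    non_ac = [i for i in range(n) if i not in anticodon]

    def with_anticodon(seq: str, triplet: str) -> str:
        return seq[:32] + triplet + seq[35:]

    leu_consensus = with_anticodon(_random_dna(rng, n), "CAG")
    n_div = max(1, int(round(0.4 * len(non_ac))))
    div_pos = sorted(rng.choice(len(non_ac), size=n_div, replace=False))
    ser_consensus = _mutate_dna(rng, leu_consensus, [non_ac[i] for i in div_pos])
    other_consensus = _random_dna(rng, n)

    def noisy(consensus: str) -> str:
        pos = [i for i in non_ac if rng.random() < config.trna_noise]
        return _mutate_dna(rng, consensus, pos)

    labels: dict[str, str] = {}
    n_leu, n_ser, n_other = config.trna_sizes
    leu = {}
    for i in range(n_leu):
        rid = f"leu{i:02d}"
        leu[rid] = noisy(leu_consensus)
        labels[rid] = "leu"
    ser = {}
    for i in range(n_ser):
        rid = f"ser{i:02d}"
        ser[rid] = noisy(ser_consensus)
        labels[rid] = "ser"
    other = {}
    triplets = [a + b + c for a in _DNA for b in _DNA for c in _DNA if a + b + c != "CAG"]
    for i in range(n_other):
        rid = f"oth{i:02d}"
        trip = triplets[int(rng.integers(len(triplets)))]
        other[rid] = with_anticodon(noisy(other_consensus), trip)
        labels[rid] = "other"
    return TrnaReferenceSet(leu, ser, other), labels
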