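"""Score CUG sites against reference families and aggregate by majority rule.

Two independent lines of evidence are computed for every CUG codon in a
predicted gene, both read off the alignment column the codon maps to:

* **amino-acid composition** — the residues the reference family shows at
  that column.  Large hydrophobic residues (L, I, V, M, F) indicate a
  leucine position and hence the standard code; small polar residues
  (S, T, C, A) indicate a serine position and hence the Alternative Yeast
  Codon Usage (AYCU).  A simple majority over the column decides; if neither
  class holds a majority the site is ambiguous.  Composition is counted over
  all reference rows, including incompletely assembled genes.
* **CUG-position conservation** — whether reference genes carry a CUG codon
  at the same column, and if so whether those genes come from species that
  decode CUG as leucine or as serine.  Only completely assembled reference
  genes contribute, because a truncated gene cannot vouch for codon
  conservation.

Per-protein and genome-wide verdicts are majority votes over the
non-ambiguous site verdicts of each feature; the combined call requires the
two features to agree.  A query without any CUG codon yields the distinct
state ``"no-evidence"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .homolog_finder import (
    PredictedGene,
    extract_best_gene,
    find_candidate_regions_multi,
    six_frame_translate,
)
from .pairwise_align import GAP, PROTEIN_SCHEME, ScoringScheme
from .profile_mapping import ColumnMap, align_to_profile, align_to_single, build_profile

__all__ = [
    "HYDROPHOBIC",
    "POLAR_SMALL",
    "ReferenceFamily",
    "CugSiteReport",
    "VerdictTally",
    "AggregateVerdict",
    "FamilyPrediction",
    "GenomeVerdict",
    "annotate_cug_sites",
    "composition_verdict",
    "conservation_counts",
    "conservation_verdict",
    "build_site_report",
    "aggregate",
    "predict_decoding",
]

#: Large hydrophobic residues: indicator for leucine, i.e. the standard code.
HYDROPHOBIC = frozenset("LIVMF")
#: Small polar residues: indicator for serine, i.e. the AYCU.
POLAR_SMALL = frozenset("STCA")

STANDARD_LABEL = "standard"
AYCU_LABEL = "aycu"
AMBIGUOUS = "ambiguous"
NO_EVIDENCE = "no-evidence"
DECODING_LABELS = (STANDARD_LABEL, AYCU_LABEL)


@dataclass
class ReferenceFamily:
    """One protein family of the reference data.

    ``rows`` maps sequence id to its gapped alignment row; ``cug_columns``
    marks, per row, the 0-based alignment columns whose residue is encoded by
    CUG; ``complete`` flags fully assembled genes; ``decoding`` gives each
    species' CUG translation scheme.
    """

    family_id: str
    rows: dict[str, str]
    species: dict[str, str]
    complete: dict[str, bool]
    cug_columns: dict[str, frozenset[int]]
    decoding: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> list[str]:
        """Invariant violations as human-readable messages (empty == valid)."""
        errors: list[str] = []
        ncols = self.n_columns
        for sid, row in self.rows.items():
            if len(row) != ncols:
                errors.append(
                    f"family {self.family_id}: row {sid} has length {len(row)}, expected {ncols}"
                )
            sp = self.species.get(sid)
            if sp is None:
                errors.append(f"family {self.family_id}: row {sid} has no species")
            elif sp not in self.decoding:
                errors.append(
                    f"family {self.family_id}: species {sp} of row {sid} has no decoding label"
                )
            elif self.decoding[sp] not in DECODING_LABELS:
                errors.append(
                    f"family {self.family_id}: species {sp} has invalid decoding "
                    f"{self.decoding[sp]!r}"
                )
            if sid not in self.complete:
                errors.append(f"family {self.family_id}: row {sid} has no completeness flag")
            for col in self.cug_columns.get(sid, frozenset()):
                if not (0 <= col < len(row)):
                    errors.append(
                        f"family {self.family_id}: row {sid} CUG annotation at column "
                        f"{col + 1} outside alignment"
                    )
                elif row[col] == GAP:
                    errors.append(
                        f"family {self.family_id}: row {sid} CUG annotation at column "
                        f"{col + 1} points at a gap"
                    )
        for sid in self.cug_columns:
            if sid not in self.rows:
                errors.append(
                    f"family {self.family_id}: CUG annotation for unknown row {sid}"
                )
        return errors

    def representative(self) -> tuple[str, str]:
        """(sequence id, ungapped sequence) of the least-gapped complete row."""
        candidates = [sid for sid, ok in self.complete.items() if ok and sid in self.rows]
        if not candidates:
            candidates = list(self.rows)
        sid = min(candidates, key=lambda s: (self.rows[s].count(GAP), s))
        return sid, self.rows[sid].replace(GAP, "")

    def column_composition(self, column: int) -> Counter:
        """Residue counts at a column over all rows (gaps excluded)."""
        comp: Counter = Counter()
        for row in self.rows.values():
            ch = row[column]
            if ch != GAP:
                comp[ch] += 1
        return comp


@dataclass(frozen=True)
class CugSiteReport:
    """Evidence gathered for one query CUG codon.

    Indices are 1-based; ``column`` is ``None`` when the residue sits in a
    query-only insertion and could not be compared to the reference.
    """

    residue_index: int
    column: Optional[int]
    composition: dict[str, int]
    hydrophobic_count: int
    polar_small_count: int
    cug_as_leu_count: int
    cug_as_ser_count: int
    composition_verdict: str
    conservation_verdict: str


def annotate_cug_sites(
    gene: PredictedGene, colmap: ColumnMap
) -> list[tuple[int, Optional[int]]]:
    """(1-based residue index, 0-based column or None) for every CTG codon."""
    if len(colmap) != len(gene.protein):
        raise ValueError("column map length does not match gene protein length")
    sites: list[tuple[int, Optional[int]]] = []
    for i, codon in enumerate(gene.codons):
        if codon.upper().replace("U", "T") == "CTG":
            sites.append((i + 1, colmap[i]))
    return sites


def composition_verdict(
    composition: Mapping[str, int], *, min_occupancy: int = 5
) -> str:
    """Majority-rule verdict from an alignment column's residue counts.

    ``standard`` if the hydrophobic class outnumbers both the polar-small
    class and all remaining residues; ``aycu`` symmetrically; ties or a
    majority in neither class — or fewer than *min_occupancy* residues —
    give ``ambiguous``.
    """
    n = sum(composition.values())
    if n < min_occupancy:
        return AMBIGUOUS
    h = sum(c for aa, c in composition.items() if aa in HYDROPHOBIC)
    p = sum(c for aa, c in composition.items() if aa in POLAR_SMALL)
    rest = n - h - p
    if h > p and h > rest:
        return STANDARD_LABEL
    if p > h and p > rest:
        return AYCU_LABEL
    return AMBIGUOUS


def conservation_counts(family: ReferenceFamily, column: int) -> tuple[int, int]:
    """(CUG-as-leucine, CUG-as-serine) counts among complete annotated rows."""
    leu = ser = 0
    for sid, cols in family.cug_columns.items():
        if column not in cols or not family.complete.get(sid, False):
            continue
        label = family.decoding[family.species[sid]]
        if label == STANDARD_LABEL:
            leu += 1
        else:
            ser += 1
    return leu, ser


def conservation_verdict(family: ReferenceFamily, column: int) -> str:
    """Majority decoding among complete reference genes with a CUG here."""
    leu, ser = conservation_counts(family, column)
    if leu > ser:
        return STANDARD_LABEL
    if ser > leu:
        return AYCU_LABEL
    return AMBIGUOUS


def build_site_report(
    family: ReferenceFamily,
    residue_index: int,
    column: Optional[int],
    *,
    min_occupancy: int = 5,
) -> CugSiteReport:
    """Assemble both feature verdicts for one CUG site."""
    if column is None:
        return CugSiteReport(
            residue_index=residue_index,
            column=None,
            composition={},
            hydrophobic_count=0,
            polar_small_count=0,
            cug_as_leu_count=0,
            cug_as_ser_count=0,
            composition_verdict=AMBIGUOUS,
            conservation_verdict=AMBIGUOUS,
        )
    comp = family.column_composition(column)
    leu, ser = conservation_counts(family, column)
    return CugSiteReport(
        residue_index=residue_index,
        column=column + 1,
        composition=dict(sorted(comp.items())),
        hydrophobic_count=sum(c for aa, c in comp.items() if aa in HYDROPHOBIC),
        polar_small_count=sum(c for aa, c in comp.items() if aa in POLAR_SMALL),
        cug_as_leu_count=leu,
        cug_as_ser_count=ser,
        composition_verdict=composition_verdict(comp, min_occupancy=min_occupancy),
        conservation_verdict=conservation_verdict(family, column),
    )


@dataclass(frozen=True)
class VerdictTally:
    standard: int = 0
    aycu: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.standard + self.aycu + self.ambiguous

    def majority(self) -> str:
        if self.total == 0:
            return NO_EVIDENCE
        if self.standard > self.aycu:
            return STANDARD_LABEL
        if self.aycu > self.standard:
            return AYCU_LABEL
        return AMBIGUOUS


def _tally(verdicts: Iterable[str]) -> VerdictTally:
    c = Counter(verdicts)
    return VerdictTally(
        standard=c.get(STANDARD_LABEL, 0),
        aycu=c.get(AYCU_LABEL, 0),
        ambiguous=c.get(AMBIGUOUS, 0),
    )


@dataclass(frozen=True)
class AggregateVerdict:
    """Majority-vote summary of site reports at protein or genome level."""

    composition: str
    conservation: str
    combined: str
    composition_tally: VerdictTally
    conservation_tally: VerdictTally
    n_sites: int


def aggregate(site_reports: Sequence[CugSiteReport], level: str = "protein") -> AggregateVerdict:
    """Per-feature majority over site verdicts, plus the combined call.

    The combined verdict is the shared feature verdict when composition and
    conservation agree on a decoding, ``ambiguous`` when they disagree or
    neither feature is decisive, and ``no-evidence`` when there are no CUG
    sites at all.
    """
    comp_t = _tally(r.composition_verdict for r in site_reports)
    cons_t = _tally(r.conservation_verdict for r in site_reports)
    if not site_reports:
        return AggregateVerdict(NO_EVIDENCE, NO_EVIDENCE, NO_EVIDENCE, comp_t, cons_t, 0)
    comp_v = comp_t.majority()
    cons_v = cons_t.majority()
    if comp_v == cons_v and comp_v in DECODING_LABELS:
        combined = comp_v
    else:
        combined = AMBIGUOUS
    return AggregateVerdict(comp_v, cons_v, combined, comp_t, cons_t, len(site_reports))


@dataclass(frozen=True)
class FamilyPrediction:
    """Pipeline output for one reference family."""

    family_id: str
    gene: Optional[PredictedGene]
    column_map: Optional[ColumnMap]
    sites: tuple[CugSiteReport, ...]
    verdict: AggregateVerdict


@dataclass(frozen=True)
class GenomeVerdict:
    """Aggregated decoding call for a whole query genome/transcriptome."""

    families: tuple[FamilyPrediction, ...]
    overall: AggregateVerdict

    @property
    def n_genes(self) -> int:
        return sum(1 for f in self.families if f.gene is not None)

    def all_sites(self) -> list[CugSiteReport]:
        return [s for f in self.families for s in f.sites]


def predict_decoding(
    contigs: Mapping[str, str],
    reference,
    *,
    aligner: str = "profile",
    scheme: ScoringScheme = PROTEIN_SCHEME,
    k: int = 5,
    min_word_hits: int = 3,
    flank: int = 500,
    min_gene_score: int = 50,
    min_occupancy: int = 5,
    cug_aware_mapping: bool = True,
) -> GenomeVerdict:
    """Run the full decoding pipeline on a set of contigs.

    *reference* is a loaded reference bundle or any object with a
    ``families`` attribute yielding :class:`ReferenceFamily` objects.  One
    gene is predicted per family (the best-scoring candidate region wins),
    mapped to the family alignment with the chosen aligner (``profile`` or a
    pairwise fallback ``nw``/``gotoh``/``sw``/``lcs`` against the family
    representative), and its CUG sites are scored.

    Seeding defaults are slightly stricter here (k=5, three word hits) than
    in the single-reference search because every reference row of every
    family seeds at once.  With ``cug_aware_mapping`` (default), CUG-encoded
    residues are treated as leucine-or-serine during column mapping (profile
    aligner) or masked to 'X' (pairwise fallback), so the 'L' they are
    rendered as cannot bias their placement away from serine-type columns;
    the reported gene still shows CUG as 'L'.
    """
    families: Sequence[ReferenceFamily] = getattr(reference, "families", reference)
    reps = {fam.family_id: fam.representative() for fam in families}
    ungapped = {
        fam.family_id: {sid: row.replace(GAP, "") for sid, row in fam.rows.items()}
        for fam in families
    }
    frames = {cid: six_frame_translate(seq) for cid, seq in contigs.items()}
    # every reference sequence seeds the search, as in a translated BLAST
    # over the full reference data; extraction aligns against the row that
    # seeded the region best
    regions = find_candidate_regions_multi(
        contigs,
        ungapped,
        k=k,
        min_word_hits=min_word_hits,
        flank=flank,
        frames=frames,
    )
    predictions: list[FamilyPrediction] = []
    for fam in families:
        rep_sid, rep_seq = reps[fam.family_id]
        best: Optional[PredictedGene] = None
        for region in regions[fam.family_id]:
            partner = ungapped[fam.family_id].get(region.best_seed_row, rep_seq)
            gene = extract_best_gene(
                contigs[region.contig_id],
                region,
                partner,
                scheme,
                min_score=min_gene_score,
                family_id=fam.family_id,
            )
            # tie-break on strand-independent content so that mirrored
            # inputs select the same gene
            if gene is not None and (
                best is None
                or (gene.score, len(gene.protein), gene.protein)
                > (best.score, len(best.protein), best.protein)
            ):
                best = gene
        if best is None:
            predictions.append(
                FamilyPrediction(fam.family_id, None, None, (), aggregate(()))
            )
            continue
        cug_idx = frozenset(
            i for i, c in enumerate(best.codons) if c == "CTG"
        ) if cug_aware_mapping else frozenset()
        if aligner == "profile":
            colmap = align_to_profile(
                best.protein,
                build_profile(list(fam.rows.values()), fam.family_id),
                scheme,
                leu_ser_ambiguous=cug_idx,
            )
        else:
            map_protein = "".join(
                "X" if i in cug_idx else ch for i, ch in enumerate(best.protein)
            )
            colmap = align_to_single(map_protein, fam.rows[rep_sid], aligner, scheme)
        sites = tuple(
            build_site_report(fam, res, col, min_occupancy=min_occupancy)
            for res, col in annotate_cug_sites(best, colmap)
        )
        predictions.append(
            FamilyPrediction(fam.family_id, best, colmap, sites, aggregate(sites))
        )
    overall = aggregate([s for p in predictions for s in p.sites], level="genome")
    return GenomeVerdict(tuple(predictions), overall)
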