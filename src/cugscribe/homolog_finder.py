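"""Locate and extract candidate coding regions homologous to reference proteins.

The search is a deterministic translated homology scan: contigs are translated
in all six frames, exact protein k-mers shared with a reference are clustered
into candidate regions, each region is extended by a flank (default 500 nt,
because gene extraction works better with intergenic context included), and
the best-scoring local alignment between a region's frame translations and
the reference yields a single-exon gene model.

CTG is rendered as leucine throughout the search, whatever the organism's
actual decoding — homology detection must stay agnostic to the very question
the pipeline answers.  The CUG decision is made downstream from the extracted
codon coordinates, never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .genetic_codes import STANDARD, translate
from .pairwise_align import PROTEIN_SCHEME, ScoringScheme, smith_waterman

__all__ = [
    "FrameTranslation",
    "CandidateRegion",
    "PredictedGene",
    "reverse_complement",
    "six_frame_translate",
    "find_candidate_regions",
    "find_candidate_regions_multi",
    "extract_best_gene",
]

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a contig.

    ``frame`` is +1..+3 for the forward strand and -1..-3 for frames of the
    reverse complement.  ``codon_starts[i]`` is the smallest forward-strand
    coordinate of residue *i*'s codon, so every residue is traceable to its
    nucleotide triple regardless of strand.
    """

    frame: int
    protein: str
    codon_starts: np.ndarray

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def six_frame_translate(contig: str) -> list[FrameTranslation]:
    """Translate a contig in all six frames with coordinate maps."""
    L = len(contig)
    out: list[FrameTranslation] = []
    for f in range(3):
        prot = translate(contig[f:], STANDARD)
        starts = f + 3 * np.arange(len(prot), dtype=np.int64)
        out.append(FrameTranslation(f + 1, prot, starts))
    rc = reverse_complement(contig)
    for f in range(3):
        prot = translate(rc[f:], STANDARD)
        # residue i sits on rc[f+3i : f+3i+3] == forward [L-f-3i-3, L-f-3i)
        starts = L - f - 3 * np.arange(len(prot), dtype=np.int64) - 3
        out.append(FrameTranslation(-(f + 1), prot, starts))
    return out


@dataclass(frozen=True)
class CandidateRegion:
    """A flank-extended genomic interval that may contain a homolog.

    Coordinates are 0-based half-open on the forward strand, clamped to the
    contig.  Regions produced for one contig and strand never overlap.
    ``best_seed_row`` names the reference sequence contributing the most
    seeds (when the search ran with several references per family); it is
    the natural alignment partner for gene extraction.
    """

    contig_id: str
    strand: str
    start: int
    end: int
    n_seeds: int
    flank: int
    best_seed_row: Optional[str] = None


def _cluster_positions(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    clusters: list[list[int]] = []
    for q in positions:
        if clusters and q - clusters[-1][-1] <= max_gap:
            clusters[-1].append(q)
        else:
            clusters.append([q])
    return clusters


def _merge_regions_with_row(
    regions: list[tuple[int, int, int, str]]
) -> list[tuple[int, int, int, str]]:
    """Merge overlapping/touching (start, end, n_seeds, best_row) intervals.

    The merged interval keeps the best row of its largest seed cluster.
    """
    merged: list[tuple[int, int, int, str]] = []
    best: list[tuple[int, str]] = []  # (n_seeds of the dominant cluster, row)
    for start, end, n, sid in sorted(regions):
        if merged and start <= merged[-1][1]:
            ps, pe, pn, psid = merged[-1]
            bn, bsid = best[-1]
            if n > bn:
                bn, bsid = n, sid
            merged[-1] = (ps, max(pe, end), pn + n, bsid)
            best[-1] = (bn, bsid)
        else:
            merged.append((start, end, n, sid))
            best.append((n, sid))
    return merged


def find_candidate_regions_multi(
    contigs: Mapping[str, str],
    references: Mapping[str, Union[str, Mapping[str, str]]],
    *,
    k: int = 4,
    min_word_hits: int = 2,
    flank: int = 500,
    frames: Optional[Mapping[str, list[FrameTranslation]]] = None,
) -> dict[str, list[CandidateRegion]]:
    """Seed-and-cluster search for several protein families in one scan.

    Each family may be searched with a single reference protein or — as the
    pipeline does, mirroring a translated BLAST over every reference
    sequence — with all of its reference sequences at once
    (``{family: {seq_id: ungapped_protein}}``).  One shared k-mer index over
    everything keeps the contig translations from being rescanned per family.
    Per family, seed positions from all its references are clustered jointly;
    each region records the reference row that contributed the most seeds.
    """
    fam_refs: dict[str, dict[str, str]] = {}
    for fam, ref in references.items():
        fam_refs[fam] = {fam: ref} if isinstance(ref, str) else dict(ref)
        for sid, seq in fam_refs[fam].items():
            if len(seq) < k:
                raise ValueError(f"reference {sid!r} shorter than word size k={k}")
    # word -> {family: [(reference position, row id), ...]}
    index: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for fam, rows in fam_refs.items():
        for sid, seq in rows.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], {}).setdefault(fam, []).append((i, sid))
    max_len = {fam: max(len(s) for s in rows.values()) for fam, rows in fam_refs.items()}

    raw: dict[str, dict[tuple[str, str], list[tuple[int, int, int, str]]]] = {
        fam: {} for fam in fam_refs
    }
    band = 32  # diagonal tolerance (aa); hits off by more cannot be one gene
    for contig_id, seq in contigs.items():
        fts = frames[contig_id] if frames is not None else six_frame_translate(seq)
        for ft in fts:
            prot = ft.protein
            hits: dict[str, list[tuple[int, int, str]]] = {}  # fam -> (q, diag, row)
            for q in range(len(prot) - k + 1):
                sources = index.get(prot[q : q + k])
                if sources:
                    for fam, entries in sources.items():
                        bucket = hits.setdefault(fam, [])
                        for rpos, sid in entries:
                            bucket.append((q, q - rpos, sid))
            for fam, triples in hits.items():
                max_gap = max(60, max_len[fam])
                by_band: dict[int, list[tuple[int, int, str]]] = {}
                for q, diag, sid in triples:
                    by_band.setdefault(diag // band, []).append((q, diag, sid))
                for members in by_band.values():
                    qs = sorted({q for q, _, _ in members})
                    for cluster in _cluster_positions(qs, max_gap):
                        if len(cluster) < min_word_hits:
                            continue
                        lo_q, hi_q = cluster[0], cluster[-1]
                        per_row: dict[str, int] = {}
                        for q, _, sid in members:
                            if lo_q <= q <= hi_q:
                                per_row[sid] = per_row.get(sid, 0) + 1
                        best_sid = max(sorted(per_row), key=lambda s: per_row[s])
                        coords: list[int] = []
                        for q in (lo_q, hi_q):
                            coords.append(int(ft.codon_starts[q]))
                            coords.append(int(ft.codon_starts[q + k - 1]))
                        lo = max(0, min(coords) - flank)
                        hi = min(len(seq), max(coords) + 3 + flank)
                        key = (contig_id, ft.strand)
                        raw[fam].setdefault(key, []).append((lo, hi, len(cluster), best_sid))

    out: dict[str, list[CandidateRegion]] = {fam: [] for fam in fam_refs}
    for fam, by_key in raw.items():
        for (contig_id, strand), intervals in sorted(by_key.items()):
            for start, end, n, sid in _merge_regions_with_row(intervals):
                out[fam].append(
                    CandidateRegion(contig_id, strand, start, end, n, flank, sid)
                )
    return out


def find_candidate_regions(
    contigs: Mapping[str, str],
    reference_protein: str,
    *,
    k: int = 4,
    min_word_hits: int = 2,
    flank: int = 500,
    frames: Optional[Mapping[str, list[FrameTranslation]]] = None,
) -> list[CandidateRegion]:
    """Candidate regions for a single reference protein (see the multi variant)."""
    return find_candidate_regions_multi(
        contigs,
        {"query": reference_protein},
        k=k,
        min_word_hits=min_word_hits,
        flank=flank,
        frames=frames,
    )["query"]


@dataclass(frozen=True)
class PredictedGene:
    """A single-exon gene model extracted from a candidate region.

    ``protein`` renders every CTG codon as 'L'.  ``codon_starts[i]`` is the
    forward-strand coordinate of the first nucleotide of residue *i*'s codon;
    the map is strictly monotone (increasing on '+', decreasing on '-').
    ``codons`` holds the sense-strand triplets, so translating them with the
    standard code reproduces ``protein``.
    """

    family_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    protein: str
    codons: tuple[str, ...]
    codon_starts: tuple[int, ...]
    score: int

    def cug_residues(self) -> list[int]:
        """1-based residue indices encoded by CTG."""
        return [i + 1 for i, c in enumerate(self.codons) if c == "CTG"]


def extract_best_gene(
    contig_seq: str,
    region: CandidateRegion,
    reference_protein: str,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    *,
    min_score: int = 50,
    family_id: str = "",
) -> Optional[PredictedGene]:
    """Best local alignment of the region's frame translations vs the reference.

    Only the region's own strand is searched (seeds already fixed the strand).
    Returns ``None`` when no frame reaches *min_score*.
    """
    sub = contig_seq[region.start : region.end]
    fts = six_frame_translate(sub)
    wanted = [ft for ft in fts if ft.strand == region.strand]
    best = None
    best_ft = None
    for ft in wanted:
        if not ft.protein:
            continue
        aln = smith_waterman(ft.protein, reference_protein, scheme)
        if best is None or aln.score > best.score:
            best = aln
            best_ft = ft
    if best is None or best.score < min_score:
        return None
    prot = best_ft.protein[best.a_start : best.a_end]
    starts = [int(s) + region.start for s in best_ft.codon_starts[best.a_start : best.a_end]]
    if region.strand == "+":
        codons = tuple(contig_seq[s : s + 3] for s in starts)
    else:
        codons = tuple(reverse_complement(contig_seq[s : s + 3]) for s in starts)
    nt_lo = min(starts)
    nt_hi = max(starts) + 3
    return PredictedGene(
        family_id=family_id,
        contig_id=region.contig_id,
        strand=region.strand,
        start=nt_lo,
        end=nt_hi,
        protein=prot,
        codons=codons,
        codon_starts=tuple(starts),
        score=int(best.score),
    )
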