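"""Classify a tRNA with CAG anticodon as leucine-type, serine-type, or other.

The amino-acid identity of the tRNA whose anticodon (CAG) reads the CUG codon
determines the genetic code of the species, so this classification is the
pipeline's independent second line of evidence.  A query is compared by
Smith-Waterman score against three labelled reference sets (leu-tRNA_CAG,
ser-tRNA_CAG, and tRNAs with other anticodons); the best-scoring class wins
and the margin over the runner-up class is reported so users can judge
confidence.  Secondary-structure prediction is out of scope: the anticodon is
located positionally within the loop window of a standard-length tRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .pairwise_align import AlignmentResult, DNA_SCHEME, ScoringScheme, smith_waterman

__all__ = ["TrnaReferenceSet", "TrnaCall", "find_cag_anticodon", "classify_trna"]

LABELS = ("leu", "ser", "other")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TrnaReferenceSet:
    """Three labelled tRNA collections (id -> DNA sequence, introns removed)."""

    leu_cag: Mapping[str, str]
    ser_cag: Mapping[str, str]
    other: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.leu_cag or not self.ser_cag:
            raise ValueError("leu and ser reference sets must be non-empty")

    def by_label(self, label: str) -> Mapping[str, str]:
        return {"leu": self.leu_cag, "ser": self.ser_cag, "other": self.other}[label]

    def swapped(self) -> "TrnaReferenceSet":
        """Leu and ser sets exchanged (used to test label symmetry)."""
        return TrnaReferenceSet(self.ser_cag, self.leu_cag, self.other)

    def without(self, label: str, ref_id: str) -> "TrnaReferenceSet":
        """Copy with one reference removed (for leave-one-out checks)."""
        sets = {lab: dict(self.by_label(lab)) for lab in LABELS}
        sets[label].pop(ref_id, None)
        return TrnaReferenceSet(sets["leu"], sets["ser"], sets["other"])


@dataclass(frozen=True)
class TrnaCall:
    """Classification of one query tRNA.

    ``margin`` is the best class score minus the runner-up class score
    (zero for ties and for unclassifiable queries).
    """

    label: str
    scores: dict[str, int]
    margin: int
    nearest_id: Optional[str]
    alignment: Optional[AlignmentResult]


def find_cag_anticodon(
    trna: str,
    *,
    window: tuple[int, int] = (32, 38),
    length_range: tuple[int, int] = (70, 95),
) -> Optional[int]:
    """1-based start of a CAG triplet inside the anticodon-loop window.

    Returns ``None`` when the sequence length is outside *length_range* or no
    CAG starts within the window (both bounds inclusive, 1-based).
    """
    s = _normalize(trna)
    if not (length_range[0] <= len(s) <= length_range[1]):
        return None
    for p in range(window[0], window[1] + 1):
        if s[p - 1 : p + 2] == "CAG":
            return p
    return None


def classify_trna(
    query: str,
    refs: TrnaReferenceSet,
    scheme: ScoringScheme = DNA_SCHEME,
    *,
    min_score: int = 100,
) -> TrnaCall:
    """Nearest-reference classification by best Smith-Waterman score per class.

    The label is the arg-max class; queries scoring below *min_score*
    everywhere, or tying between the two best classes, are labelled
    ``"none"``.  Case and U/T spelling of the query are irrelevant.
    """
    q = _normalize(query)
    best_per_class: dict[str, int] = {}
    nearest: dict[str, tuple[str, AlignmentResult]] = {}
    for label in LABELS:
        refs_of = refs.by_label(label)
        for ref_id in sorted(refs_of):
            aln = smith_waterman(q, _normalize(refs_of[ref_id]), scheme)
            if label not in best_per_class or aln.score > best_per_class[label]:
                best_per_class[label] = int(aln.score)
                nearest[label] = (ref_id, aln)
    ranked = sorted(best_per_class.items(), key=lambda kv: (-kv[1], kv[0]))
    top_label, top_score = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0
    margin = top_score - runner_up
    if top_score < min_score or (len(ranked) > 1 and margin == 0):
        return TrnaCall("none", best_per_class, 0, None, None)
    ref_id, aln = nearest[top_label]
    return TrnaCall(top_label, best_per_class, margin, ref_id, aln)
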