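"""Codon tables and translation utilities for the two yeast decoding schemes.

Most *Saccharomycetes* translate the CUG codon (DNA ``CTG``) as leucine, as in
the standard genetic code.  A subset of yeasts — many but not all of the
"*Candida*" species — decode the same codon as serine; this variant is known
as the Alternative Yeast Codon Usage (AYCU).  The two codon tables differ at
exactly this one codon, which is what makes CUG positions diagnostic for the
decoding scheme.

This module provides the two tables, a codon-by-codon translator, and a
verification routine that compares a given protein against the re-translation
of its own cDNA and highlights every CUG-encoded residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "GeneticCode",
    "STANDARD",
    "AYCU",
    "CODES",
    "TranslationCheckReport",
    "translate",
    "cug_codon_positions",
    "check_translation",
]

#: Canonical one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# IUPAC nucleotide letters accepted by the translator.  Ambiguity codes are
# legal input; any codon containing one translates to 'X'.
_VALID_NT = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry DNA codon table.

    Parameters
    ----------
    name:
        ``"standard"`` or ``"aycu"``.
    table:
        Mapping of the 64 uppercase DNA codons to a one-letter amino acid or
        ``"*"`` for a stop codon.
    """

    name: str
    table: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(
                f"genetic code {self.name!r} has {len(self.table)} codons, expected 64"
            )
        bad = {aa for aa in self.table.values() if aa != "*" and aa not in AMINO_ACIDS}
        if bad:
            raise ValueError(f"genetic code {self.name!r} has invalid amino acids: {bad}")

    def __getitem__(self, codon: str) -> str:
        return self.table[codon]

    def codons_for(self, amino_acid: str) -> list[str]:
        """All codons translating to *amino_acid*, in alphabetical order."""
        return sorted(c for c, aa in self.table.items() if aa == amino_acid)


def _standard_table() -> dict[str, str]:
    ncbi = _CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        table[stop] = "*"
    return table


STANDARD = GeneticCode("standard", _standard_table())
#: Alternative Yeast Codon Usage: identical to the standard code except that
#: CTG encodes serine instead of leucine.
AYCU = GeneticCode("aycu", {**_standard_table(), "CTG": "S"})

CODES: Mapping[str, GeneticCode] = {"standard": STANDARD, "aycu": AYCU}


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_NT
    if bad:
        for pos, ch in enumerate(s):
            if ch in bad:
                raise ValueError(
                    f"invalid nucleotide {ch!r} at position {pos + 1}"
                )
    return s


def translate(
    mrna: str,
    code: GeneticCode = STANDARD,
    *,
    stop_char: str = "*",
    trim_at_stop: bool = False,
) -> str:
    """Translate a nucleotide sequence codon by codon.

    The sequence is split into consecutive triplets; 1–2 trailing nucleotides
    are ignored.  ``U`` is accepted as a synonym of ``T`` and case does not
    matter.  Codons containing ``N`` (or any other ambiguity code) yield
    ``'X'``.  Stop codons render as *stop_char* and translation continues past
    them unless *trim_at_stop* is set — internal stops are something to report
    to the user, not a reason to truncate silently.
    """
    s = _normalize(mrna)
    table = code.table
    out: list[str] = []
    for i in range(0, len(s) - len(s) % 3, 3):
        aa = table.get(s[i : i + 3], "X")
        if aa == "*":
            if trim_at_stop:
                break
            aa = stop_char
        out.append(aa)
    return "".join(out)


def cug_codon_positions(cdna: str) -> list[int]:
    """1-based residue indices whose codon is CTG (equivalently CUG)."""
    s = _normalize(cdna)
    return [i // 3 + 1 for i in range(0, len(s) - len(s) % 3, 3) if s[i : i + 3] == "CTG"]


@dataclass(frozen=True)
class TranslationCheckReport:
    """Result of verifying a protein against the translation of its cDNA.

    ``mismatches`` holds ``(residue_index, given_aa, retranslated_aa)``
    triples with 1-based indices; ``cug_positions`` lists every CTG-encoded
    residue whether or not it mismatches.  ``corrected`` is the full
    re-translation under the requested code.
    """

    cug_positions: tuple[int, ...]
    mismatches: tuple[tuple[int, str, str], ...]
    corrected: str

    @property
    def is_consistent(self) -> bool:
        return not self.mismatches


def check_translation(
    protein: str,
    cdna: str,
    code: GeneticCode = STANDARD,
    *,
    stop_char: str = "*",
) -> TranslationCheckReport:
    """Compare *protein* against the re-translation of *cdna* under *code*.

    The cDNA must encode exactly ``len(protein)`` residues (1–2 trailing
    nucleotides are tolerated).  ``'X'`` on either side never counts as a
    mismatch: an unknown residue is unknowable, not wrong.
    """
    s = _normalize(cdna)
    n = len(protein)
    if not (3 * n <= len(s) <= 3 * n + 2):
        raise ValueError(
            f"cDNA length {len(s)} does not match protein length {n} "
            f"(expected {3 * n} to {3 * n + 2} nucleotides)"
        )
    correct = translate(s, code, stop_char=stop_char)
    mismatches = tuple(
        (i + 1, g, c)
        for i, (g, c) in enumerate(zip(protein.upper(), correct))
        if g != c and g != "X" and c != "X"
    )
    return TranslationCheckReport(
        cug_positions=tuple(cug_codon_positions(s)),
        mismatches=mismatches,
        corrected=correct,
    )
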