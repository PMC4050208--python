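"""Shared I/O, reference-bundle validation, and report rendering.

On-disk reference bundle layout (the same layout the generator emits and the
``predict`` command consumes)::

    bundle/
      families/<family_id>.fasta   aligned FASTA, one file per family
      sequences.tsv                seq_id  species  complete (yes/no)
      cug_annotations.tsv          family  seq_id  column (1-based)
      species.tsv                  species  code (standard|aycu)
      trna/leu_cag.fa ser_cag.fa other.fa   optional tRNA references

JSON is the canonical machine-readable report format; TSV serves spreadsheet
use, and the text rendering mirrors a summary/per-protein-detail split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .cug_classifier import GenomeVerdict, ReferenceFamily
from .synthetic_data import ReferenceBundle
from .trna_classifier import TrnaCall, TrnaReferenceSet

__all__ = [
    "BundleValidationError",
    "read_fasta",
    "write_fasta",
    "load_reference_bundle",
    "save_reference_bundle",
    "PredictionReport",
    "render_report",
    "setup_logging",
]

logger = logging.getLogger("cugscribe")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=None,  # stderr
    )


class BundleValidationError(ValueError):
    """Raised when a reference bundle violates its invariants."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid reference bundle:\n" + "\n".join(errors))


def read_fasta(path: Union[str, Path]) -> list[SeqRecord]:
    """Read FASTA records; duplicate ids are rejected, an empty file warns."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(
    records: Iterable[Union[SeqRecord, tuple[str, str]]],
    path: Union[str, Path],
    *,
    wrap: int = 80,
) -> None:
    """Write records (SeqRecord or (id, sequence) pairs) wrapped at 80 columns."""
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=wrap).write_file(recs)


def _read_trna_sets(trna_dir: Path) -> Optional[TrnaReferenceSet]:
    files = {
        "leu": trna_dir / "leu_cag.fa",
        "ser": trna_dir / "ser_cag.fa",
        "other": trna_dir / "other.fa",
    }
    if not all(f.exists() for f in files.values()):
        return None
    sets = {
        label: {rec.id: str(rec.seq) for rec in read_fasta(f)}
        for label, f in files.items()
    }
    return TrnaReferenceSet(sets["leu"], sets["ser"], sets["other"])


def load_reference_bundle(directory: Union[str, Path]) -> ReferenceBundle:
    """Load and validate a reference bundle; every violation is reported."""
    directory = Path(directory)
    errors: list[str] = []

    species_df = pd.read_csv(directory / "species.tsv", sep="\t", dtype=str)
    decoding: dict[str, str] = {}
    for _, row in species_df.iterrows():
        code = row["code"]
        if code not in ("standard", "aycu"):
            errors.append(f"species.tsv: species {row['species']} has invalid code {code!r}")
        decoding[row["species"]] = code

    seq_df = pd.read_csv(directory / "sequences.tsv", sep="\t", dtype=str)
    species_of: dict[str, str] = {}
    complete: dict[str, bool] = {}
    for _, row in seq_df.iterrows():
        sid = row["seq_id"]
        species_of[sid] = row["species"]
        flag = str(row["complete"]).strip().lower()
        if flag not in ("yes", "no"):
            errors.append(f"sequences.tsv: row {sid} has invalid complete flag {row['complete']!r}")
        complete[sid] = flag == "yes"

    ann_df = pd.read_csv(directory / "cug_annotations.tsv", sep="\t")
    annotations: dict[str, dict[str, set[int]]] = {}
    for _, row in ann_df.iterrows():
        annotations.setdefault(str(row["family"]), {}).setdefault(
            str(row["seq_id"]), set()
        ).add(int(row["column"]) - 1)

    families: list[ReferenceFamily] = []
    fam_dir = directory / "families"
    for fasta in sorted(fam_dir.glob("*.fasta")):
        fid = fasta.stem
        try:
            records = read_fasta(fasta)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        rows = {rec.id: str(rec.seq).upper() for rec in records}
        fam_ann = {
            sid: frozenset(cols) for sid, cols in annotations.get(fid, {}).items()
        }
        for sid in fam_ann:
            if sid not in rows:
                errors.append(
                    f"cug_annotations.tsv: family {fid} annotation for unknown sequence {sid}"
                )
        fam = ReferenceFamily(
            family_id=fid,
            rows=rows,
            species={sid: species_of.get(sid, "") for sid in rows},
            complete={sid: complete.get(sid, False) for sid in rows},
            cug_columns={sid: cols for sid, cols in fam_ann.items() if sid in rows},
            decoding=decoding,
        )
        for sid in rows:
            if sid not in species_of:
                errors.append(f"family {fid}: sequence {sid} missing from sequences.tsv")
        errors.extend(fam.validate())
        families.append(fam)

    if not families:
        errors.append(f"no family alignments found under {fam_dir}")
    if errors:
        raise BundleValidationError(errors)

    trna = _read_trna_sets(directory / "trna")
    return ReferenceBundle(tuple(families), decoding, trna)


def save_reference_bundle(
    bundle: ReferenceBundle, directory: Union[str, Path]
) -> None:
    """Write a bundle in the on-disk layout ``load_reference_bundle`` reads."""
    directory = Path(directory)
    fam_dir = directory / "families"
    fam_dir.mkdir(parents=True, exist_ok=True)
    seq_rows = []
    ann_rows = []
    for fam in bundle.families:
        write_fasta(
            [(sid, fam.rows[sid]) for sid in sorted(fam.rows)],
            fam_dir / f"{fam.family_id}.fasta",
        )
        for sid in sorted(fam.rows):
            seq_rows.append(
                {
                    "seq_id": sid,
                    "species": fam.species[sid],
                    "complete": "yes" if fam.complete[sid] else "no",
                }
            )
            for col in sorted(fam.cug_columns.get(sid, frozenset())):
                ann_rows.append(
                    {"family": fam.family_id, "seq_id": sid, "column": col + 1}
                )
    pd.DataFrame(seq_rows, columns=["seq_id", "species", "complete"]).to_csv(
        directory / "sequences.tsv", sep="\t", index=False
    )
    pd.DataFrame(ann_rows, columns=["family", "seq_id", "column"]).to_csv(
        directory / "cug_annotations.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(bundle.decoding.items()), columns=["species", "code"]
    ).to_csv(directory / "species.tsv", sep="\t", index=False)
    if bundle.trna is not None:
        trna_dir = directory / "trna"
        trna_dir.mkdir(exist_ok=True)
        for label, fname in (("leu", "leu_cag.fa"), ("ser", "ser_cag.fa"), ("other", "other.fa")):
            refs = bundle.trna.by_label(label)
            write_fasta(sorted(refs.items()), trna_dir / fname)


# --------------------------------------------------------------------------
# Prediction reports
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionReport:
    """Serializable summary of a pipeline run.

    ``metadata`` records inputs, parameters and seed so the run can be
    reproduced exactly; ``families`` holds per-family gene predictions and
    per-site CUG evidence; ``overall`` the genome-level verdicts.
    """

    metadata: dict
    overall: dict
    families: list[dict]
    trna: Optional[dict] = None

    @classmethod
    def from_verdict(
        cls,
        verdict: GenomeVerdict,
        metadata: Optional[dict] = None,
        trna_call: Optional[TrnaCall] = None,
    ) -> "PredictionReport":
        families = []
        for fp in verdict.families:
            gene = None
            if fp.gene is not None:
                gene = {
                    "contig_id": fp.gene.contig_id,
                    "strand": fp.gene.strand,
                    "start": fp.gene.start + 1,  # 1-based inclusive in reports
                    "end": fp.gene.end,
                    "score": fp.gene.score,
                    "protein": fp.gene.protein,
                }
            families.append(
                {
                    "family_id": fp.family_id,
                    "gene": gene,
                    "verdict": _verdict_dict(fp.verdict),
                    "sites": [asdict(s) for s in fp.sites],
                }
            )
        trna = None
        if trna_call is not None:
            trna = {
                "label": trna_call.label,
                "scores": dict(trna_call.scores),
                "margin": trna_call.margin,
                "nearest_id": trna_call.nearest_id,
            }
        return cls(
            metadata=metadata or {},
            overall=_verdict_dict(verdict.overall),
            families=families,
            trna=trna,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PredictionReport":
        data = json.loads(text)
        return cls(
            metadata=data["metadata"],
            overall=data["overall"],
            families=data["families"],
            trna=data.get("trna"),
        )

    def site_table(self) -> pd.DataFrame:
        """One row per CUG site; residue and column indices are 1-based."""
        rows = []
        for fam in self.families:
            for site in fam["sites"]:
                rows.append(
                    {
                        "family": fam["family_id"],
                        "residue": site["residue_index"],
                        "column": site["column"],
                        "hydrophobic": site["hydrophobic_count"],
                        "polar_small": site["polar_small_count"],
                        "cug_as_leu": site["cug_as_leu_count"],
                        "cug_as_ser": site["cug_as_ser_count"],
                        "composition_verdict": site["composition_verdict"],
                        "conservation_verdict": site["conservation_verdict"],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "family",
                "residue",
                "column",
                "hydrophobic",
                "polar_small",
                "cug_as_leu",
                "cug_as_ser",
                "composition_verdict",
                "conservation_verdict",
            ],
        )

    def render_text(self) -> str:
        lines = ["CUG decoding prediction", "=" * 23, "", "Summary", "-" * 7]
        ov = self.overall
        if ov["combined"] == "no-evidence":
            lines.append("no-evidence: the query contains no CUG codons mappable to the reference")
        else:
            lines.append(f"combined verdict:      {ov['combined']}")
        lines.append(f"composition feature:   {ov['composition']} "
                     f"(standard {ov['composition_tally']['standard']}, "
                     f"aycu {ov['composition_tally']['aycu']}, "
                     f"ambiguous {ov['composition_tally']['ambiguous']})")
        lines.append(f"conservation feature:  {ov['conservation']} "
                     f"(standard {ov['conservation_tally']['standard']}, "
                     f"aycu {ov['conservation_tally']['aycu']}, "
                     f"ambiguous {ov['conservation_tally']['ambiguous']})")
        lines.append(f"CUG sites analysed:    {ov['n_sites']}")
        if self.trna is not None:
            lines.append(
                f"tRNA_CAG identity:     {self.trna['label']} (margin {self.trna['margin']})"
            )
        lines += ["", "Per-family detail", "-" * 17]
        for fam in self.families:
            gene = fam["gene"]
            if gene is None:
                lines.append(f"{fam['family_id']}: no gene predicted")
                continue
            v = fam["verdict"]
            lines.append(
                f"{fam['family_id']}: {gene['contig_id']}:{gene['start']}-{gene['end']} "
                f"({gene['strand']}) score {gene['score']} | "
                f"composition {v['composition']}, conservation {v['conservation']}, "
                f"combined {v['combined']}"
            )
            for site in fam["sites"]:
                col = site["column"] if site["column"] is not None else "insertion"
                lines.append(
                    f"    CUG at residue {site['residue_index']} -> column {col}: "
                    f"H={site['hydrophobic_count']} P={site['polar_small_count']} "
                    f"cug-leu={site['cug_as_leu_count']} cug-ser={site['cug_as_ser_count']} "
                    f"[{site['composition_verdict']}/{site['conservation_verdict']}]"
                )
        return "\n".join(lines) + "\n"


def _verdict_dict(v) -> dict:
    return {
        "composition": v.composition,
        "conservation": v.conservation,
        "combined": v.combined,
        "composition_tally": asdict(v.composition_tally),
        "conservation_tally": asdict(v.conservation_tally),
        "n_sites": v.n_sites,
    }


def render_report(report: PredictionReport, format: str = "json") -> str:
    """Serialize a report as ``json``, ``tsv`` (site table) or ``text``."""
    if format == "json":
        return report.to_json()
    if format == "tsv":
        return report.site_table().to_csv(sep="\t", index=False)
    if format == "text":
        return report.render_text()
    raise ValueError(f"unknown report format {format!r}")
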