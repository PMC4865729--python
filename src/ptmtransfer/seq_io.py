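"""Reading, writing and validation of proteomes and PTM site annotations.

Proteomes are plain FASTA; site annotations are TSV.  Two annotation
dialects are accepted:

* the canonical tidy form, one row per **site**, with a required header
  ``protein_id  position  residue  ptm_type`` and an optional trailing
  ``organism`` column;
* a compact per-protein form, one row per **protein**:
  ``protein_id<TAB>pos1:res1:type1,pos2:res2:type2,...`` (no header).

Positions are 1-based and inclusive everywhere in user-facing I/O.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid letters.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Letters legal in a normalized sequence ('X' = unknown residue, also the pad).
ALLOWED_LETTERS = frozenset(STANDARD_AA + "X")
#: Ambiguity / non-standard codes folded into 'X' on input.
_AMBIGUOUS = {"B", "Z", "U", "O", "J"}


class SeqIOError(ValueError):
    """Raised for unrecoverable input-format or validation problems."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence of a proteome."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record with empty id")
        if not self.sequence:
            raise SeqIOError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            raise SeqIOError(
                f"protein {self.id!r} contains illegal letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise SeqIOError(
                f"position {position} out of range for protein {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    """An experimentally known PTM site (1-based position)."""

    protein_id: str
    position: int
    residue: str
    ptm_type: str
    organism: str | None = None

    def key(self) -> tuple[str, int, str]:
        """Identity of the site: (protein, position, PTM type)."""
        return (self.protein_id, self.position, self.ptm_type)


@dataclass
class RejectedRow:
    line: int
    content: str
    reason: str


@dataclass
class AnnotationReport:
    """Outcome of validating an annotation table against a proteome."""

    accepted: list[SiteAnnotation]
    rejected: list[RejectedRow] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["line", "content", "reason"])
            for r in self.rejected:
                w.writerow([r.line, r.content, r.reason])


def normalize_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase, strip trailing stop codons, fold non-standard letters to 'X'."""
    seq = raw.strip().upper().rstrip("*")
    out = []
    for ch in seq:
        if ch in ALLOWED_LETTERS:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("X")
        else:
            raise SeqIOError(f"illegal sequence character {ch!r}{context}")
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are normalized (see :func:`normalize_sequence`); duplicate ids
    and empty files are hard errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # e.g. sequence data before the first header
        raise SeqIOError(f"malformed FASTA {path}: {exc}") from exc
    if not parsed:
        raise SeqIOError(f"FASTA file {path} contains no records")
    for rec in parsed:
        if rec.id in seen:
            raise SeqIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = normalize_sequence(str(rec.seq), context=f" in record {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column FASTA.  Round-trips through :func:`read_fasta`."""
    if not records:
        raise SeqIOError("refusing to write an empty FASTA file")
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def _iter_site_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            yield lineno, [c.strip() for c in row]


def _parse_tidy(rows: list[tuple[int, list[str]]], header: list[str]):
    cols = {name: i for i, name in enumerate(header)}
    for required in ("protein_id", "position", "residue", "ptm_type"):
        if required not in cols:
            raise SeqIOError(f"annotation header missing column {required!r}")
    for lineno, row in rows:
        fields = {name: row[i] if i < len(row) else "" for name, i in cols.items()}
        yield lineno, "\t".join(row), fields


def _parse_per_protein(rows: list[tuple[int, list[str]]]):
    for lineno, row in rows:
        if len(row) != 2:
            yield lineno, "\t".join(row), None
            continue
        protein_id, triplets = row
        for triplet in triplets.split(","):
            parts = triplet.split(":")
            if len(parts) != 3:
                yield lineno, "\t".join(row), None
                break
            pos, res, ptm = parts
            yield lineno, "\t".join(row), {
                "protein_id": protein_id,
                "position": pos,
                "residue": res,
                "ptm_type": ptm,
                "organism": "",
            }


def read_annotations(
    path: str | Path,
    proteome: Sequence[ProteinRecord],
    *,
    report_path: str | Path | None = None,
) -> AnnotationReport:
    """Read and validate a PTM-site annotation table against a loaded proteome.

    Every accepted row satisfies ``residue == sequence[position]`` (1-based)
    for a protein present in the proteome.  Bad rows are rejected with a
    reason, never fatal on their own; an annotation file from which *no* row
    survives is a hard error.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteome}
    all_rows = list(_iter_site_rows(path))
    if not all_rows:
        raise SeqIOError(f"annotation file {path} is empty")

    first = all_rows[0][1]
    if "position" in first and "protein_id" in first:
        parsed = _parse_tidy(all_rows[1:], first)
    else:
        parsed = _parse_per_protein(all_rows)

    accepted: list[SiteAnnotation] = []
    rejected: list[RejectedRow] = []
    for lineno, content, fields in parsed:
        if fields is None:
            rejected.append(RejectedRow(lineno, content, "unparseable row"))
            continue
        pid = fields["protein_id"]
        protein = by_id.get(pid)
        if protein is None:
            rejected.append(RejectedRow(lineno, content, f"unknown protein {pid!r}"))
            continue
        try:
            pos = int(fields["position"])
        except ValueError:
            rejected.append(RejectedRow(lineno, content, "non-integer position"))
            continue
        if not 1 <= pos <= len(protein):
            rejected.append(
                RejectedRow(lineno, content, f"position {pos} out of range 1..{len(protein)}")
            )
            continue
        residue = fields["residue"].upper()
        if protein.sequence[pos - 1] != residue:
            rejected.append(
                RejectedRow(
                    lineno, content,
                    f"residue mismatch: annotation says {residue!r}, "
                    f"sequence has {protein.sequence[pos - 1]!r} at {pos}",
                )
            )
            continue
        organism = fields.get("organism") or None
        accepted.append(
            SiteAnnotation(pid, pos, residue, fields["ptm_type"], organism)
        )

    if not accepted:
        raise SeqIOError(f"no valid annotation rows survived validation of {path}")
    report = AnnotationReport(accepted=accepted, rejected=rejected)
    if report_path is not None:
        report.write(report_path)
    return report


def write_annotations(annotations: Sequence[SiteAnnotation], path: str | Path) -> None:
    """Write annotations in the canonical tidy TSV dialect."""
    has_org = any(a.organism for a in annotations)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["protein_id", "position", "residue", "ptm_type"]
        if has_org:
            header.append("organism")
        w.writerow(header)
        for a in annotations:
            row = [a.protein_id, a.position, a.residue, a.ptm_type]
            if has_org:
                row.append(a.organism or "")
            w.writerow(row)
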