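"""Peptide-window extraction around PTM sites and candidate residues.

A window is the 2w+1 residue segment centered on a modified (or candidate)
residue, with positions falling off either end of the protein padded with
'X'.  'X' is used as the pad because it stays legal input to every
alignment backend and scores non-positively against everything in the
standard matrices, so padding can never create spurious similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq_io import ProteinRecord, SiteAnnotation

#: Pad character used to complement windows that run off a sequence end.
PAD = "X"

#: Default candidate residue sets per PTM type.
DEFAULT_RESIDUE_SETS: Mapping[str, frozenset[str]] = {
    "phosphorylation": frozenset("STY"),
    "acetylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "methylation": frozenset("KR"),
    "sumoylation": frozenset("K"),
}

#: Default half-width; window length 15 is the dominant convention for
#: sequence-based PTM predictors.  Configurable everywhere it is used.
DEFAULT_HALF_WIDTH = 7


class WindowError(ValueError):
    pass


def residue_set_for(ptm_type: str, override: Iterable[str] | None = None) -> frozenset[str]:
    """Candidate residues for a PTM type; user-defined types need an override."""
    if override is not None:
        rs = frozenset(str(r).upper() for r in override)
        if not rs:
            raise WindowError("residue set must be non-empty")
        return rs
    try:
        return DEFAULT_RESIDUE_SETS[ptm_type]
    except KeyError:
        raise WindowError(
            f"no default residue set for PTM type {ptm_type!r}; supply one explicitly"
        ) from None


@dataclass(frozen=True)
class PeptideWindow:
    """A 2w+1 residue segment centered on position ``center_position``."""

    protein_id: str
    center_position: int  # 1-based in the parent protein
    half_width: int
    sequence: str
    ptm_type: str

    @property
    def window_id(self) -> str:
        return format_window_id(self.protein_id, self.center_position, self.ptm_type)

    @property
    def center_residue(self) -> str:
        return self.sequence[self.half_width]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateSite:
    """A residue of a query protein eligible for a given PTM type."""

    protein_id: str
    position: int  # 1-based
    residue: str
    ptm_type: str


def format_window_id(protein_id: str, position: int, ptm_type: str) -> str:
    return f"{protein_id}|{position}|{ptm_type}"


def parse_window_id(window_id: str) -> tuple[str, int, str]:
    """Invert :func:`format_window_id`.

    Splits from the right so protein accessions containing '|' survive.
    """
    parts = window_id.rsplit("|", 2)
    if len(parts) != 3:
        raise WindowError(f"corrupt window id {window_id!r}")
    protein_id, pos_s, ptm_type = parts
    try:
        position = int(pos_s)
    except ValueError:
        raise WindowError(f"corrupt window id {window_id!r}: bad position") from None
    if not protein_id or position < 1 or not ptm_type:
        raise WindowError(f"corrupt window id {window_id!r}")
    return protein_id, position, ptm_type


def extract_window(
    protein: ProteinRecord, position: int, w: int, ptm_type: str
) -> PeptideWindow:
    """Extract the 2w+1 window centered at a 1-based position.

    Positions before the start or past the end of the sequence are filled
    with the pad character.
    """
    if w < 0:
        raise WindowError(f"half-width w must be >= 0, got {w}")
    if not 1 <= position <= len(protein):
        raise WindowError(
            f"position {position} out of range 1..{len(protein)} "
            f"for protein {protein.id!r}"
        )
    seq = protein.sequence
    i = position - 1
    left = seq[max(0, i - w): i]
    right = seq[i + 1: i + 1 + w]
    window = PAD * (w - len(left)) + left + seq[i] + right + PAD * (w - len(right))
    return PeptideWindow(
        protein_id=protein.id,
        center_position=position,
        half_width=w,
        sequence=window,
        ptm_type=ptm_type,
    )


def enumerate_candidates(
    protein: ProteinRecord,
    ptm_type: str,
    residue_set: Iterable[str] | None = None,
) -> list[CandidateSite]:
    """All positions of ``protein`` carrying a residue eligible for ``ptm_type``,
    in ascending position order."""
    rs = residue_set_for(ptm_type, residue_set)
    return [
        CandidateSite(protein.id, i + 1, ch, ptm_type)
        for i, ch in enumerate(protein.sequence)
        if ch in rs
    ]


def build_known_peptides(
    proteome: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    w: int,
) -> list[PeptideWindow]:
    """One window per unique annotated site, ordered by (protein_id, position).

    Duplicate annotation rows collapse to a single window.
    """
    by_id = {p.id: p for p in proteome}
    seen: set[tuple[str, int, str]] = set()
    windows: list[PeptideWindow] = []
    for ann in sorted(annotations, key=lambda a: (a.protein_id, a.position, a.ptm_type)):
        if ann.key() in seen:
            continue
        seen.add(ann.key())
        try:
            protein = by_id[ann.protein_id]
        except KeyError:
            raise WindowError(
                f"annotation references protein {ann.protein_id!r} "
                "absent from the proteome"
            ) from None
        windows.append(extract_window(protein, ann.position, w, ann.ptm_type))
    return windows


def windows_to_records(windows: Sequence[PeptideWindow]) -> list[ProteinRecord]:
    """Serialize windows as FASTA-able records whose ids are window_ids.

    This is exactly the file handed to an external search backend as the
    known-peptides database.
    """
    return [
        ProteinRecord(id=win.window_id, description="", sequence=win.sequence)
        for win in windows
    ]
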