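"""The three-stage search and the cross-promotion E-value (CPE) verdict.

Stage 1 aligns the candidate peptide window against the known-peptides
database to find the best-matching known peptide (the "hit peptide"; its
parent protein is the "hit protein").  Stages 2 and 3 then ask whether the
query protein and the hit protein are reciprocal best hits at whole-protein
scale: the hit protein searched against the query proteome must find the
query protein as its best match, and the query protein searched against the
known proteome must find the hit protein as its best match.  Only when both
directions agree is the transferred site accepted — a deliberately stringent
criterion that rejects sites whose local peptide similarity is not backed by
whole-protein homology.

Reciprocity is decided by best-hit identity with ties: the partner counts
as best when its E-value equals the smallest E-value in the search (exact
ties count as best).  Ties matter in practice: near-identical full-length
matches underflow to E = 0.0, and a protein present verbatim in both
proteomes must still count as its own best match when an equally strong
homolog sits beside it.  A tolerant equality mode (relative tolerance 1e-9)
is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alignment import (
    AlignmentHit,
    SearchParams,
    SequenceDatabase,
    best_hit,
    get_backend,
    smith_waterman,
)
from .seq_io import ProteinRecord
from .windowing import PeptideWindow, CandidateSite, parse_window_id


class CPEError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideHit:
    """Best-matching known peptide for a candidate site (stage-1 result)."""

    candidate: CandidateSite
    hit_window_id: str
    hit_protein_id: str
    hit_site_position: int
    peptide_evalue: float
    center_aligned: bool
    backend: str = "internal"


@dataclass(frozen=True)
class ReciprocalResult:
    """One direction of the reciprocal check."""

    best_evalue: float
    partner_evalue: float
    best_subject: str | None
    best_raw_score: int
    partner_raw_score: int
    reciprocal: bool


@dataclass(frozen=True)
class CPEEvidence:
    """The four E-values of the reciprocal check plus the verdict inputs.

    ``E_h_best``/``E_h_q``: hit protein vs whole query proteome / vs the
    query protein.  ``E_q_best``/``E_q_h``: query protein vs whole known
    proteome / vs the hit protein.  Missing pairwise hits are +inf.
    """

    E_h_best: float
    E_h_q: float
    E_q_best: float
    E_q_h: float
    best_subject_h: str | None
    best_subject_q: str | None
    reciprocal_h: bool
    reciprocal_q: bool
    backend: str = "internal"


def _direction(
    hits: list[AlignmentHit],
    partner_id: str,
    strict_evalue_equality: bool = False,
) -> ReciprocalResult:
    top = best_hit(hits)
    if top is None:
        return ReciprocalResult(math.inf, math.inf, None, 0, 0, False)
    partner = next((h for h in hits if h.subject_id == partner_id), None)
    if partner is None:
        return ReciprocalResult(top.evalue, math.inf, top.subject_id, top.raw_score, 0, False)
    if strict_evalue_equality:
        reciprocal = partner.evalue <= top.evalue * (1.0 + 1e-9)
    else:
        reciprocal = partner.evalue == top.evalue
    return ReciprocalResult(
        top.evalue, partner.evalue, top.subject_id,
        top.raw_score, partner.raw_score, reciprocal,
    )


def blast1_find_hit(
    candidate_window: PeptideWindow,
    known_peptides: SequenceDatabase,
    params: SearchParams,
    backend="internal",
    strict_center: bool = True,
) -> PeptideHit | None:
    """Stage 1: best-matching known peptide for a candidate window.

    The database search itself runs without an E-value cutoff (default
    protein-search cutoffs silently drop short-peptide hits); the
    configured cutoff is applied to the best hit afterwards.  In strict
    center mode (default) the candidate's central residue must align onto
    the known window's central residue, otherwise the hit is discarded —
    local flank similarity must not transfer a site to the wrong residue.
    """
    bk = get_backend(backend)
    hits = bk.search(candidate_window, known_peptides, params.relaxed(), 0)
    top = best_hit(hits)
    if top is None or top.evalue > params.evalue_cutoff:
        return None
    # among exact ties, a window from the query protein itself wins: when a
    # protein sits verbatim in both proteomes its self-peptide must be the
    # hit, or reciprocity would be judged against an equally similar homolog
    ties = [h for h in hits
            if h.evalue == top.evalue and h.raw_score == top.raw_score]
    for h in ties:
        if parse_window_id(h.subject_id)[0] == candidate_window.protein_id:
            top = h
            break
    protein_id, site_position, _ = parse_window_id(top.subject_id)
    pair_map = top.pair_map
    if not pair_map and top.raw_score > 0:  # traceback was deferred
        pair_map = smith_waterman(
            candidate_window.sequence, known_peptides.get(top.subject_id),
            params.matrix, params.gap_open, params.gap_extend,
            top.query_id, top.subject_id,
        ).pair_map
    w = candidate_window.half_width
    center = (w + 1, w + 1)
    center_aligned = center in pair_map
    if strict_center and not center_aligned:
        return None
    return PeptideHit(
        candidate=CandidateSite(
            candidate_window.protein_id,
            candidate_window.center_position,
            candidate_window.center_residue,
            candidate_window.ptm_type,
        ),
        hit_window_id=top.subject_id,
        hit_protein_id=protein_id,
        hit_site_position=site_position,
        peptide_evalue=top.evalue,
        center_aligned=center_aligned,
        backend=bk.name,
    )


def blast2_reciprocal(
    hit_protein: ProteinRecord,
    query_protein_id: str,
    query_proteome: SequenceDatabase,
    params: SearchParams,
    backend="internal",
    strict_evalue_equality: bool = False,
) -> ReciprocalResult:
    """Stage 2: search the hit protein against the query proteome.

    Returns the best-match E-value, the E-value against the query protein
    specifically (+inf if absent), and whether the query protein *is* the
    best match.  The query protein must be present in the query proteome.
    """
    if query_protein_id not in query_proteome:
        raise CPEError(
            f"query protein {query_protein_id!r} is not in the query proteome "
            "database; queries must be contained in the query proteome"
        )
    hits = get_backend(backend).search(hit_protein, query_proteome, params, 0)
    return _direction(hits, query_protein_id, strict_evalue_equality)


def blast3_reciprocal(
    query_protein: ProteinRecord,
    hit_protein_id: str,
    known_proteome: SequenceDatabase,
    params: SearchParams,
    backend="internal",
    strict_evalue_equality: bool = False,
) -> ReciprocalResult:
    """Stage 3: mirror of stage 2 — query protein vs the known proteome."""
    if hit_protein_id not in known_proteome:
        raise CPEError(
            f"hit protein {hit_protein_id!r} is not in the known proteome database"
        )
    hits = get_backend(backend).search(query_protein, known_proteome, params, 0)
    return _direction(hits, hit_protein_id, strict_evalue_equality)


def make_evidence(
    forward: ReciprocalResult, reverse: ReciprocalResult, backend: str = "internal"
) -> CPEEvidence:
    return CPEEvidence(
        E_h_best=forward.best_evalue,
        E_h_q=forward.partner_evalue,
        E_q_best=reverse.best_evalue,
        E_q_h=reverse.partner_evalue,
        best_subject_h=forward.best_subject,
        best_subject_q=reverse.best_subject,
        reciprocal_h=forward.reciprocal,
        reciprocal_q=reverse.reciprocal,
        backend=backend,
    )


def cpe_verdict(evidence: CPEEvidence) -> bool:
    """True iff both reciprocal conditions hold simultaneously."""
    return evidence.reciprocal_h and evidence.reciprocal_q


def evalue_verdict(peptide_hit: PeptideHit, threshold: float) -> bool:
    """The plain E-value benchmark: accept iff the stage-1 peptide E-value
    is at or below the threshold."""
    if not threshold > 0:
        raise CPEError("threshold must be positive")
    return peptide_hit.peptide_evalue <= threshold
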