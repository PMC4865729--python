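"""Model building, whole-proteome prediction, and evaluation.

A *model* is the bundle of the three search databases the pipeline needs:
the known proteome, its known-peptides database (one 2w+1 window per
annotated site), and the query proteome.  Any of the three can be replaced
to customize a model; rebuilding from identical inputs yields identical
checksums and hence the same model name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from . import seq_io
from .seq_io import ProteinRecord, SiteAnnotation
from .windowing import (
    DEFAULT_HALF_WIDTH,
    PeptideWindow,
    build_known_peptides,
    enumerate_candidates,
    extract_window,
    residue_set_for,
    windows_to_records,
)
from .alignment import SearchParams, SequenceDatabase, get_backend
from .cpe import (
    blast1_find_hit,
    blast2_reciprocal,
    blast3_reciprocal,
    cpe_verdict,
    evalue_verdict,
    make_evidence,
)

log = logging.getLogger("ptmtransfer")


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model bundle

@dataclass
class ModelBundle:
    """The three search databases plus provenance metadata."""

    name: str
    known_proteome: list[ProteinRecord]
    known_peptides: list[PeptideWindow]
    query_proteome: list[ProteinRecord]
    w: int
    ptm_type: str
    residue_set: frozenset[str]
    backend_name: str = "internal"
    manifest: dict = field(default_factory=dict)

    def known_db(self) -> SequenceDatabase:
        return SequenceDatabase.from_records("known_proteome", self.known_proteome)

    def peptides_db(self) -> SequenceDatabase:
        return SequenceDatabase.from_records(
            "known_peptides", windows_to_records(self.known_peptides)
        )

    def query_db(self) -> SequenceDatabase:
        return SequenceDatabase.from_records("query_proteome", self.query_proteome)

    def save(self, models_dir: str | Path) -> Path:
        """Persist as FASTA files plus a JSON manifest under models_dir/name."""
        root = Path(models_dir) / self.name
        root.mkdir(parents=True, exist_ok=True)
        seq_io.write_fasta(self.known_proteome, root / "known_proteome.fasta")
        seq_io.write_fasta(windows_to_records(self.known_peptides), root / "known_peptides.fasta")
        seq_io.write_fasta(self.query_proteome, root / "query_proteome.fasta")
        (root / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return root

    @classmethod
    def load(cls, models_dir: str | Path, name: str) -> "ModelBundle":
        root = Path(models_dir) / name
        if not (root / "manifest.json").exists():
            raise PipelineError(f"no model named {name!r} under {models_dir}")
        manifest = json.loads((root / "manifest.json").read_text())
        known = seq_io.read_fasta(root / "known_proteome.fasta")
        query = seq_io.read_fasta(root / "query_proteome.fasta")
        w = int(manifest["w"])
        windows = []
        from .windowing import parse_window_id

        for rec in seq_io.read_fasta(root / "known_peptides.fasta"):
            pid, pos, ptm = parse_window_id(rec.id)
            windows.append(PeptideWindow(pid, pos, w, rec.sequence, ptm))
        return cls(
            name=name,
            known_proteome=known,
            known_peptides=windows,
            query_proteome=query,
            w=w,
            ptm_type=manifest["ptm_type"],
            residue_set=frozenset(manifest["residue_set"]),
            backend_name=manifest.get("backend", "internal"),
            manifest=manifest,
        )


def _digest(parts: Iterable[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\x00")
    return h.hexdigest()


def assemble_model(
    known: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    query: Sequence[ProteinRecord],
    w: int = DEFAULT_HALF_WIDTH,
    ptm_type: str = "phosphorylation",
    residue_set: Iterable[str] | None = None,
    backend: str = "internal",
) -> ModelBundle:
    """Build a model bundle from in-memory, already validated inputs."""
    rs = residue_set_for(ptm_type, residue_set)
    relevant = [a for a in annotations if a.ptm_type == ptm_type]
    if not relevant:
        raise PipelineError(f"no annotations of PTM type {ptm_type!r}")
    bad = [a for a in relevant if a.residue not in rs]
    if bad:
        raise PipelineError(
            f"{len(bad)} annotations carry residues outside the candidate set "
            f"{sorted(rs)} for {ptm_type!r} (first: {bad[0]})"
        )
    windows = build_known_peptides(known, relevant, w)
    checksums = {
        "known_proteome": _digest(f">{p.id}\n{p.sequence}" for p in known),
        "known_peptides": _digest(f">{x.window_id}\n{x.sequence}" for x in windows),
        "query_proteome": _digest(f">{p.id}\n{p.sequence}" for p in query),
    }
    name = f"{ptm_type}_w{w}_" + _digest(sorted(checksums.values()))[:12]
    manifest = {
        "name": name,
        "w": w,
        "ptm_type": ptm_type,
        "residue_set": sorted(rs),
        "backend": backend,
        "checksums": checksums,
        "n_known_proteins": len(known),
        "n_known_peptides": len(windows),
        "n_query_proteins": len(query),
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return ModelBundle(
        name=name,
        known_proteome=list(known),
        known_peptides=windows,
        query_proteome=list(query),
        w=w,
        ptm_type=ptm_type,
        residue_set=rs,
        backend_name=backend,
        manifest=manifest,
    )


def build_model(
    known_fasta: str | Path,
    annotations_tsv: str | Path,
    query_fasta: str | Path,
    w: int = DEFAULT_HALF_WIDTH,
    ptm_type: str = "phosphorylation",
    residue_set: Iterable[str] | None = None,
    backend: str = "internal",
) -> ModelBundle:
    """File-based entry point: read, validate, and assemble a model."""
    known = seq_io.read_fasta(known_fasta)
    query = seq_io.read_fasta(query_fasta)
    report = seq_io.read_annotations(annotations_tsv, known)
    if report.rejected:
        log.info("annotation validation rejected %d rows", len(report.rejected))
    return assemble_model(known, report.accepted, query, w, ptm_type, residue_set, backend)


def build_m1_m2(
    known: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    test_organism: str,
    w: int = DEFAULT_HALF_WIDTH,
    ptm_type: str = "phosphorylation",
    residue_set: Iterable[str] | None = None,
    backend: str = "internal",
) -> tuple[ModelBundle, ModelBundle, list[SiteAnnotation]]:
    """Organism-holdout model pair.

    M1 excludes every protein and site tagged with ``test_organism`` from
    the known databases; M2 includes everything.  Both share the same query
    proteome: the test organism's proteins.  Returns (M1, M2, truth) where
    truth is the held-out organism's annotation set.
    """
    tagged_ids = {a.protein_id for a in annotations if a.organism == test_organism}
    if not tagged_ids:
        raise PipelineError(f"no annotations tagged with organism {test_organism!r}")
    truth = [a for a in annotations if a.organism == test_organism]
    query = [p for p in known if p.id in tagged_ids]
    known_m1 = [p for p in known if p.id not in tagged_ids]
    ann_m1 = [a for a in annotations if a.organism != test_organism]
    m1 = assemble_model(known_m1, ann_m1, query, w, ptm_type, residue_set, backend)
    m2 = assemble_model(list(known), list(annotations), query, w, ptm_type, residue_set, backend)
    return m1, m2, truth


# ---------------------------------------------------------------------------
# prediction

@dataclass(frozen=True)
class Prediction:
    """One putative PTM site with full reciprocal-search provenance."""

    query_protein_id: str
    position: int
    residue: str
    ptm_type: str
    hit_protein_id: str
    hit_site_position: int
    peptide_evalue: float
    E_h_best: float
    E_h_q: float
    E_q_best: float
    E_q_h: float
    cpe_yes: bool
    evalue_yes: bool

    def key(self) -> tuple[str, int, str]:
        return (self.query_protein_id, self.position, self.ptm_type)


def predict(
    query_ids: Sequence[str],
    model: ModelBundle,
    params: SearchParams | None = None,
    mode: str = "cpe",
    backend=None,
    strict_center: bool = True,
) -> list[Prediction]:
    """Run the full pipeline for the given query proteins.

    For every candidate residue: stage-1 peptide search, then (if a hit
    peptide survives) the two whole-protein reciprocal searches, then both
    verdicts.  ``mode`` selects which rows are emitted: ``cpe`` (default)
    keeps reciprocal-positive sites, ``evalue`` keeps plain-benchmark
    positives, ``both`` keeps every candidate with a stage-1 hit and
    reports both verdicts.  Whole-protein searches are cached per protein,
    so cost scales with distinct proteins, not candidates.
    """
    if mode not in {"cpe", "evalue", "both"}:
        raise PipelineError(f"unknown mode {mode!r}")
    params = params or SearchParams()
    bk = get_backend(backend if backend is not None else model.backend_name)
    query_by_id = {p.id: p for p in model.query_proteome}
    known_by_id = {p.id: p for p in model.known_proteome}
    missing = [q for q in query_ids if q not in query_by_id]
    if missing:
        raise PipelineError(
            f"query protein(s) {missing} not contained in the query proteome "
            "database; every query must exist in the query proteome"
        )
    peptides_db = model.peptides_db()
    known_db = model.known_db()
    query_db = model.query_db()

    blast2_cache: dict[str, object] = {}
    blast3_cache: dict[str, object] = {}
    rows: list[Prediction] = []
    for qid in query_ids:
        protein = query_by_id[qid]
        candidates = enumerate_candidates(protein, model.ptm_type, model.residue_set)
        log.info("query %s: %d candidate residues", qid, len(candidates))
        n_hits = 0
        for cand in candidates:
            if cand.residue not in model.residue_set:  # residue-type guard
                continue
            window = extract_window(protein, cand.position, model.w, model.ptm_type)
            ph = blast1_find_hit(window, peptides_db, params, bk, strict_center)
            if ph is None:
                continue
            n_hits += 1
            hit_protein = known_by_id.get(ph.hit_protein_id)
            if hit_protein is None:
                raise PipelineError(
                    f"hit peptide {ph.hit_window_id!r} does not resolve to a "
                    "known-proteome protein: corrupt model"
                )
            fwd = blast2_cache.get(ph.hit_protein_id)
            if fwd is None:
                fwd = {}
                blast2_cache[ph.hit_protein_id] = fwd
            if qid not in fwd:
                fwd[qid] = blast2_reciprocal(hit_protein, qid, query_db, params, bk)
            forward = fwd[qid]
            rev = blast3_cache.get(qid)
            if rev is None:
                rev = {}
                blast3_cache[qid] = rev
            if ph.hit_protein_id not in rev:
                rev[ph.hit_protein_id] = blast3_reciprocal(
                    protein, ph.hit_protein_id, known_db, params, bk
                )
            reverse = rev[ph.hit_protein_id]
            evidence = make_evidence(forward, reverse, bk.name)
            if ph.backend != evidence.backend:
                raise PipelineError("mixed backends within one CPE evaluation")
            cpe_yes = cpe_verdict(evidence)
            ev_yes = evalue_verdict(ph, params.evalue_cutoff)
            log.debug(
                "site %s:%d E1=%.3g Ehb=%.3g Ehq=%.3g Eqb=%.3g Eqh=%.3g cpe=%s",
                qid, cand.position, ph.peptide_evalue, evidence.E_h_best,
                evidence.E_h_q, evidence.E_q_best, evidence.E_q_h, cpe_yes,
            )
            row = Prediction(
                query_protein_id=qid,
                position=cand.position,
                residue=cand.residue,
                ptm_type=model.ptm_type,
                hit_protein_id=ph.hit_protein_id,
                hit_site_position=ph.hit_site_position,
                peptide_evalue=ph.peptide_evalue,
                E_h_best=evidence.E_h_best,
                E_h_q=evidence.E_h_q,
                E_q_best=evidence.E_q_best,
                E_q_h=evidence.E_q_h,
                cpe_yes=cpe_yes,
                evalue_yes=ev_yes,
            )
            if mode == "cpe" and not cpe_yes:
                continue
            if mode == "evalue" and not ev_yes:
                continue
            rows.append(row)
        log.info("query %s: %d stage-1 hits, %d rows kept", qid, n_hits, len(rows))
    rows.sort(key=lambda r: (r.query_protein_id, r.position, r.ptm_type))
    return rows


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvalReport:
    """Site-level precision/recall of predictions against a truth set.

    A prediction is correct iff its (protein, position, PTM type) triple is
    in the truth set.  Undefined ratios (0 predictions, or empty truth) are
    NaN, never an exception.
    """

    n_predicted: int
    n_correct: int
    n_truth: int

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_predicted if self.n_predicted else math.nan

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_truth if self.n_truth else math.nan

    def summary(self) -> str:
        p = "undefined" if math.isnan(self.precision) else f"{100*self.precision:.1f}%"
        r = "undefined" if math.isnan(self.recall) else f"{100*self.recall:.1f}%"
        return (
            f"predicted={self.n_predicted} correct={self.n_correct} "
            f"truth={self.n_truth} precision={p} recall={r}"
        )


def evaluate(
    predictions: Sequence[Prediction], truth: Sequence[SiteAnnotation]
) -> EvalReport:
    truth_keys = {a.key() for a in truth}
    pred_keys = {p.key() for p in predictions}
    n_correct = len(pred_keys & truth_keys)
    return EvalReport(n_predicted=len(pred_keys), n_correct=n_correct, n_truth=len(truth_keys))


# ---------------------------------------------------------------------------
# output

_TSV_COLUMNS = [
    "query_protein_id", "position", "residue", "ptm_type",
    "hit_protein_id", "hit_site_position", "peptide_evalue",
    "E_h_best", "E_h_q", "E_q_best", "E_q_h", "cpe_verdict", "evalue_verdict",
]


def _fmt_e(v: float) -> str:
    if math.isinf(v):
        return "inf"
    return f"{v:.6g}"


def write_predictions(
    predictions: Sequence[Prediction], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write predictions as TSV (all fields) or GFF3 (modified_amino_acid
    features, 1-based coordinates, provenance in the attributes column)."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for p in predictions:
            lines.append("\t".join([
                p.query_protein_id, str(p.position), p.residue, p.ptm_type,
                p.hit_protein_id, str(p.hit_site_position), _fmt_e(p.peptide_evalue),
                _fmt_e(p.E_h_best), _fmt_e(p.E_h_q), _fmt_e(p.E_q_best), _fmt_e(p.E_q_h),
                "yes" if p.cpe_yes else "no", "yes" if p.evalue_yes else "no",
            ]))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "gff3":
        lines = ["##gff-version 3"]
        for i, p in enumerate(predictions, start=1):
            attrs = ";".join([
                f"ID=ptm{i:06d}",
                f"ptm_type={p.ptm_type}",
                f"residue={p.residue}",
                f"hit_protein={p.hit_protein_id}",
                f"hit_site={p.hit_site_position}",
                f"peptide_evalue={_fmt_e(p.peptide_evalue)}",
                f"cpe_verdict={'yes' if p.cpe_yes else 'no'}",
                f"evalue_verdict={'yes' if p.evalue_yes else 'no'}",
            ])
            lines.append("\t".join([
                p.query_protein_id, "ptmtransfer", "modified_amino_acid",
                str(p.position), str(p.position), _fmt_e(p.peptide_evalue),
                ".", ".", attrs,
            ]))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise PipelineError(f"unknown output format {fmt!r}")


def read_predictions(path: str | Path) -> list[Prediction]:
    """Read back a prediction TSV written by :func:`write_predictions`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _TSV_COLUMNS:
        raise PipelineError(f"{path} is not a prediction TSV")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(Prediction(
            query_protein_id=f[0], position=int(f[1]), residue=f[2], ptm_type=f[3],
            hit_protein_id=f[4], hit_site_position=int(f[5]),
            peptide_evalue=float(f[6]), E_h_best=float(f[7]), E_h_q=float(f[8]),
            E_q_best=float(f[9]), E_q_h=float(f[10]),
            cpe_yes=f[11] == "yes", evalue_yes=f[12] == "yes",
        ))
    return out
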