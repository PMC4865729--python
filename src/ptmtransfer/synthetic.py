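"""Synthetic proteome pairs with planted PTM sites and controlled homology.

Every pipeline stage is testable without downloads: the generator emulates
a known proteome with experimentally annotated sites, a query proteome of
point-mutated homologs (planted site residues preserved, so ground truth
stays well defined), unrelated decoy proteins, and an optional "paralog
trap" — a known protein sharing only a local peptide with a query protein
whose true whole-protein partner is a different (unannotated) paralog, the
situation the reciprocal benchmark exists to reject.

What this emulates, and what it does not: sequences are i.i.d. draws from a
background composition (uniform by default, Robinson–Robinson optionally),
homologs diverge by point substitution only.  Real proteomes have motif
structure around sites, domain architecture, repeats and indels; passing
tests here demonstrate the pipeline's search/verdict logic, not performance
on real data.

Mutations are coupled across divergence levels: one uniform variate is
drawn per position and a position mutates iff its variate falls below the
divergence, so the mutation sets at increasing divergence are nested for a
fixed seed and recovery is structurally non-increasing in divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import seq_io
from .seq_io import ProteinRecord, SiteAnnotation, STANDARD_AA
from .alignment import ROBINSON_FREQUENCIES
from .windowing import DEFAULT_HALF_WIDTH, residue_set_for


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; the defaults are the study conditions used
    throughout the test suite."""

    seed: int = 42
    n_proteins: int = 30
    length_range: tuple[int, int] = (200, 400)
    n_sites_per_protein: tuple[int, int] = (2, 4)
    ptm_type: str = "phosphorylation"
    residue_set: frozenset[str] = frozenset("STY")
    divergence: float = 0.05
    n_decoys: int = 0
    paralog_trap: bool = False
    w: int = DEFAULT_HALF_WIDTH
    background: str = "uniform"  # or "robinson"

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise SyntheticError("divergence must be in [0, 1)")
        if self.n_proteins < 1:
            raise SyntheticError("n_proteins must be >= 1")
        if not self.residue_set:
            raise SyntheticError("residue_set must be non-empty")
        if self.background not in {"uniform", "robinson"}:
            raise SyntheticError(f"unknown background {self.background!r}")


_AA = np.array(list(STANDARD_AA))


def _background_probs(config: SynthConfig) -> np.ndarray:
    if config.background == "uniform":
        return np.full(20, 1.0 / 20)
    total = sum(ROBINSON_FREQUENCIES.values())
    return np.array([ROBINSON_FREQUENCIES[a] / total for a in STANDARD_AA])


def _random_sequence(rng: np.random.Generator, length: int, p: np.ndarray) -> str:
    return "".join(rng.choice(_AA, size=length, p=p))


def make_known_proteome(
    config: SynthConfig,
    organism: str | None = None,
    id_prefix: str = "K",
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Random proteome with planted PTM sites (plus unannotated decoys)."""
    rng = np.random.default_rng(config.seed)
    p = _background_probs(config)
    lo, hi = config.length_range
    slo, shi = config.n_sites_per_protein
    residues = sorted(config.residue_set)
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    for i in range(config.n_proteins):
        pid = f"{id_prefix}{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_sequence(rng, length, p))
        n_sites = int(rng.integers(slo, shi + 1))
        # keep sites clear of the termini so their windows are pad-free
        interior = np.arange(config.w, length - config.w)
        positions = sorted(rng.choice(interior, size=n_sites, replace=False) + 1)
        for pos in positions:
            res = residues[int(rng.integers(len(residues)))]
            seq[pos - 1] = res
            annotations.append(
                SiteAnnotation(pid, int(pos), res, config.ptm_type, organism)
            )
        proteins.append(ProteinRecord(pid, f"synthetic {organism or 'known'}", "".join(seq)))
    for i in range(config.n_decoys):
        length = int(rng.integers(lo, hi + 1))
        proteins.append(
            ProteinRecord(f"{id_prefix}D{i + 1:03d}", "synthetic decoy",
                          _random_sequence(rng, length, p))
        )
    return proteins, annotations


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    protected: set[int],
    divergence: float,
) -> str:
    """Point-mutate a sequence; positions in ``protected`` (1-based) never
    change.  Random draws do not depend on ``divergence``, so mutation sets
    are nested across divergence levels at a fixed generator state."""
    u = rng.random(len(sequence))
    repl = rng.integers(0, 19, size=len(sequence))
    out = list(sequence)
    for i, ch in enumerate(sequence):
        if u[i] >= divergence or (i + 1) in protected:
            continue
        others = [a for a in STANDARD_AA if a != ch]
        out[i] = others[int(repl[i])] if ch in STANDARD_AA else STANDARD_AA[int(repl[i])]
    return "".join(out)


def derive_query_proteome(
    known: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    config: SynthConfig,
    rename_prefix: str | None = None,
    organism: str | None = None,
) -> tuple[list[ProteinRecord], list[SiteAnnotation], list[ProteinRecord]]:
    """Query homologs of the known proteome, plus ground truth.

    Each query protein is a point-mutated copy of a known protein with
    planted site residues preserved; query decoys carry no true sites.
    Returns ``(query_proteins, true_sites, extra_known)``; ``extra_known``
    is non-empty only with ``paralog_trap`` and holds the unannotated
    paralog that must be appended to the *known* proteome to arm the trap.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    p = _background_probs(config)
    sites_by_protein: dict[str, list[SiteAnnotation]] = {}
    for a in annotations:
        sites_by_protein.setdefault(a.protein_id, []).append(a)

    queries: list[ProteinRecord] = []
    truth: list[SiteAnnotation] = []
    extra_known: list[ProteinRecord] = []
    for i, protein in enumerate(known):
        anns = sites_by_protein.get(protein.id, [])
        protected = {a.position for a in anns}
        mutated = _mutate(rng, protein.sequence, protected, config.divergence)
        qid = f"{rename_prefix}{i + 1:04d}" if rename_prefix else protein.id
        queries.append(ProteinRecord(qid, f"homolog of {protein.id}", mutated))
        for a in anns:
            truth.append(
                SiteAnnotation(qid, a.position, a.residue, a.ptm_type, organism)
            )
    for i in range(config.n_decoys):
        length = int(rng.integers(*config.length_range) + 0)
        queries.append(
            ProteinRecord(f"QD{i + 1:03d}", "synthetic query decoy",
                          _random_sequence(rng, length, p))
        )
    if config.paralog_trap:
        trap_q, trap_p = _build_trap(rng, known, annotations, config, p)
        queries.append(trap_q)
        extra_known.append(trap_p)
    return queries, truth, extra_known


def _build_trap(
    rng: np.random.Generator,
    known: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    config: SynthConfig,
    p: np.ndarray,
) -> tuple[ProteinRecord, ProteinRecord]:
    """Build (trap query, unannotated known paralog).

    The trap query embeds one annotated window verbatim, so its stage-1
    best hit is that known peptide; the paralog is identical to the trap
    query everywhere *except* the window, so the trap query's whole-protein
    best match in the known proteome is the paralog, not the hit protein —
    reciprocity fails while the plain E-value benchmark accepts."""
    w = config.w
    by_id = {pr.id: pr for pr in known}
    site = next(
        (a for a in annotations
         if w < a.position <= len(by_id[a.protein_id]) - w),
        None,
    )
    if site is None:
        raise SyntheticError("no interior site available to build a paralog trap")
    host = by_id[site.protein_id]
    window = host.sequence[site.position - 1 - w: site.position + w]
    length = int(np.mean(config.length_range))
    backbone = _random_sequence(rng, length, p)
    center = length // 2
    start = center - w - 1  # 0-based start so the site sits at `center`
    trap_seq = backbone[:start] + window + backbone[start + 2 * w + 1:]
    trap_q = ProteinRecord("TRAPQ01", f"trap query sharing window of {host.id}", trap_seq)
    scrambled = _random_sequence(rng, 2 * w + 1, p)
    paralog_seq = trap_seq[:start] + scrambled + trap_seq[start + 2 * w + 1:]
    trap_p = ProteinRecord("TRAPP01", "unannotated paralog of TRAPQ01", paralog_seq)
    return trap_q, trap_p


# ---------------------------------------------------------------------------
# named scenarios

@dataclass
class Scenario:
    """A complete fixture bundle for one named study condition."""

    name: str
    config: SynthConfig
    known: list[ProteinRecord]
    annotations: list[SiteAnnotation]
    query: list[ProteinRecord]
    truth: list[SiteAnnotation]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the four fixture files; byte-stable for a fixed seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "known": out / "known.fasta",
            "annotations": out / "annotations.tsv",
            "query": out / "query.fasta",
            "truth": out / "truth.tsv",
        }
        seq_io.write_fasta(self.known, paths["known"])
        seq_io.write_annotations(self.annotations, paths["annotations"])
        seq_io.write_fasta(self.query, paths["query"])
        seq_io.write_annotations(self.truth, paths["truth"])
        return paths


SCENARIO_NAMES = ("self_inclusion", "holdout", "paralog_trap", "empty")


def scenario(name: str, seed: int = 42, **overrides) -> Scenario:
    """Build a named scenario.

    ``self_inclusion`` — query proteome identical to the known proteome
    (every test protein and site verbatim in the model databases).
    ``holdout`` — a base organism plus a diverged test organism, annotations
    carrying organism tags for M1/M2 model construction.
    ``paralog_trap`` — homolog queries plus one armed trap.
    ``empty`` — query proteins with no candidate residues at all.
    """
    if name == "self_inclusion":
        config = replace(
            SynthConfig(seed=seed, n_proteins=30, length_range=(200, 400),
                        n_sites_per_protein=(2, 4), divergence=0.0, n_decoys=0),
            **overrides,
        )
        known, annotations = make_known_proteome(config)
        return Scenario(name, config, known, annotations, list(known), list(annotations))

    if name == "holdout":
        config = replace(
            SynthConfig(seed=seed, n_proteins=12, length_range=(150, 250),
                        n_sites_per_protein=(2, 3), divergence=0.05, n_decoys=0),
            **overrides,
        )
        base, base_ann = make_known_proteome(config, organism="modelorg")
        test, test_ann, _ = derive_query_proteome(
            base, base_ann, config, rename_prefix="T", organism="testorg"
        )
        known = base + test
        annotations = base_ann + test_ann
        return Scenario(name, config, known, annotations, list(test), list(test_ann))

    if name == "paralog_trap":
        config = replace(
            SynthConfig(seed=seed, n_proteins=10, length_range=(150, 250),
                        n_sites_per_protein=(2, 3), divergence=0.02, n_decoys=2,
                        paralog_trap=True),
            **overrides,
        )
        known, annotations = make_known_proteome(config)
        query, truth, extra = derive_query_proteome(known, annotations, config)
        return Scenario(name, config, known + extra, annotations, query, truth)

    if name == "empty":
        config = replace(
            SynthConfig(seed=seed, n_proteins=5, length_range=(100, 160),
                        n_sites_per_protein=(1, 2), divergence=0.0, n_decoys=0),
            **overrides,
        )
        known, annotations = make_known_proteome(config)
        rng = np.random.default_rng(config.seed + 7)
        rs = residue_set_for(config.ptm_type, config.residue_set)
        letters = np.array([a for a in STANDARD_AA if a not in rs])
        query = [
            ProteinRecord(
                f"E{i + 1:03d}", "no candidate residues",
                "".join(rng.choice(letters, size=int(rng.integers(80, 120)))),
            )
            for i in range(3)
        ]
        return Scenario(name, config, known, annotations, query, [])

    raise SyntheticError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
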