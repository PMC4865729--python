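"""Local-alignment search with Karlin–Altschul E-value statistics.

Two interchangeable backends implement one search contract:

* ``internal`` — exact Smith–Waterman (affine gaps, Gotoh) scored and
  traced by :class:`Bio.Align.PairwiseAligner`, with E-values computed
  from the ungapped Karlin–Altschul parameters (λ, K) of the scoring
  matrix:  E = K·m·n·exp(−λS).  Applying ungapped statistics to gapped
  scores makes the absolute E-value scale approximate, but every use in
  this package depends only on E-value *order* within one database, which
  the monotone map from score to E preserves exactly.
* ``blastp`` — an adapter around NCBI blastp/makeblastdb (tabular output),
  for users who want genuine BLAST heuristics and statistics.

E-values from the two backends are never comparable; hits carry a backend
tag so downstream reciprocal checks can refuse to mix them.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seq_io import ProteinRecord, STANDARD_AA


class AlignmentError(ValueError):
    pass


class BackendError(RuntimeError):
    """External search backend failed; carries the backend diagnostic."""


# Robinson & Robinson (1991) amino-acid background frequencies, the
# standard background used for protein-alignment statistics.
ROBINSON_FREQUENCIES: dict[str, float] = {
    "A": 78.05, "R": 51.29, "N": 44.87, "D": 53.64, "C": 19.25,
    "Q": 42.64, "E": 62.95, "G": 73.77, "H": 21.99, "I": 51.42,
    "L": 90.19, "K": 57.44, "M": 22.43, "F": 38.56, "P": 52.03,
    "S": 71.20, "T": 58.41, "W": 13.30, "Y": 32.16, "V": 64.41,
}


def _normalized(freqs: dict[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    if total <= 0:
        raise AlignmentError("background frequencies must have positive mass")
    return {k: v / total for k, v in freqs.items()}


@dataclass
class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix plus background frequencies.

    ``background`` covers the residue letters whose random-pairing statistics
    define λ and K; the matrix itself may score extra letters (e.g. 'X').
    """

    name: str
    array: substitution_matrices.Array
    background: dict[str, float]
    _lambda: float | None = field(default=None, repr=False, compare=False)
    _k: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.background = _normalized(dict(self.background))
        letters = sorted(self.background)
        for a in letters:
            for b in letters:
                if self.array[a][b] != self.array[b][a]:
                    raise AlignmentError(f"matrix {self.name} not symmetric at {a},{b}")
        scores = self._score_grid()
        if not (scores > 0).any():
            raise AlignmentError(f"matrix {self.name} has no positive score")
        if self.expected_score() >= 0:
            raise AlignmentError(
                f"matrix {self.name} has non-negative expected score; "
                "Karlin-Altschul statistics are undefined"
            )
        if "X" in self.array.alphabet:
            xcol = [self.array["X"][a] for a in self.array.alphabet if a != "*"]
            if max(xcol) > 0:
                raise AlignmentError(
                    f"matrix {self.name}: 'X' must score non-positively "
                    "so window padding cannot create similarity"
                )

    # -- statistics ------------------------------------------------------

    def _score_grid(self) -> np.ndarray:
        letters = sorted(self.background)
        return np.array(
            [[float(self.array[a][b]) for b in letters] for a in letters]
        )

    def _prob_vector(self) -> np.ndarray:
        letters = sorted(self.background)
        return np.array([self.background[a] for a in letters])

    def expected_score(self) -> float:
        p = self._prob_vector()
        return float(p @ self._score_grid() @ p)

    def score(self, a: str, b: str) -> int:
        return int(self.array[a][b])

    @property
    def karlin_lambda(self) -> float:
        if self._lambda is None:
            self._lambda = karlin_lambda(self._score_grid(), self._prob_vector())
        return self._lambda

    @property
    def karlin_k(self) -> float:
        if self._k is None:
            self._k = karlin_k(
                self._score_grid(), self._prob_vector(), self.karlin_lambda
            )
        return self._k

    # -- constructors ----------------------------------------------------

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls(
            name="BLOSUM62",
            array=substitution_matrices.load("BLOSUM62"),
            background=dict(ROBINSON_FREQUENCIES),
        )

    @classmethod
    def load(cls, name: str) -> "SubstitutionMatrix":
        """Load any matrix shipped with Biopython (BLOSUM*, PAM*) with the
        standard protein background."""
        return cls(
            name=name.upper(),
            array=substitution_matrices.load(name.upper()),
            background=dict(ROBINSON_FREQUENCIES),
        )

    @classmethod
    def from_match_mismatch(
        cls,
        match: int,
        mismatch: int,
        alphabet: str = STANDARD_AA,
        background: dict[str, float] | None = None,
    ) -> "SubstitutionMatrix":
        """Simple +match/−mismatch matrix over an arbitrary alphabet
        (uniform background by default)."""
        n = len(alphabet)
        arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                arr[a][b] = match if a == b else mismatch
        bg = background or {a: 1.0 / n for a in alphabet}
        return cls(name=f"match{match}mismatch{mismatch}", array=arr, background=bg)


def karlin_lambda(scores: np.ndarray, probs: np.ndarray) -> float:
    """Unique positive root λ of Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1.

    Requires a negative expected score and at least one positive score;
    solved by bracketed root-finding to relative tolerance 1e-9.
    """
    pij = np.outer(probs, probs)
    if float((pij * scores).sum()) >= 0:
        raise AlignmentError("expected score must be negative for λ to exist")
    if not (scores > 0).any():
        raise AlignmentError("no positive score; λ undefined")

    def f(lam: float) -> float:
        return float((pij * np.exp(lam * scores)).sum() - 1.0)

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise AlignmentError("failed to bracket λ")
    return float(brentq(f, 1e-12, hi, xtol=1e-15, rtol=1e-12))


def karlin_k(
    scores: np.ndarray,
    probs: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_terms: int = 5000,
) -> float:
    """Karlin–Altschul K for an integer lattice score distribution.

    Uses the series formula K = δ·λ·e^{−2σ} / (H·(1 − e^{−λδ})) with
    σ = Σ_k (1/k)·[E(e^{λS_k}; S_k<0) + P(S_k ≥ 0)], where S_k is a sum of
    k i.i.d. pair scores and δ the score lattice spacing; the series is
    truncated once a term falls below ``tol``.
    """
    iscores = np.rint(scores).astype(int)
    if not np.allclose(scores, iscores):
        raise AlignmentError("K computation requires integer scores")
    smin, smax = int(iscores.min()), int(iscores.max())
    dist = np.zeros(smax - smin + 1)
    pij = np.outer(probs, probs)
    for (i, j), p in np.ndenumerate(pij):
        dist[iscores[i, j] - smin] += p
    support = np.arange(smin, smax + 1)
    delta = 0
    for s, p in zip(support, dist):
        if p > 0 and s != 0:
            delta = math.gcd(delta, abs(int(s)))
    if delta == 0:
        raise AlignmentError("degenerate score distribution")
    # relative-entropy rate H (nats per aligned pair)
    H = lam * float((support * dist * np.exp(lam * support)).sum())
    sigma = 0.0
    conv = dist.copy()
    lo = smin
    for k in range(1, max_terms + 1):
        sc = np.arange(lo, lo + len(conv))
        neg = sc < 0
        term = float((conv[neg] * np.exp(lam * sc[neg])).sum() + conv[~neg].sum())
        sigma += term / k
        if term / k < tol and k > 10:
            break
        conv = np.convolve(conv, dist)
        lo += smin
    return delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))


def evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> float:
    """Expected chance hits scoring ≥ raw_score: E = K·m·n·exp(−λS)."""
    if m < 1 or n < 1:
        raise AlignmentError("m and n must be >= 1")
    if lam <= 0 or K <= 0:
        raise AlignmentError("lambda and K must be positive")
    return K * m * n * math.exp(-lam * raw_score)


@dataclass
class SearchParams:
    """Tunable parameters of a similarity search."""

    matrix: SubstitutionMatrix = field(default_factory=SubstitutionMatrix.blosum62)
    gap_open: int = 11
    gap_extend: int = 1
    evalue_cutoff: float = 10.0
    max_target_seqs: int = 500

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise AlignmentError("gap_extend must not exceed gap_open")
        if not self.evalue_cutoff > 0:
            raise AlignmentError("evalue_cutoff must be positive")
        if self.max_target_seqs < 1:
            raise AlignmentError("max_target_seqs must be >= 1")

    def relaxed(self) -> "SearchParams":
        """Copy with the E-value cutoff effectively removed (short-peptide
        stage; the cutoff is applied downstream)."""
        return replace(self, evalue_cutoff=math.inf)


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment result (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]
    pair_map: tuple[tuple[int, int], ...]
    backend: str = "internal"


# ---------------------------------------------------------------------------
# internal Smith-Waterman backend

_aligner_cache: dict[tuple[str, int, int], Align.PairwiseAligner] = {}


def _aligner_for(matrix: SubstitutionMatrix, gap_open: int, gap_extend: int):
    key = (matrix.name, gap_open, gap_extend)
    al = _aligner_cache.get(key)
    if al is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = matrix.array
        # a gap of length L costs gap_open + L*gap_extend
        al.open_gap_score = -(gap_open + gap_extend)
        al.extend_gap_score = -gap_extend
        _aligner_cache[key] = al
    return al


def _pair_map_from_blocks(aligned) -> tuple[tuple[int, int], ...]:
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ss, se) in zip(*aligned):
        pairs.extend((q + 1, s + 1) for q, s in zip(range(qs, qe), range(ss, se)))
    return tuple(pairs)


def smith_waterman(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal local alignment of two sequences under affine gap costs.

    The returned hit carries a NaN E-value; E-values are assigned by
    :func:`search`, which knows the database context.  A pair with no
    positive-scoring alignment yields the empty alignment with score 0.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    aligner = _aligner_for(matrix, gap_open, gap_extend)
    score = int(round(aligner.score(a, b)))
    if score <= 0:
        return AlignmentHit(
            query_id, subject_id, 0, math.nan, math.nan, (0, 0), (0, 0), (), "internal"
        )
    aln = aligner.align(a, b)[0]  # deterministic first traceback
    pm = _pair_map_from_blocks(aln.aligned)
    qlo, qhi = pm[0][0], pm[-1][0]
    slo, shi = pm[0][1], pm[-1][1]
    return AlignmentHit(
        query_id, subject_id, score, math.nan, math.nan,
        (qlo, qhi), (slo, shi), pm, "internal",
    )


# ---------------------------------------------------------------------------
# batched short-sequence scorer
#
# For peptide-window searches the per-call overhead of the pairwise aligner
# dominates, so equal-length subjects are scored in one vectorized Gotoh
# sweep.  Scores are identical to smith_waterman(); tests assert this.

_NEG = np.int32(-(2 ** 20))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _ord_score_table(matrix: SubstitutionMatrix) -> np.ndarray:
    table = getattr(matrix, "_ord_table", None)
    if table is None:
        table = np.full((128, 128), _NEG, dtype=np.int32)
        letters = [c for c in matrix.array.alphabet if c != "*"]
        for a in letters:
            for b in letters:
                table[ord(a), ord(b)] = int(matrix.array[a][b])
        matrix._ord_table = table
    return table


def batch_local_scores(
    query: str,
    subjects: np.ndarray,
    matrix: SubstitutionMatrix,
    gap_open: int,
    gap_extend: int,
) -> np.ndarray:
    """Smith–Waterman (affine) scores of one query against a (N, L) array of
    encoded equal-length subjects; one DP sweep vectorized over N."""
    q = _encode(query)
    table = _ord_score_table(matrix)
    n, lb = subjects.shape
    goge = np.int32(gap_open + gap_extend)
    ge = np.int32(gap_extend)
    h_prev = np.zeros((n, lb + 1), dtype=np.int32)
    f_prev = np.full((n, lb + 1), _NEG, dtype=np.int32)
    best = np.zeros(n, dtype=np.int32)
    for i in range(1, len(q) + 1):
        srow = table[q[i - 1], subjects]  # (n, lb)
        f_cur = np.maximum(h_prev - goge, f_prev - ge)
        h_cur = np.zeros((n, lb + 1), dtype=np.int32)
        e = np.full(n, _NEG, dtype=np.int32)
        for j in range(1, lb + 1):
            e = np.maximum(h_cur[:, j - 1] - goge, e - ge)
            diag = h_prev[:, j - 1] + srow[:, j - 1]
            h = np.maximum(np.maximum(diag, 0), np.maximum(e, f_cur[:, j]))
            h_cur[:, j] = h
            np.maximum(best, h, out=best)
        h_prev, f_prev = h_cur, f_cur
    return best


# ---------------------------------------------------------------------------
# databases and search

@dataclass
class SequenceDatabase:
    """A named, ordered collection of sequences searched as one unit.

    The Karlin–Altschul E-value of a hit uses the *summed* residue count of
    every database sequence as the database length n.
    """

    name: str
    entries: list[tuple[str, str]]  # (id, sequence)

    def __post_init__(self) -> None:
        if not self.entries:
            raise AlignmentError(f"database {self.name!r} is empty")
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise AlignmentError(f"database {self.name!r} has duplicate ids")

    @classmethod
    def from_records(cls, name: str, records: Sequence[ProteinRecord]) -> "SequenceDatabase":
        return cls(name=name, entries=[(r.id, r.sequence) for r in records])

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return any(i == seq_id for i, _ in self.entries)

    def get(self, seq_id: str) -> str:
        for i, s in self.entries:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def grouped_by_length(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(entry indices, encoded (N, L) array) per distinct sequence length;
        cached on the instance."""
        cached = getattr(self, "_by_length", None)
        if cached is None:
            groups: dict[int, list[int]] = {}
            for idx, (_, seq) in enumerate(self.entries):
                groups.setdefault(len(seq), []).append(idx)
            cached = [
                (
                    np.array(idxs, dtype=np.intp),
                    np.stack([_encode(self.entries[i][1]) for i in idxs]),
                )
                for _, idxs in sorted(groups.items())
            ]
            self._by_length = cached
        return cached


def _query_id_and_seq(query) -> tuple[str, str]:
    if isinstance(query, str):
        return "query", query
    if hasattr(query, "window_id"):
        return query.window_id, query.sequence
    return query.id, query.sequence


def _sort_and_truncate(hits: list[AlignmentHit], max_target_seqs: int) -> list[AlignmentHit]:
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits[:max_target_seqs]


class InternalBackend:
    """Exhaustive Smith–Waterman over every database sequence.

    Short queries against short subjects take the vectorized batch-scoring
    path; long sequences go through the pairwise aligner directly.  Both
    produce identical scores.
    """

    name = "internal"
    _BATCH_MAX_LEN = 64

    def _scores(self, qseq: str, database: SequenceDatabase, params: SearchParams) -> list[int]:
        n_entries = len(database.entries)
        scores = [0] * n_entries
        batchable = len(qseq) <= self._BATCH_MAX_LEN
        aligner = None
        for idxs, encoded in database.grouped_by_length():
            if batchable and encoded.shape[1] <= self._BATCH_MAX_LEN:
                group_scores = batch_local_scores(
                    qseq, encoded, params.matrix, params.gap_open, params.gap_extend
                )
                for idx, s in zip(idxs, group_scores):
                    scores[idx] = int(s)
            else:
                if aligner is None:
                    aligner = _aligner_for(params.matrix, params.gap_open, params.gap_extend)
                for idx in idxs:
                    scores[idx] = int(round(aligner.score(qseq, database.entries[idx][1])))
        return scores

    def search(
        self,
        query,
        database: SequenceDatabase,
        params: SearchParams,
        n_traceback: int | None = None,
    ) -> list[AlignmentHit]:
        qid, qseq = _query_id_and_seq(query)
        if not qseq:
            raise AlignmentError("empty query sequence")
        lam = params.matrix.karlin_lambda
        K = params.matrix.karlin_k
        m, n = len(qseq), database.total_length
        ln2 = math.log(2.0)
        hits: list[AlignmentHit] = []
        for (sid, _), s in zip(database.entries, self._scores(qseq, database, params)):
            if s <= 0:
                continue  # no positive-scoring local alignment: not a hit
            e = evalue(s, m, n, lam, K)
            if e > params.evalue_cutoff:
                continue
            hits.append(
                AlignmentHit(
                    qid, sid, s, (lam * s - math.log(K)) / ln2, e,
                    (0, 0), (0, 0), (), self.name,
                )
            )
        hits = _sort_and_truncate(hits, params.max_target_seqs)
        # traceback for the top n_traceback surviving hits (all by default)
        limit = len(hits) if n_traceback is None else min(n_traceback, len(hits))
        out: list[AlignmentHit] = []
        for rank, h in enumerate(hits):
            if rank >= limit:
                out.append(h)
                continue
            aln = smith_waterman(
                qseq, database.get(h.subject_id), params.matrix,
                params.gap_open, params.gap_extend, qid, h.subject_id,
            )
            out.append(
                replace(
                    h,
                    query_range=aln.query_range,
                    subject_range=aln.subject_range,
                    pair_map=aln.pair_map,
                )
            )
        return out


class BlastpBackend:
    """Adapter to NCBI blastp/makeblastdb with the same search contract.

    Sequence ids are remapped to safe local accessions before database
    construction (pipe characters in window ids collide with NCBI seqid
    syntax) and restored on parse.  Short queries (< 30 residues) run with
    ``-task blastp-short`` and composition-based statistics disabled, since
    default settings silently drop 15-mer hits.
    """

    name = "blastp"

    def __init__(self, workdir: str | Path | None = None) -> None:
        self._workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="ptmxfer_blast_"))
        self._workdir.mkdir(parents=True, exist_ok=True)
        self._db_cache: dict[int, tuple[Path, dict[str, str]]] = {}
        for tool in ("blastp", "makeblastdb"):
            if shutil.which(tool) is None:
                raise BackendError(f"external backend requires {tool!r} on PATH")

    def _ensure_db(self, database: SequenceDatabase) -> tuple[Path, dict[str, str]]:
        cached = self._db_cache.get(id(database))
        if cached is not None:
            return cached
        dbdir = self._workdir / f"db{len(self._db_cache):04d}"
        dbdir.mkdir(exist_ok=True)
        fasta = dbdir / "db.fasta"
        alias: dict[str, str] = {}
        with open(fasta, "w") as fh:
            for i, (sid, seq) in enumerate(database.entries):
                safe = f"s{i:06d}"
                alias[safe] = sid
                fh.write(f">{safe}\n{seq}\n")
        proc = subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot"],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise BackendError(f"makeblastdb failed: {proc.stderr.strip()}")
        self._db_cache[id(database)] = (fasta, alias)
        return fasta, alias

    def search(
        self,
        query,
        database: SequenceDatabase,
        params: SearchParams,
        n_traceback: int | None = None,  # blastp reports alignments regardless
    ) -> list[AlignmentHit]:
        qid, qseq = _query_id_and_seq(query)
        dbpath, alias = self._ensure_db(database)
        qfile = self._workdir / "query.fasta"
        qfile.write_text(f">q\n{qseq}\n")
        cutoff = params.evalue_cutoff
        cmd = [
            "blastp", "-query", str(qfile), "-db", str(dbpath),
            "-outfmt", "6 sseqid score bitscore evalue qstart qend sstart send qseq sseq",
            "-evalue", str(1e9 if math.isinf(cutoff) else cutoff),
            "-max_target_seqs", str(params.max_target_seqs),
            "-matrix", params.matrix.name,
            "-gapopen", str(params.gap_open), "-gapextend", str(params.gap_extend),
            "-num_threads", "1",
        ]
        if len(qseq) < 30:
            cmd += ["-task", "blastp-short", "-comp_based_stats", "0", "-seg", "no"]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(f"blastp failed: {proc.stderr.strip()}")
        best: dict[str, AlignmentHit] = {}
        for line in proc.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                continue
            sid = alias.get(f[0], f[0])
            raw = int(round(float(f[1])))
            hit = AlignmentHit(
                qid, sid, raw, float(f[2]), float(f[3]),
                (int(f[4]), int(f[5])), (int(f[6]), int(f[7])),
                _pair_map_from_strings(int(f[4]), int(f[6]), f[8], f[9]),
                self.name,
            )
            prev = best.get(sid)
            if prev is None or (hit.evalue, -hit.raw_score) < (prev.evalue, -prev.raw_score):
                best[sid] = hit
        hits = [h for h in best.values() if h.evalue <= params.evalue_cutoff]
        return _sort_and_truncate(hits, params.max_target_seqs)


def _pair_map_from_strings(
    qstart: int, sstart: int, qaln: str, saln: str
) -> tuple[tuple[int, int], ...]:
    pairs: list[tuple[int, int]] = []
    q, s = qstart, sstart
    for qc, sc in zip(qaln, saln):
        if qc != "-" and sc != "-":
            pairs.append((q, s))
        if qc != "-":
            q += 1
        if sc != "-":
            s += 1
    return tuple(pairs)


_BACKENDS = {"internal": InternalBackend, "blastp": BlastpBackend}


def get_backend(name_or_backend):
    """Resolve a backend name (or pass an instantiated backend through)."""
    if isinstance(name_or_backend, str):
        try:
            return _BACKENDS[name_or_backend]()
        except KeyError:
            raise AlignmentError(f"unknown backend {name_or_backend!r}") from None
    return name_or_backend


def search(
    query,
    database: SequenceDatabase,
    params: SearchParams,
    backend="internal",
    n_traceback: int | None = None,
) -> list[AlignmentHit]:
    """Search one query against a database; hits with E ≤ cutoff, sorted by
    (evalue, −raw_score, subject_id) and truncated to ``max_target_seqs``."""
    return get_backend(backend).search(query, database, params, n_traceback)


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """First element of a contract-sorted hit list (smallest E-value), or None."""
    return hits[0] if hits else None
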