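# Methods

## The transfer model

`ptmtransfer` treats PTM-site annotation of an unannotated proteome as a
homology-transfer problem.  Its unit of evidence is a peptide window of
length 2w+1 centered on a modified residue; its acceptance criterion is a
reciprocal best-hit test at whole-protein scale.  The underlying
assumptions are:

* a modified site's local sequence context (the window) is conserved well
  enough between homologs for local alignment to find it;
* local context alone is insufficient evidence — similar short peptides
  occur in unrelated proteins — so a transferred site is trusted only when
  the query protein and the protein contributing the known site are each
  other's best whole-protein match in the opposing proteome (the
  cross-promotion E-value, CPE, criterion);
* the query protein must itself be a member of the query proteome
  database, because the reciprocal test searches that database.

A candidate site passes the plain E-value benchmark when its stage-1
peptide E-value is at or below the configured cutoff, and passes CPE when
additionally both reciprocal conditions hold.  Because every CPE-positive
site already survived the stage-1 cutoff, CPE positives are a subset of
E-value positives on any input: the reciprocal benchmark trades
sensitivity for specificity.

## Search stages

1. **Peptide search.** The candidate window is aligned against every
   known-peptide window.  This stage runs with the E-value cutoff removed
   and applies it only to the best hit afterwards, because cutoffs tuned
   for full-length proteins silently discard legitimate 15-mer hits.  In
   strict-center mode (default, on) the candidate's central residue must
   be aligned onto the known window's central residue; otherwise flank
   similarity could transfer a site onto the wrong residue of a similar
   peptide.  A residue-type guard independently ensures the candidate
   residue belongs to the PTM type's residue set.
2. **Hit protein vs query proteome** and
3. **query protein vs known proteome**, both full database searches whose
   best-match and partner-specific E-values feed the verdict.

Whole-protein search results are cached per protein within a prediction
run, so the cost of stages 2–3 scales with the number of distinct
proteins rather than the number of candidate sites.

## Reciprocity and ties

Reciprocity is decided by best-hit *identity allowing exact ties*: the
partner counts as best iff its E-value equals the smallest E-value of the
search.  Two tie situations are real, not hypothetical:

* near-identical full-length matches underflow to E = 0.0 in double
  precision, and a protein present verbatim in both proteomes must still
  count as its own best match when an equally strong homolog sits beside
  it;
* in stage 1, a protein present verbatim in both proteomes can carry a
  window identical to a homolog's window.  Among stage-1 hits tied on
  exact (E-value, raw score), the window whose parent protein *is* the
  query protein is preferred; otherwise the tie would resolve
  lexicographically to the homolog and reciprocity would then be judged
  against the wrong protein, rejecting every self-site.  Self-hits are
  deliberately never excluded — the self-inclusive (M2) evaluation model
  depends on them.

A tolerant-equality mode (relative tolerance 1e-9 on the E-value ratio) is
available behind a flag for experiments with backends that round E-values.

## Alignment engine and statistics

The internal backend computes exact Smith–Waterman local alignments under
affine gap costs (a gap of length L costs `gap_open + L·gap_extend`),
scored and traced by Biopython's pairwise aligner; equal-length short
subjects (peptide windows) are scored in a single vectorized Gotoh sweep
that produces identical scores.  Traceback is deterministic (the engine's
first optimal alignment); the test suite checks scores, not a particular
co-optimal path, against an independently written brute-force oracle.

E-values use ungapped Karlin–Altschul parameters applied to gapped scores:

* λ is the positive root of `Σᵢⱼ pᵢpⱼ e^(λ sᵢⱼ) = 1`, found by bracketed
  Brent root-finding (relative tolerance 1e-12, asserted to satisfy the
  root equation to 1e-9), with Robinson–Robinson background frequencies;
* K comes from the lattice series
  `K = δ λ e^(−2σ) / (H (1 − e^(−λδ)))` with
  `σ = Σ_k (1/k)[E(e^(λS_k); S_k<0) + P(S_k ≥ 0)]`, truncated when a term
  falls below 1e-10 (k-fold score distributions by repeated convolution).

Using ungapped (λ, K) with gapped scores makes the absolute E-value scale
approximate.  Every decision in the pipeline depends only on E-value
*order* within one database — best-hit identity, cutoff filtering, hit
sorting — and the map from score to E-value is strictly monotone, so the
approximation cannot change a verdict relative to exact gapped statistics
with the same scores.  The database length n in `E = K·m·n·e^(−λS)` is the
summed residue count of all database sequences; no edge-effect correction
is applied.  Alignments with no positive-scoring region are not hits.

The external backend shells out to NCBI `makeblastdb`/`blastp` (tabular
output), remapping sequence ids to safe local accessions because window
ids contain `|`, which collides with NCBI seqid syntax.  Queries shorter
than 30 residues run as `blastp-short` with composition-based statistics
and low-complexity filtering off, since default settings drop short
queries.  E-values from different backends are never mixed within one CPE
decision; hits carry a backend tag and the pipeline enforces it.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| w | 7 | window half-width; length 15 is the dominant convention for sequence-based PTM predictors; configurable per model |
| matrix | BLOSUM62 | standard protein scoring; any Biopython-shipped matrix by name |
| gap open / extend | 11 / 1 | the standard protein-search penalties |
| evalue_cutoff | 10 | applied to stage-1 best hits and to stages 2–3; matches the conventional default of protein search tools, and doubles as the plain-benchmark threshold |
| max_target_seqs | 500 | hit-list truncation after sorting by (E-value, −score, subject id) |
| strict_center | on | see stage 1 above |
| residue sets | S/T/Y, K, K, K/R, K | phosphorylation, acetylation, ubiquitination, sumoylation, methylation; user types supply their own |

Pad character is `X`: it remains legal input to every backend and scores
non-positively against everything (asserted at matrix construction), so
padding can never create similarity.

## Synthetic data

The generator emulates the structure of the real task, not its biology:
i.i.d. sequences from a background composition (uniform by default;
Robinson–Robinson available), planted sites whose residues are drawn from
the PTM type's residue set and kept clear of the termini, homolog
derivation by point substitution at a configured divergence (planted site
residues protected, so ground truth remains well defined), unrelated
decoys, and an optional paralog trap: a query protein embedding one known
window verbatim whose whole-protein best match in the known proteome is an
unannotated near-duplicate — locally identical, globally non-reciprocal,
exactly the case the CPE benchmark exists to reject.

Mutation draws are coupled across divergence values (one uniform variate
per position; a position mutates iff its variate is below the divergence),
so mutation sets are nested in divergence at a fixed seed and recovery is
non-increasing along a divergence grid by construction rather than on
average.

What passing tests show: the search, verdict and evaluation logic behave
as specified under controlled homology.  What they do not show: real
proteomes have motif structure around sites, domains, repeats and indels;
none of these are modelled, and no performance number computed here
transfers to real data.

Study-condition sizes used by the test suite and the acceptance script
were chosen to exercise every code path at interactive runtimes: the
self-inclusive condition uses 30 proteins of length 200–400 with 2–4
phosphorylation sites each; holdout and trap conditions use 10–12 proteins
of length 150–250.

## Degenerate inputs and edge policies

* Annotation rows that contradict the proteome (unknown protein, position
  out of range, residue mismatch) are rejected row-by-row with a reported
  reason; only an annotation table with *no* surviving row is fatal.
* Duplicate annotation rows collapse to one window; duplicate FASTA ids
  are fatal.
* Precision is NaN when nothing was predicted; recall is NaN when the
  truth set is empty; neither raises.
* A query id absent from the query proteome is a hard error naming the id.
* Stage-2/3 partner absent from the hit list ⇒ partner E-value +inf ⇒
  verdict no.

## Known limitations

* Prediction sets are not monotone in the known database: enriching the
  known proteome can *retract* a prediction, because a spurious
  peptide-level transfer that was reciprocal against the smaller database
  loses reciprocity when a better partner appears.  The test suite
  demonstrates this on organism-holdout instances: the retracted calls are
  false positives, and true-site recovery is monotone (the self-inclusive
  model recovers every site the exclusion model does, and all others).
* CPE guards protein identity, not site placement: within a genuinely
  reciprocal protein pair, a weak window match can still transfer a site
  onto a mis-mapped position.  Raising the stage-1 cutoff stringency
  reduces this at the cost of sensitivity.
* Internal E-values are order-faithful, not calibrated; do not compare
  them numerically with BLAST's.
* No indel evolution, motif models or structural filtering in the
  generator; no PSI-BLAST profiles or kinase-specific sub-classification
  in the pipeline.
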