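# ptmtransfer

Homology-based transfer of post-translational-modification (PTM) site
annotations from a proteome with experimental PTM data (the *known*
proteome) to a proteome without any (the *query* proteome).

Most experimentally verified PTM sites belong to a handful of model
organisms, so for a new organism the only evidence available is sequence
homology.  `ptmtransfer` takes the known proteome, its annotated sites
(phosphorylation on S/T/Y, acetylation/ubiquitination/sumoylation on K,
methylation on K/R, or any user-defined type), and the query proteome, and
asks for every candidate residue of a query protein whether a known
modified site can be transferred onto it with whole-protein support.

## Method

For each candidate residue the pipeline runs three local-alignment
searches:

1. the candidate's peptide window (2w+1 residues, default w = 7, ends
   padded with `X`) is searched against the *known peptides* database (one
   window per annotated site) to find the best-matching known peptide and
   its parent, the **hit protein**;
2. the hit protein is searched against the whole query proteome, giving
   the best-match E-value `E(h, best)` and the E-value against the query
   protein specifically, `E(h, q)`;
3. symmetrically, the query protein is searched against the whole known
   proteome, giving `E(q, best)` and `E(q, h)`.

The site is accepted under the **cross-promotion E-value (CPE)** benchmark
iff the two searches are reciprocal — `E(h, q) = E(h, best)` and
`E(q, h) = E(q, best)` simultaneously, i.e. the query protein and the hit
protein are each other's best whole-protein match (exact ties count as
best).  The plain E-value benchmark (accept whenever the stage-1 peptide
E-value is at or below a threshold) is computed alongside for comparison;
CPE positives are always a subset of E-value positives — less sensitive,
more specific.

E-values use Karlin–Altschul statistics, `E = K·m·n·e^(−λS)`, with λ the
positive root of `Σᵢⱼ pᵢpⱼ e^(λ·sᵢⱼ) = 1` and `K` from the standard lattice
series, both computed from the scoring matrix (default BLOSUM62, gap open
11, extend 1).  Alignment runs on a built-in exact Smith–Waterman engine by
default; an adapter to NCBI `blastp`/`makeblastdb` is available
(`--backend blastp`), and the four E-values of one CPE decision always come
from a single backend.

## Worked example

Everything below is generated — no downloads.  The `simulate` command
writes a synthetic study condition: a base organism with annotated sites
plus a 5%-diverged test organism, with organism tags in the annotation
table.

```sh
ptmtransfer simulate --scenario holdout --seed 7 --out fixtures
ptmtransfer build-db --known fixtures/known.fasta \
    --annotations fixtures/annotations.tsv --query fixtures/query.fasta \
    --models-dir models
# -> phosphorylation_w7_e876af45c12e        (deterministic model name)

ptmtransfer predict --model phosphorylation_w7_e876af45c12e \
    --models-dir models --all --mode cpe --out predictions.tsv
# -> 38 predictions written to predictions.tsv

ptmtransfer evaluate --predictions predictions.tsv \
    --truth fixtures/truth.tsv --query fixtures/query.fasta
# -> predicted=38 correct=32 truth=32 precision=84.2% recall=100.0%
```

Every row of `predictions.tsv` carries the transferred site, the hit
protein and hit site it came from, the stage-1 peptide E-value, the four
CPE E-values and both verdicts:

```
query_protein_id  position  residue  ptm_type         hit_protein_id  hit_site_position  peptide_evalue  ...  cpe_verdict  evalue_verdict
T0001             38        Y        phosphorylation  T0001           38                 9.41879e-09     ...  yes          yes
```

The `holdout` command reconstructs the two evaluation models in one step —
M1 excludes the test organism's PTM data from the known databases, M2
includes everything — and scores both against the held-out truth:

```sh
ptmtransfer holdout --known fixtures/known.fasta \
    --annotations fixtures/annotations.tsv --organism testorg
# -> M1 (phosphorylation_w7_929d88e9d6c6): predicted=35 correct=32 truth=32 precision=91.4% recall=100.0%
# -> M2 (phosphorylation_w7_e876af45c12e): predicted=38 correct=32 truth=32 precision=84.2% recall=100.0%
```

The same pipeline is available as a library (`ptmtransfer.predict`,
`ptmtransfer.build_m1_m2`, `ptmtransfer.scenario`, ...); the CLI is a thin
layer over it.

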