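# Methods

## Benchmark model

The package implements a time-delayed evaluation of protein function
prediction. A *time point* is one database release: GO annotations (GAF) plus
protein sequences (FASTA). A *time window* (t0, t1) pairs two releases. The
benchmark at a window consists of:

1. **Common test set** — proteins present in both releases with exactly equal
   amino-acid sequences (case-insensitive string equality; no tolerance for
   fragments or changed headers). Predictions made on a t0 sequence remain
   valid at t1 only if the sequence did not change.
2. **Ground truth** — per aspect, for each common-test protein:
   `propagate(exp_t1) \ propagate(exp_t0)`, the true-path closure of the
   protein's experimental annotations at t1 minus the closure at t0, with the
   aspect root removed. Proteins with an empty difference in an aspect are not
   benchmark proteins for that aspect (per-aspect membership, the standard
   CAFA practice). This set is disjoint from everything experimentally known
   at t0 by construction, so a method is rewarded only for anticipating new
   knowledge. Terms that were present at t0 only with non-experimental
   evidence (e.g. IEA) and gained experimental support by t1 *do* enter the
   ground truth — that is precisely the signal the non-experimental GOA
   baseline measures.

No no-knowledge / limited-knowledge partition is applied: the ground truth
pools proteins with and without prior experimental annotations in the aspect.

## Ontology handling

The GO DAG is read from OBO 1.2 via `obonet` into a `networkx` child→parent
DiGraph. Only `is_a` and `part_of` edges participate in propagation, the
standard CAFA convention; `regulates`-family and other relations are dropped.
Obsolete terms are kept in a side index with their `replaced_by` pointer but
never auto-remapped (silent remapping could change the ground truth);
annotations to obsolete terms are dropped with a logged count. Aspect roots
are the unique parentless terms per namespace, cross-checked against the three
canonical GO root identifiers when they are present. Cycles and cross-aspect
edges are validation errors.

## Evidence classes

The default experimental evidence set is
{EXP, IDA, IPI, IMP, IGI, IEP, HTP, HDA, HMP, HGI, HEP, TAS, IC} — the classic
experimental codes, their high-throughput variants, and the curator codes
TAS/IC. Whether the high-throughput and author-statement codes should count as
"experimental" is a judgment call; the set is therefore a configuration knob
(`evidence_codes`), not a constant. Records carrying a NOT qualifier are
excluded everywhere.

## Baselines

All four baselines transfer only *experimental* annotations of training
proteins and emit scores in (0, 1]; aspect roots are excluded from predictions
and ground truth alike (a configurable flag), since root terms are trivially
true and would inflate precision.

- **naive** — every target receives every term, scored by the term's relative
  frequency among the *propagated* experimental annotation sets of the
  training snapshot ("database" = the experimental training snapshot).
  Propagated counting is the CAFA convention; frequency is then antitone
  along the DAG, so the output needs no further propagation.
- **goa_nonexp** — each target's propagated non-experimental t0 terms
  (all-evidence closure minus experimental closure) at score exactly 1.0.
- **blast** — score(target, term) = max identity over hit subjects whose
  propagated experimental set contains the term. The similarity statistic is
  identity fraction in [0, 1]; the hit table is an input (BLAST `-outfmt 6`
  is read directly), so any statistic on that scale can be substituted.
  Because annotation sets are ancestry-closed, the per-term max over
  neighbours automatically satisfies ancestor-score monotonicity.
- **embedding** — the same transfer with cosine similarity (negative values
  clipped to 0) over an embedding table, restricted to the `top_k = 50`
  most-similar annotated training proteins. The metric and neighbourhood size
  are defaults chosen for robustness, both configurable.

`pairwise_identity` (used by the fixture generator so no external aligner is
needed) is a Needleman–Wunsch global alignment with match +1, mismatch 0 and
free gaps; identity = matches / alignment length, with a deterministic
diagonal → up → left traceback preference.

## Evaluation

Protein-centric (macro) averaging with the m(τ)/n denominators described in
the README; proteins with ground truth but no predictions at τ count against
recall but not precision. Micro-averaged pooling (`averaging="micro"`) is
provided because "a collection of binary predictions" admits both readings.
Scores are compared with a closed lower bound (score ≥ τ), which matters at
grid edges. Prediction scores outside (0, 1] are validation errors; unknown
or obsolete terms are dropped with a count. Fmax ties resolve to the smallest
τ, making `tau_best` deterministic. Floating-point accumulation iterates
proteins in sorted order, so no reported number depends on input file order.

`fmax_oracle` recomputes Fmax by materialising every distinct score plus the
grid as candidate thresholds, using plain set operations and sharing no code
with the sweep; it refuses instances above 50 proteins / 200 terms and exists
for cross-checking only.

## Synthetic data generator

The generator emulates the accumulation structure of real release pairs, not
their scale. Defaults (all configurable on `FixtureConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_terms` | 50/aspect | ontology size incl. root |
| `n_top` | 10 | root children (top-level branches) |
| `branching` | 2 | max parents per term |
| `n_proteins` | 100 | proteins per release |
| `p_annot` | 0.6 | P(protein experimentally annotated at t0) |
| `gain_rate` | 2.0 | expected gained leaf terms per protein per window |
| `nonexp_rate` | 0.3 | P(gain pre-announced as IEA at t0) |
| `bg_nonexp_rate` | 0.3 | P(unrelated IEA annotation at t0) |
| `mut_rate` | 0.1 | P(one residue substitution between releases) |
| `seq_length` | 60 | residues per protein |

Design choices that matter:

- **Topology.** Each aspect is a balanced forest: the root fans out to
  `n_top` branch heads and later terms attach (1–2 parents, diamonds allowed)
  within a single branch. As in the real GO, unrelated terms then share
  little beyond the root, so the closures of randomly chosen false terms
  rarely intersect a protein's ground truth — random predictions score near
  zero, and the corruption dial `q` spans the full quality range. A
  preferential-attachment prototype instead produced shallow hub DAGs in
  which every closure passed through the same few terms, compressing the
  dynamic range of the benchmark.
- **Accumulation-only.** Every t0 annotation line literally reappears at t1;
  gains are new experimental leaf-term annotations. Annotation *removals*
  (term obsoletion aside) would need a different ground-truth rule and are
  out of scope.
- **No-knowledge gains.** Gains are placed in aspects where the protein has
  no prior experimental annotation. Under the difference ground truth, a
  protein with prior knowledge in the same aspect can never be recovered
  perfectly (max-rule propagation forces the already-known ancestors of any
  predicted gained term above threshold, capping precision below 1), so this
  choice makes the quality dial well-calibrated: `q = 0` yields Fmax = 1.0
  exactly. Prior-knowledge (limited-knowledge) ground-truth algebra is still
  exercised by the builder's unit tests; the *benchmark builder itself* pools
  both cases whenever its real inputs contain them.
- **Scores on the grid.** Generated prediction scores live on the 0.01 grid
  (a high band, [0.71, 1.00]), so the oracle's score-derived candidate
  thresholds coincide with the sweep grid and the two routes are exactly
  comparable.
- **Embeddings** are unit-normalised dipeptide (k = 2) count vectors —
  deliberately simple, but their cosine correlates with alignment identity on
  sequence families, which is all the transfer baselines need.

What the generator does **not** emulate: realistic GO topology statistics
(term counts, depth distribution), realistic sequence evolution (one
substitution per window at most), annotation biases between organisms, or
database-scale sizes. Passing tests therefore demonstrate correctness of the
benchmark machinery — set algebra, propagation, metric computation,
determinism — not predictor performance on real data.

## Numerical and procedural details

- Threshold grid: {0.01, …, 1.00} by 0.01 (`tau_step` configurable).
- Evaluation problem sizes: the default synthetic study uses 100 proteins and
  3×50 terms; the oracle cross-check runs on 12-protein/3×15-term instances so
  brute force stays instant. Test-suite sweeps use 20 seeds.
- Windows are labelled `t0--t1` (ASCII) in file and directory names.
- The catalog marks a window "ready" only after every supplied prediction set
  evaluates cleanly; failures quarantine partial results in a staging
  directory and leave the window "pending".
- All generators are pure functions of (config, seed); CLI subcommands write
  byte-identical outputs on identical inputs (catalog stamps derive from the
  release id, and every output directory carries a run manifest with input
  SHA-256 hashes).

## Known limitations

- Information-accretion-weighted metrics (the S-measure family) are not
  implemented; evaluation is unweighted precision/recall/F1.
- GPAD/GPI input, isoform-level annotations and taxon filtering are not
  supported.
- `replaced_by` pointers are recorded but never applied; annotations to
  obsolete terms are simply dropped.
- Running BLAST or producing protein language-model embeddings is out of
  scope; both enter as tabular inputs.
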