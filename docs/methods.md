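# Methods

## The transfer model

`idptransfer` treats annotation transfer as a gated projection problem.
The unit of annotation is a *region* of a reference protein — a 1-based
inclusive span carrying one ontology term (GO for function, IDPO for
disorder-specific structure/function). An annotation is projected onto an
ortholog through a family multiple sequence alignment, and the projection
is trusted only if the alignment is demonstrably reliable *at the scale of
that region*, not merely overall.

The assumptions are the standard ones of ortholog-based transfer:
one-to-one orthologs are likely functionally equivalent; the reference
sequences are high-quality, so they can anchor filtering of the (variable
quality) ortholog sets; and alignment reliability, not sequence identity
alone, is the right license for transfer — in particular for disordered
regions, whose fast evolution makes locally poor alignments common inside
globally acceptable ones.

## Pipeline stages and parameters

| Stage | Parameter | Default | Why |
|---|---|---|---|
| Entry filters | canonical map | optional | canonical/identity rules need an external sequence source; when absent those two rules are skipped with a warning |
| Reference clustering | identity threshold | 80% | removes redundant references while keeping distinct proteins; 60% available for the sensitivity grid |
| Ortholog length filter | bounds | [0.30, 1.30] × ref length | too-short sequences cannot cover the reference, too-long ones likely carry extra domains; a stricter [0.70, 1.30] mode is a config switch |
| Global MSA filter | identity to reference | 60% | below this, MSAs of disordered proteins stop being reliable; 80% in the grid |
| Reliability gate | NorMD minimum | 0.6 (strict >) | conventional NorMD reliability threshold |
| Region filter | identity in window | 60% | same rationale, applied within the region window; 80% in the grid |
| Gap model (aligner and NorMD) | open 10, extend 0.5 | BLOSUM62 scores | standard affine parameters for half-bit matrices |

Clustering identity is defined as identical residue pairs over the full
global-alignment length (gap columns included) — the reproducible,
alignment-based contract, with the word-based CD-HIT heuristic regarded as
an accelerator rather than a definition. Identity to the reference inside
an MSA uses a different denominator on purpose: reference non-gap columns,
so that deletions in an ortholog lower its score — the quantity being
measured is fidelity to the annotated reference positions.

The per-region order of operations is: chop the window → realign the
ungapped subsequences → measure per-row region identity → drop rows below
the region threshold → realign survivors → score with NorMD. Realigning
before measuring avoids penalizing orthologs for global-alignment
artifacts inside the window; realigning after filtering gives the score to
the alignment that transfer will actually use. Slicing without
realignment is available behind `region_realign=False`. Rows with zero
residues in the window get no record — an annotation cannot be placed on
nothing. Overlapping reference regions are processed independently, each
with its own window, filter and score. The region gate can be disabled
(`region_gate=False`) for the comparison mode that quantifies how many
globally-licensed transfers region-level QC rejects; in that mode every
present row survives and the NorMD check is skipped, so the gated transfer
set is always a subset of the ungated one.

## NorMD

The quality score is a normalized mean-distance objective built from
residue similarity alone. For each unordered pair of rows the aligned
score is

S_pair = Σ over mutually ungapped columns of s(a, b) − affine gap penalties,

with s the BLOSUM62 score and gaps opposite a residue penalized
open/extend (terminal gaps unpenalized by default, so fragments are not
punished twice). It is normalized between two ab initio anchors computed
from the sequences themselves:

* S_max = min of the two self-alignment scores Σ s(a, a) — the best the
  pair could do;
* S_rand = min(len) · f_i' S f_k, the expected per-column score of
  unrelated sequences with the pair's residue compositions and lengths;

normd_pair = (S_pair − S_rand)/(S_max − S_rand), and the alignment score
is the mean over pairs, accumulated in row-id-sorted order so that the
score is exactly invariant to row permutation. Identical ungapped
sequences score exactly 1; mutually random sequences score near 0 (the
aligner's optimization keeps the value slightly above the composition
expectation); values above 1 are arithmetically legal. A degenerate pair
with S_max ≤ S_rand (e.g. all-undefined residues) contributes 0 — such an
alignment carries no signal either way. Matrix, gap penalties and the 0.6
threshold are exposed as configuration; the defaults above are the
package's reference values, and the test suite pins the score's behavior
(separation of identical vs random families, exact permutation
invariance, monotone degradation under column shuffling) rather than any
single constant.

## Built-in aligner

External aligners (MAFFT, Clustal Omega) are the production path, run with
their defaults through subprocess adapters. The built-in progressive
aligner exists so that the entire pipeline is runnable and exactly
reproducible with no external binaries: UPGMA guide tree over 3-mer cosine
distances, profile–profile global dynamic programming with affine gaps
(open 10, extend 0.5) on expected BLOSUM62 scores, deterministic
tie-breaking (match preferred over gap-in-second over gap-in-first). With
two sequences it reduces to plain pairwise global alignment and its scores
match an independent dynamic-programming implementation exactly. It does
no iterative refinement and is intended for family sizes in the tens, not
thousands.

## Synthetic families

The generator emulates what the pipeline consumes — per-reference ortholog
sets at controlled pairwise identity — not how real families arise. A
reference is drawn uniformly over the 20 residues; each ortholog applies
an exact count of substitutions at uniformly chosen positions (identity
calibration is exact absent indels), then insertions/deletions with
geometric lengths at a per-residue event rate. Substituted residues are
drawn with BLOSUM62-conditional weights (2^(score/2), identity excluded)
rather than uniformly, so a synthetic family at a given percent identity
looks to similarity-based scores like a real homolog family at that
identity — the regime the NorMD gate is calibrated for. Planted annotated
windows can carry an identity override (the locally-diverged decoy
construction); indels keep a 2-residue margin away from planted windows by
default so ground-truth projected spans are well defined. Every edit is
recorded, so the generator emits the true alignment, realized identities
and expected transfer table.

What the generator does not emulate: tree-structured evolution and rate
heterogeneity (orthologs are independent perturbations of the reference),
compositional bias of real disordered regions, fragmentary or wrongly
predicted database sequences beyond simple length variation, and paralog
contamination. Passing tests therefore demonstrate that the machinery is
correct under controlled identity structure, not that the thresholds are
optimal for any particular proteome.

The benchmark scenarios fix the study conditions used by the tests and the
acceptance script: three families, 200-residue references, eight orthologs
at 75–95% identity, indel rate 0.01/residue, two planted regions (one
IDPO, one GO term); the decoy variant adds one ortholog per family at
~73% realized global identity diverged to ~30% inside the first region.
These sizes keep a full 16-configuration threshold grid under a minute
while exercising every gate.

## Numerical and design choices

* Coordinates are 1-based inclusive in every external format; the single
  conversion to Python slices happens at `AnnotatedRegion.slice`.
* Tie-breaks are deterministic everywhere: clustering visits sequences by
  (length descending, accession); transfer tables sort by (region start,
  term, ortholog); DP traceback prefers match states.
* `.` and `-` are both accepted as gaps on read; `-` is written.
* Degenerate inputs are data, not errors, wherever the protocol says so: a
  region with fewer than two surviving rows is "untransferable", an entry
  failing a filter is a rejection with its first failing rule. Errors are
  reserved for contract violations (ragged alignments, regions outside the
  sequence, single-row NorMD).
* The pinned public-release census (entry counts before/after filtering
  and the 80% cluster count for the curated disorder database, version
  9.1) is implemented and asserted in the test suite, but runs only when
  the release JSON is placed at `data/disprot-9.1.json` — the file is too
  large to ship and must be downloaded.
* plDDT vectors with any value above 1.5 are treated as 0–100 scaled and
  divided by 100; the disorder call is value < 0.7.
* Annotation overlap is reference-normalized (denominator: the reference
  region's column window) and compares regions within the same ontology
  namespace, reporting the best-overlapping candidate; the statistic is
  deliberately asymmetric between the two proteins.

## Known limitations

* Greedy clustering computes all-vs-representative global alignments; it
  is quadratic and meant for thousands of references at most.
* NorMD here follows the published objective's structure (column
  similarity, self-alignment maximum, composition-expected correction) with
  the reference defaults exposed as configuration; scores from other NorMD
  implementations may differ in absolute value near the threshold.
* No ontology-aware propagation: term identifiers are opaque strings, and
  no GO-DAG reasoning is attempted.
* Ortholog acquisition is file-based by design (`<reference>.<provider>.fasta`);
  live orthology-database queries are out of scope.
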