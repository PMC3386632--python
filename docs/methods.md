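# Methods

## The search pattern

A disintegrin presents its integrin-recognition tripeptide on a loop
bracketed by cysteine residues whose pairing exposes the motif. The
scanner therefore implements the bounded-gap pattern
`C-x(0,16)-XYZ-x(0,16)-C`: a literal tripeptide occurrence qualifies iff
a cysteine lies within 16 residues on each side, strictly outside the
tripeptide. Choices the pattern statement leaves open, fixed here:

- **Symmetric bounds.** The same 0–16 spacer bound applies on both
  sides; both bounds are independently configurable per pattern.
- **One match per motif occurrence,** not per cysteine pair. When
  several cysteines qualify on a side, the *innermost* one is reported,
  giving a canonical single answer that matches the shortest
  cysteine-bracketed loop. A single cysteine may serve as the right
  flank of one match and the left flank of the next.
- **Exact-literal matching.** `X` (unknown residue) in a sequence never
  matches a motif position; tripeptides containing `X` are rejected as
  patterns. Ambiguity codes (B, Z, U) are rejected at load time rather
  than silently translated, since their intended reading is
  input-specific.
- **Coordinates are 1-based inclusive** in every output.
- **Scanning runs on the full precursor.** Matches inside the predicted
  signal peptide are kept and flagged `overlaps_signal` (the secretion
  filter concerns which proteins are considered, not which region is
  scanned); downstream users can exclude them.

Matches within a sequence are sorted by position, then tripeptide, so
output is independent of pattern-list order.

## Secretion gate

Secreted candidates are identified by a deterministic heuristic modeled
on the classical tripartite signal-peptide architecture, with every
threshold explicit so that the gate is reproducible offline:

| parameter | default | meaning |
|---|---|---|
| n-region window | 10 | initial Met or a K/R within the first 10 residues |
| h-region window | 30 | the hydrophobic core must overlap residues 1–30 |
| minimum h-run | 8 | consecutive residues from {A,I,L,M,F,V,W} |
| cleavage cap | 45 | signal peptides longer than this are not considered |

The h-region is taken as the first maximal hydrophobic run whose overlap
with the 30-residue window reaches the minimum length; the cleavage site
is the first position after the run end whose −3 and −1 residues
(relative to the cut) are both small ({A,G,S,C,T}), searched up to the
cap, with fallback `run end + 5` (capped). The score is the run length
over 30, capped at 1. Sequences shorter than 15 residues are reported
non-secreted rather than erroring.

This heuristic is a transparent gate, not a reimplementation of a
neural/HMM signal-peptide predictor; no attempt is made to reproduce any
particular server's accept/reject set. Users with real predictions can
import them as TSV (`seq_id`, `has_signal` Y/N, `cleavage_pos`,
`score`); imported verdicts always override the heuristic.

## Annotation and duodegrins

The tripeptide → integrin/cell mapping ships as editable data because the
assignments are putative, inferred from characterized disintegrins of
each motif class: RGD and WGD with the αIIbβ3/αvβ3/α5β1 group, KGD and
RED with αIIbβ3 (the RED assignment follows disagregin, a tick αIIbβ3
antagonist carrying RED on a Kunitz scaffold), MLD with the leukocyte
integrins α4β1/α4β7/α9β1, KTS and RTS with α1β1, VGD with α5β1. Unknown
tripeptides annotate as unmapped rather than erroring.

A **duodegrin** is a sequence with more than one tripeptide motif; this
package requires ≥ 2 *distinct* motif types (the combinations observed in
midgut cysteine-rich proteins are distinct pairs such as VGD+RTS and
RED+VGD, whereas precursors with one or two RGD copies are not given the
name). Same-type multiplicity is visible through the per-sequence match
count.

## Phylogenetics

Distances are uncorrected p-distances with pairwise gap deletion — the
scale of "percent amino-acid divergence" — with no multiple-hit
correction; a pair with zero comparable columns is an error (and, inside
the bootstrap, triggers resampling of the replicate, counted in the log).
Trees are built by standard Saitou–Nei neighbor joining: join the pair
minimizing `Q(i,j) = (n−2) d(i,j) − R_i − R_j`, branch lengths
`l_i = d(i,j)/2 + (R_i − R_j)/(2(n−2))`, reduction
`d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2`. Numerical choices:

- **Ties** in Q are broken by the smallest (i, j) pair in the current
  node order, so results are exactly reproducible.
- **Negative branch lengths** are clamped to zero after computation;
  the raw estimates are retained on each node (`raw_length`).
- On an additive matrix the reconstruction is exact: recovery of every
  split and all leaf-to-leaf path lengths to ≤ 1e−9 is part of the test
  suite.

Bootstrap supports are computed for the bipartitions of the single
full-data tree (not a consensus): each of B replicates resamples n_cols
columns with replacement under a seeded generator, and a bipartition's
support is the rounded percentage of replicate trees containing it.
Default B = 1000 (tests and the acceptance script use 100–200 for speed);
replicate count and the p-distance choice are package defaults, stated
here as choices.

Newick output writes branch lengths to 6 decimals and integer supports
as internal-node labels; round-trip parse equality is tested against an
independent Newick parser.

## Synthetic fixtures

The generator emulates the intended input — GenBank-style secreted
proteins of blood-feeding taxa — closely enough to exercise every stage
with known truth:

- Background residues are drawn uniformly over the 20 amino acids with
  the cysteine weight as a parameter (default 0.05; boundary tests
  raise it), because the flank-hit probability must be controllable.
- Record length is uniform on 80–300 residues; 60% of records receive a
  planted signal peptide built to satisfy the gate exactly; the mean
  number of planted motifs per record is 0.8 (Poisson), with spacers
  uniform on [0, 16] and cysteine-free fillers so the planted flanks
  are innermost.
- Decoys probe the boundaries: a motif whose entire 17-residue right
  window is cysteine-free (undetectable), a motif with a left spacer of
  exactly 17 (undetectable), and a motif planted inside the signal
  peptide (detectable, flagged). Non-secreted records have hydrophobic
  runs in the first 30 residues broken by construction, so gate
  rejection is guaranteed, not probabilistic; for the same reason
  planted segments are never spliced into that window.
- Two secreted records always carry a planted VGD+RTS pair so duodegrin
  flagging is exercised at any problem size.
- After assembly the proteome is **audited**: the scanner enumerates
  all hits, accidental motifs arising from the random background are
  appended to the ledger, planted expectations that fail are raised as
  construction errors. Fixture-based counts are therefore exact, and an
  independent brute-force oracle in the test suite verifies the
  scanner (and hence the audit) separately.

What passing these tests shows — and does not. The fixtures establish
that the pattern engine, gate, annotation and pipeline plumbing behave
exactly as specified on sequences *whose ground truth is known by
construction*. They do not establish biological sensitivity or
specificity on real proteomes: real signal peptides are more varied than
the heuristic's definition, real cysteine spacing is not uniform, and a
motif hit remains putative until the protein is shown to behave as a
disintegrin. The headline candidate counts reported from public-database
screens depend on the database snapshot and are not reproducible from
fixtures; all acceptance checks are therefore property-based
(recall/precision against the ledger, boundary exactness, additive-tree
recovery, support behavior, byte-identical reruns).

## Problem sizes and defaults

The acceptance script uses a 200-record proteome, 50 random trees of
5–12 leaves, and 200 bootstrap replicates; the test suite additionally
runs 1000 random sequences (lengths 20–400, cysteine frequency 0.08)
against the brute-force oracle. All randomness flows from explicit
seeds; identical seeds give byte-identical fixtures, trees and pipeline
outputs.

## Known limitations

- The gate heuristic has no transmembrane-segment discrimination; a
  protein with an N-terminal TM helix can pass.
- Taxon scoping is substring/code matching on header metadata, not
  taxonomy-aware retrieval.
- Only literal tripeptide + bounded-cysteine-flank patterns are
  supported, not the full PROSITE grammar.
- Gene-ontology columns and external hyperlinks of a hosted worksheet
  are out of scope; the database is plain TSV (optional XLSX mirror).
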