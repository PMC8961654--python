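# Methods

## Model

pepspot treats peptide spotting as two nested ranking problems.

**Sequence stage.** A fragment of the query is assumed to bind the receptor
the way the template peptide does: same register, same interface. Under
that assumption the only information needed to rank fragments is (i) how
substitutable each fragment letter is for the template letter at that
position, and (ii) how much that position matters to the interface. The
score of fragment letter *a* at template position *j* is

    (1 + N_inter(j) · Θ) · B(a, b_j)

with *B* a symmetric substitution matrix, *b_j* the template-peptide letter,
and *N_inter(j)* the number of hydrophobic or ionic receptor residues in
heavy-atom contact (≤ 5.0 Å) with template-peptide residue *j*. Θ ∈ {0, 1}
selects the weighting regime: `galaxy` applies the interface weight only to
positively scoring (conserved) pairs, `modified` applies it to all pairs so
that a poor substitution at a hot-spot position is penalized as strongly as
a good one is rewarded, and `raw` disables the weight. The fragment score
is the plain sum over aligned positions; fragments shorter than the
template are left-anchored and unaligned template positions contribute
nothing. There is no gapped alignment in this stage: for peptides of 4–14
residues, gap placement has no statistical support and would mostly add
noise.

Algebraic consequences that the tests pin down: the weight never changes
the sign of a term; `galaxy` leaves non-positive entries untouched; at
N_inter = 0 all three regimes coincide; |score| is non-decreasing in
N_inter.

**Structure stage.** The sequence score cannot see physics — a fragment of
hydrophobic residues may thread poorly onto a polar template peptide yet
pack beautifully against a greasy pocket. The rerank therefore rebuilds
the top-T fragments in 3D on the template scaffold, scores a small
ensemble of decoys per fragment with a structure-based potential, keeps
the minimum (best) decoy energy per fragment — the usual decoy-selection
convention — and reorders by it. Ties preserve the sequence-stage order.
Fragments whose backend or scorer fails are marked unscored and ranked
after all scored fragments rather than aborting the run.

## Contact definition

Two residues are in contact when at least one heavy-atom pair (one atom
from each residue, two atoms in total) lies within the threshold, i.e. the
minimum inter-residue heavy-atom distance is ≤ 5.0 Å. This matches the
convention of the template-based docking literature this score family
descends from. For users who read "at least two heavy atoms" as two
distinct atom *pairs*, `residue_contacts(..., min_pairs=2)` switches the
predicate; nothing else changes.

Residue class sets (configurable, always logged in `run.json`):

| set          | letters              | role                                   |
|--------------|----------------------|----------------------------------------|
| hydrophobic  | A V L I M F W C P    | counted in N_inter; −1 pair weight     |
| ionic (−)    | D E                  | counted in N_inter; charge pairing     |
| ionic (+)    | K R H                | counted in N_inter; charge pairing     |

Only the *receptor* residue's class enters N_inter; the peptide residue's
own class is irrelevant to the interface count (it matters only to the
contact potential).

## Key parameters

| parameter        | default  | units | rationale                                          |
|------------------|----------|-------|----------------------------------------------------|
| contact threshold| 5.0      | Å     | heavy-atom interface convention                    |
| k                | template | aa    | window = template peptide length                   |
| min window       | 2        | aa    | shorter tails carry no signal                      |
| matrix / mode    | BLOSUM62 / modified | — | best-performing combination; the package default |
| top_T            | 25       | hits  | stage-2 entry threshold, user-adjustable           |
| n_decoys         | 4        | —     | enough to average out graft jitter                 |
| σ (graft jitter) | 0.2      | Å     | perturbs decoys without crossing contact margins   |
| RMSD classes     | 1.5 / 3.0| Å     | L/M/H bins, half-open [0,1.5), [1.5,3), [3,∞)      |
| pair filters     | 4–14 aa, id ≤ 0.80, ratio > 0.6, Jaccard ≥ 0.5, ≤5/receptor | — | benchmark assembly rules |

Boundary conventions that the data do not dictate were fixed once and
tested: RMSD class bins are half-open on the right (1.5 Å is M, 3.0 Å is
H); peptide identity uses the shorter peptide as denominator (conservative
for the ≤ 80 % filter); "same binding site" is operationalized as Jaccard
overlap ≥ 0.5 between the receptor contact-residue sets of the two
complexes; rank change is reported as seq_rank − structure_rank so that
positive means improvement.

## Windowing

A query of length L scanned with window k produces windows at every start
position, the C-terminal ones shrinking from k down to the 2-residue
minimum — exactly L − 1 fragments when L > k (a 777-residue query gives
776 nonapeptides). `allow_short_tail=False` restores the plain L − k + 1
full-window scan. Duplicate fragment sequences are all retained; evaluation
takes the best rank among occurrences of the true binder.

## Geometry kernels

Receptor superposition is a hand-written Kabsch solve (SVD with the
determinant correction against reflections) over Cα atoms matched by
author numbering, falling back to a sequence alignment when the numbering
disagrees; the tests check it against an independent SVD implementation
(`scipy.spatial.transform.Rotation.align_vectors`) on random point sets.
Peptide RMSD is computed over sequence-aligned Cα pairs *without*
re-fitting on the peptide — the receptor frame is the biological frame.
Pairs missing a Cα are dropped with a warning. Pairwise alignments
(peptide equivalences, identity, receptor fallback) use global
Needleman–Wunsch with BLOSUM62, gap open −10 / extend −1 via Biopython.

## Synthetic data: what it emulates and what it does not

`pepspot.fixtures` builds complexes with *exactly known* contact structure:
residues are compact atom clusters on a regular layout, planned contacts
are placed at ≤ 4.0 Å minimum heavy-atom distance and every unplanned pair
at ≥ 6.5 Å. Because the margins straddle the 5.0 Å predicate by ≥ 1 Å on
each side, contact maps — and therefore N_inter, the contact potential and
everything downstream — are immune to the graft backend's 0.2 Å jitter.
Planted-binder queries embed a (optionally mutated) copy of the template
peptide in a uniform-random background at a seeded offset; displaced-pair
fixtures translate the peptide rigidly so the post-superposition RMSD
equals the construction displacement to numerical precision.

What passing on these fixtures shows: the arithmetic of the score, the
contact predicate, the ranking contracts, the superposition/RMSD kernels
and the end-to-end plumbing are correct. What it does not show: real
interfaces are not generated — side-chain packing, backbone deviation
between target and template peptides, compositional bias of real
sequences, and the discriminative power of real statistical potentials are
all outside the synthetic conditions. Accuracy rates measured here
(planted-binder recovery at 100 %, synthetic benchmark top-N) are
correctness checks of the machinery, not performance estimates on
experimental complexes.

The built-in contact-potential scorer is likewise a deliberately coarse
residue-class potential whose virtue is that its optimum is computable by
hand in tests; serious reranking of real complexes should go through the
SOAP/DOPE/VoroMQA adapters when those tools are installed.

## Numerical and degenerate-input choices

* Ranking ties break by fragment start (earlier wins), then source id;
  rerank ties by prior sequence rank then start. All orderings are total,
  so identical inputs give byte-identical tables; parallel decoy scoring
  (joblib, partitioned by fragment with per-fragment seeds derived from
  `SeedSequence((seed, index))`) is tested equal to serial.
* Unknown or nonstandard letters ('X', B, Z, …) score 0 at their positions
  instead of aborting; MSE-like residues map to their parent letter during
  parsing, residues without a standard parent become 'X' and belong to no
  class set.
* Altloc: highest occupancy wins, ties prefer blank/'A'; first model only;
  HETATM residues without an amino-acid parent are dropped.
* Matrix files are validated for symmetry (1e−9) and full 20-letter
  coverage, with the first offending cell named.
* A peptide chain longer than 50 residues is rejected with a hint that the
  receptor and peptide selections may be swapped.
* Zero-variance inputs to the hydrophobicity–rank correlation return NaN
  with a warning (the statistic is undefined, not zero).

## Problem sizes

The test suite and acceptance script run on deliberately small instances —
receptors of ~10 residues, 120–777-residue queries, 20–50 seeded
replicates, 20-case synthetic benchmarks — chosen so the full suite
completes in seconds while still exercising every code path at full
precision. All sizes are parameters; nothing in the implementation is
specialized to them.

## Known limitations

* The graft backend cannot model fragments longer than the template
  peptide, insertions, or any backbone rearrangement; it inherits the
  template register by construction.
* One scorer drives the rerank; when several are computed they are
  reported side by side, not combined into a consensus.
* mmCIF input, hydrogen handling, structure repair and binding-affinity
  prediction are out of scope.
* The worked example on the real TSG101/HRS structures requires reference
  files from RCSB/UniProt that are not redistributable with the package;
  the corresponding test documents the expected outcome (true binder at
  sequence rank 20 of 776) and fails visibly when the files are absent.
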