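# pepspot

Template-based **spotting** of receptor-binding peptides: given an
experimentally determined receptor–peptide complex (the *template*) and the
full-length sequence of a protein known to interact with the same receptor,
pepspot identifies *which* short fragment of that sequence is the binding
peptide — and models its bound conformation.

This sits at the crossroads of protein–protein and protein–peptide
interaction prediction: docking tools assume the peptide is already known;
here the peptide must first be found inside a sequence of hundreds of
residues. The intended users are structural bioinformaticians triaging
candidate binding motifs before experiments (peptide arrays, mutagenesis) or
before expensive flexible docking.

## Method

**Stage 1 — sequence threading.** The query is scanned with a sliding window
of the template-peptide length *k* (plus shrinking C-terminal windows, so a
query of length *L* yields *L* − 1 fragments). Each fragment is threaded
without gaps onto the template peptide and scored with an
interface-weighted substitution matrix. For query letter *a* aligned to
template-peptide position *j* (template letter *b*):

```
score(a, j) = (1 + N_inter(j) · Θ) · B(a, b)
```

where *B* is a substitution matrix (built-in BLOSUM62, or any
user-supplied symmetric matrix such as QU3), *N_inter(j)* is the number of
hydrophobic or ionic receptor residues whose minimum heavy-atom distance to
template-peptide residue *j* is ≤ 5.0 Å, and Θ gates the weight:

* **raw** — no weight, plain *B(a, b)*;
* **galaxy** — Θ = 1 only where *B(a, b)* > 0 (conserved pairs);
* **modified** — Θ = 1 always (the package default, "BLOSUM62-M").

The weight concentrates the score on the peptide positions that actually
touch the receptor, which plain substitution matrices know nothing about.
Fragments are ranked by the summed score.

**Stage 2 — structure-based rerank.** The top *T* fragments (default 25)
are built into 3D decoys on the template scaffold and rescored with a
structure-based potential; each fragment is represented by its best
(lowest) decoy energy and the list is reordered. The built-in *graft*
backend copies the template peptide backbone + Cβ and relabels residue
identities (with optional Gaussian coordinate jitter across decoys); the
built-in *contact-potential* scorer is a coarse residue-class pair
potential. Adapters for an external comparative-modeling engine and for
SOAP / DOPE / VoroMQA potentials expose the same contracts and raise an
explicit error when their tool is absent.

**Evaluation.** For benchmark pairs (same receptor, two peptides) the
toolkit superposes the receptors (Kabsch on shared Cα atoms), computes the
peptide Cα RMSD over sequence-aligned positions, `RMSD = sqrt(Σ dᵢ² / N)`,
bins it into classes L [0, 1.5), M [1.5, 3.0), H [3.0, ∞) Å, applies the
dataset filters (peptide lengths 4–14, pair identity ≤ 80 %, length ratio
> 0.6, shared binding site, ≤ 5 pairs per receptor), and reports top-N
spotting accuracy, rank-change summaries and the hydrophobicity–rank
correlation.

## Worked example

Generate a synthetic template complex and a 120-residue query with the
template peptide planted at a known position, then run the pipeline:

```sh
pepspot fixtures complex --receptor-seq GLSDKGYR --peptide-seq PEATAPPEE \
    --contacts "1,0;3,1;4,1" --seed 11 --out template.pdb
pepspot fixtures query --binder PEATAPPEE --length 120 --seed 9 --out query.fasta
# -> wrote query.fasta (binder planted at 25)
pepspot run --receptor template.pdb --receptor-chains A --peptide-chain B \
    --query query.fasta --top 5 --decoys 4 --seed 1 --out run
```

`run/ranked_sequence.tsv` (head):

```
rank  start  end  sequence   seq_score  matrix    mode
1     25     33   PEATAPPEE  66.000000  BLOSUM62  modified
2     31     39   PEEQADTGY  25.000000  BLOSUM62  modified
3     116    120  QQATR      12.000000  BLOSUM62  modified
```

The planted binder is spotted at rank 1 with score 66: the identity match
contributes the BLOSUM62 diagonal at every position, boosted at the two
interface positions (the receptor's Leu contacts peptide position 1 and its
Asp+Lys contact position 2, so `n_inter = [1, 2, 0, …]`).
`run/ranked_structure.tsv` shows the rerank of the top 5 by the contact
potential (the binder stays first with best decoy score −1.0), and each
`frag_<start>_<end>/` subdirectory holds the fragment FASTA, the 4 decoy
PDBs and their score table.

To benchmark over many template/target pairs, write a manifest TSV
(columns `pdb_template, pdb_target, receptor_chains,
peptide_chain_template, peptide_chain_target, query_fasta`) and run
`pepspot eval --manifest pairs.tsv --out evalout`; it emits per-case binder
ranks, a top-N accuracy table (N ∈ {1, 10, 25, 50, 75}), rank-change
summaries and an RMSD-class breakdown.

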