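"""Benchmark machinery: superposition, peptide RMSD, filters, rank metrics.

Two complexes sharing a receptor are compared by (1) least-squares rigid
superposition of the receptor C-alpha atoms (Kabsch), (2) C-alpha RMSD over
sequence-aligned peptide positions without re-fitting on the peptide:

    RMSD = sqrt( (1/N) * sum_i d_i^2 )

with d_i the post-superposition distance of the i-th equivalent pair. RMSD
values are binned into classes L [0, 1.5), M [1.5, 3.0), H [3.0, inf).
Benchmark pair filters, top-N spotting accuracy, rank-change summaries and
the hydrophobicity-rank correlation complete the evaluation toolkit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from pepspot.constants import KYTE_DOOLITTLE
from pepspot.structio import ResidueRecord, TemplateComplex

logger = logging.getLogger(__name__)


# --- rigid superposition -------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``reference``.

    Classic SVD solution with the determinant correction that excludes
    reflections.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matched Nx3 arrays")
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (moving - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    return RigidTransform(R, t)


def _ca_map(residues: Sequence[ResidueRecord]) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    for res in residues:
        ca = res.atom("CA")
        if ca is not None:
            out[(res.chain_id, res.seq_num, res.icode)] = ca
    return out


def _transform_complex(cplx: TemplateComplex, tr: RigidTransform) -> TemplateComplex:
    def move(res: ResidueRecord) -> ResidueRecord:
        return res.with_coords(tr.apply(res.coords))

    return TemplateComplex(
        tuple(move(r) for r in cplx.receptor),
        tuple(move(r) for r in cplx.peptide),
        cplx.n_inter,
    )


def superpose_receptors(
    ref: TemplateComplex, mov: TemplateComplex
) -> tuple[RigidTransform, TemplateComplex, float]:
    """Superpose the moving complex onto the reference via receptor C-alphas.

    Receptor residues are matched by (chain, author number, insertion code);
    if fewer than 3 match, a sequence alignment of the receptor chains is
    used as fallback. The transform is applied to the whole moving complex
    including its peptide. Returns (transform, moved complex, receptor RMSD).
    """
    ref_ca = _ca_map(ref.receptor)
    mov_ca = _ca_map(mov.receptor)
    shared = sorted(set(ref_ca) & set(mov_ca))
    if len(shared) >= 3:
        ref_pts = np.array([ref_ca[k] for k in shared])
        mov_pts = np.array([mov_ca[k] for k in shared])
    else:
        pairs = _align_receptor_residues(ref.receptor, mov.receptor)
        if len(pairs) < 3:
            raise ValueError(
                f"cannot superpose: only {max(len(shared), len(pairs))} matched "
                "receptor C-alpha atoms (need >= 3)")
        ref_pts = np.array([ref.receptor[i].atom("CA") for i, _ in pairs])
        mov_pts = np.array([mov.receptor[j].atom("CA") for _, j in pairs])
    tr = kabsch(mov_pts, ref_pts)
    moved = tr.apply(mov_pts)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_pts) ** 2, axis=1))))
    return tr, _transform_complex(mov, tr), rmsd


def _align_receptor_residues(
    ref: Sequence[ResidueRecord], mov: Sequence[ResidueRecord]
) -> list[tuple[int, int]]:
    """Index pairs of equivalent residues from a global sequence alignment."""
    seq_a = "".join(r.name1 for r in ref)
    seq_b = "".join(r.name1 for r in mov)
    pairs = align_positions(seq_a, seq_b)
    return [
        (i, j) for (i, j) in pairs
        if ref[i].atom("CA") is not None and mov[j].atom("CA") is not None
    ]


# --- peptide comparison --------------------------------------------------

def align_positions(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """0-based equivalent-position pairs from a global pairwise alignment.

    Needleman-Wunsch with BLOSUM62, gap open -10 / extend -1; 'X' and other
    nonstandard letters are aligned with a neutral score.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    clean_a = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in seq_a.upper())
    clean_b = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in seq_b.upper())
    aln = aligner.align(clean_a, clean_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend((a_start + off, b_start + off) for off in range(a_end - a_start))
    return pairs


def peptide_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned letters over the shorter peptide length."""
    if not seq_a or not seq_b:
        raise ValueError("peptide sequences must be non-empty")
    pairs = align_positions(seq_a, seq_b)
    matches = sum(1 for (i, j) in pairs if seq_a[i].upper() == seq_b[j].upper())
    return matches / min(len(seq_a), len(seq_b))


def peptide_rmsd(
    pep_a: Sequence[ResidueRecord],
    pep_b: Sequence[ResidueRecord],
    equivalences: Sequence[tuple[int, int]],
) -> float:
    """C-alpha RMSD over equivalent peptide positions (no re-fitting).

    Both peptides must already be in the common frame set by the receptor
    superposition. Pairs lacking a C-alpha on either side are dropped with a
    warning; if every pair is dropped, raises.
    """
    if not equivalences:
        raise ValueError("need at least one equivalence pair")
    sq = []
    for (ia, ib) in equivalences:
        ca_a = pep_a[ia].atom("CA")
        ca_b = pep_b[ib].atom("CA")
        if ca_a is None or ca_b is None:
            logger.warning("equivalence (%d,%d) lacks a C-alpha; dropped", ia, ib)
            continue
        sq.append(float(np.sum((ca_a - ca_b) ** 2)))
    if not sq:
        raise ValueError("no equivalence pair has C-alpha atoms on both sides")
    return math.sqrt(sum(sq) / len(sq))


def compare_pair(
    template: TemplateComplex, target: TemplateComplex
) -> tuple[float, str, float]:
    """(peptide RMSD, RMSD class, peptide identity) for a receptor-sharing pair."""
    _, moved, _ = superpose_receptors(template, target)
    equivalences = align_positions(template.peptide_seq, target.peptide_seq)
    rmsd = peptide_rmsd(template.peptide, moved.peptide, equivalences)
    identity = peptide_identity(template.peptide_seq, target.peptide_seq)
    return rmsd, classify_rmsd(rmsd), identity


RMSD_CLASS_BOUNDS = (1.5, 3.0)


def classify_rmsd(rmsd: float) -> str:
    """Bin an RMSD into L [0,1.5), M [1.5,3.0), H [3.0,inf)."""
    if rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    low, high = RMSD_CLASS_BOUNDS
    if rmsd < low:
        return "L"
    if rmsd < high:
        return "M"
    return "H"


# --- benchmark pair filtering --------------------------------------------

@dataclass(frozen=True)
class ComplexEntry:
    """One protein-peptide complex in a benchmark pair."""

    pdb_id: str
    receptor_chains: tuple[str, ...]
    peptide_chain: str
    peptide_seq: str
    binding_site: frozenset = frozenset()  # receptor residue keys in contact


@dataclass(frozen=True)
class BenchmarkPair:
    """Template/target complexes sharing a receptor."""

    template_entry: ComplexEntry
    target_entry: ComplexEntry
    receptor_id: str
    seq_identity: float
    peptide_rmsd: float | None = None
    rmsd_class: str | None = None


@dataclass(frozen=True)
class PairFilterConfig:
    min_len: int = 4
    max_len: int = 14
    max_identity: float = 0.80
    min_length_ratio: float = 0.6  # strictly greater than
    min_site_jaccard: float = 0.5  # binding sites deemed "the same"


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def pair_passes_filters(pair: BenchmarkPair, cfg: PairFilterConfig = PairFilterConfig()) -> bool:
    la = len(pair.template_entry.peptide_seq)
    lb = len(pair.target_entry.peptide_seq)
    if not (cfg.min_len <= la <= cfg.max_len and cfg.min_len <= lb <= cfg.max_len):
        return False
    if pair.seq_identity > cfg.max_identity:
        return False
    if min(la, lb) / max(la, lb) <= cfg.min_length_ratio:
        return False
    if _jaccard(pair.template_entry.binding_site,
                pair.target_entry.binding_site) < cfg.min_site_jaccard:
        return False
    return True


def apply_pair_filters(
    candidate_pairs: Sequence[BenchmarkPair],
    max_per_receptor: int = 5,
    seed: int = 0,
    config: PairFilterConfig = PairFilterConfig(),
) -> list[BenchmarkPair]:
    """Keep pairs passing all filters, then cap pairs per receptor.

    Filters: peptide lengths in [4, 14]; identity <= 0.80; shorter/longer
    length ratio strictly > 0.6; binding-site Jaccard overlap >= 0.5. The cap
    is a seeded uniform subsample per receptor; candidates are sorted before
    sampling so the output does not depend on input order.
    """
    kept = [p for p in candidate_pairs if pair_passes_filters(p, config)]
    kept.sort(key=lambda p: (p.receptor_id, p.template_entry.pdb_id,
                             p.target_entry.pdb_id, p.template_entry.peptide_seq,
                             p.target_entry.peptide_seq))
    by_receptor: dict[str, list[BenchmarkPair]] = {}
    for p in kept:
        by_receptor.setdefault(p.receptor_id, []).append(p)
    rng = np.random.default_rng(seed)
    out: list[BenchmarkPair] = []
    for rid in sorted(by_receptor):
        group = by_receptor[rid]
        if len(group) > max_per_receptor:
            idx = sorted(rng.choice(len(group), size=max_per_receptor, replace=False))
            group = [group[i] for i in idx]
        out.extend(group)
    return out


# --- rank metrics --------------------------------------------------------

def topn_accuracy(ranks: Sequence[int | None], n: int) -> tuple[float, str]:
    """Fraction of cases whose true binder rank is <= n.

    A None rank means the true binder was absent from the query's fragments;
    it counts as a failure.
    """
    if not ranks:
        raise ValueError("no cases")
    hits = 0
    for r in ranks:
        if r is None:
            logger.warning("true binder absent from query; counted as failure")
        elif r <= n:
            hits += 1
    return hits / len(ranks), f"{hits}/{len(ranks)}"


@dataclass(frozen=True)
class RankChangeSummary:
    n_total: int
    n_improved: int
    avg_rank_change: float  # positive = improvement (toward rank 1)
    avg_positive_change: float  # mean change over improved cases only
    top10_after: int
    top25_after: int


def rank_change_summary(
    seq_ranks: Sequence[int],
    structure_ranks: Sequence[int],
    exclude_top: int = 25,
) -> RankChangeSummary:
    """Summary of rank movement from the sequence to the structure stage.

    Cases whose sequence rank is already <= ``exclude_top`` are removed before
    summarizing, so the statistics describe what the rerank adds for the
    cases the sequence stage missed. Change = seq_rank - structure_rank;
    positive means the binder moved toward rank 1.
    """
    if len(seq_ranks) != len(structure_ranks):
        raise ValueError("rank lists have different lengths")
    pairs = [(s, t) for s, t in zip(seq_ranks, structure_ranks) if s > exclude_top]
    if not pairs:
        return RankChangeSummary(0, 0, 0.0, 0.0, 0, 0)
    changes = [s - t for s, t in pairs]
    improved = [c for c in changes if c > 0]
    return RankChangeSummary(
        n_total=len(pairs),
        n_improved=len(improved),
        avg_rank_change=float(np.mean(changes)),
        avg_positive_change=float(np.mean(improved)) if improved else 0.0,
        top10_after=sum(1 for _, t in pairs if t <= 10),
        top25_after=sum(1 for _, t in pairs if t <= 25),
    )


def hydrophobicity_index(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy over the peptide's residues."""
    values = [KYTE_DOOLITTLE[c] for c in seq.upper() if c in KYTE_DOOLITTLE]
    if not values:
        raise ValueError(f"no standard residues in peptide {seq!r}")
    return float(np.mean(values))


def hydrophobicity_rank_correlation(
    peptide_seqs: Sequence[str], ranks: Sequence[float]
) -> float:
    """Pearson r between mean peptide hydropathy and rank; NaN if undefined."""
    if len(peptide_seqs) != len(ranks) or len(peptide_seqs) < 3:
        raise ValueError("need >= 3 peptides with matching ranks")
    idx = [hydrophobicity_index(s) for s in peptide_seqs]
    if np.std(idx) == 0 or np.std(ranks) == 0:
        logger.warning("zero variance: hydrophobicity-rank correlation undefined")
        return math.nan
    r, _ = stats.pearsonr(idx, np.asarray(ranks, dtype=float))
    return float(r)


def best_binder_rank(hits, binder_seq: str) -> int | None:
    """Best sequence-stage rank among fragments exactly matching the binder."""
    ranks = [h.rank for h in hits if h.fragment.sequence == binder_seq.upper()]
    return min(ranks) if ranks else None
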