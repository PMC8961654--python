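"""Synthetic complexes, planted-binder queries and benchmark pairs.

These generators make every pipeline stage testable without any structure
downloads. Geometry is deliberately schematic (compact residue "blobs" on a
regular layout, no Ramachandran validity): what is guaranteed, by
construction, is the contact structure — planned receptor-peptide pairs sit
within 4.0 A (minimum heavy-atom distance) and every unplanned pair is kept
beyond 6.5 A, margins that straddle the 5.0 A contact predicate robustly
even under the graft backend's coordinate jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pepspot.constants import STANDARD_AA
from pepspot.modeling import AA3
from pepspot.structio import ResidueRecord, write_pdb

# Layout constants (Angstrom).
_SPACING = 10.0       # center-to-center spacing along each chain
_FAR_Y = 20.0         # y-offset of non-contacting receptor residues
_CONTACT_R = 2.5      # center distance of a planned contact
_MAX_ATOM_OFF = 0.6   # max atom offset from the residue center

# Atom offsets from the residue center; all within _MAX_ATOM_OFF.
_ATOM_OFFSETS = (
    ("N", (-0.6, 0.0, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (0.6, 0.0, 0.0)),
    ("O", (0.3, 0.5, 0.0)),
    ("CB", (0.0, -0.3, 0.5)),
)


class InfeasibleContactPlan(ValueError):
    """The requested contact plan cannot be realized with the layout guarantees."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a synthetic receptor-peptide complex.

    ``contact_plan`` lists (receptor_index, peptide_position) pairs (0-based)
    to be placed within contact range; all other receptor residues stay far
    from every peptide residue.
    """

    receptor_seq: str
    peptide_seq: str
    contact_plan: tuple[tuple[int, int], ...] = ()
    seed: int = 0


def _residue(chain_id: str, seq_num: int, letter: str, center: np.ndarray,
             rng: np.random.Generator) -> ResidueRecord:
    atoms = []
    for name, off in _ATOM_OFFSETS:
        if name == "CB" and letter == "G":
            continue
        jitter = rng.uniform(-0.05, 0.05, size=3)
        pos = center + np.asarray(off) + jitter
        atoms.append((name, round(float(pos[0]), 3), round(float(pos[1]), 3),
                      round(float(pos[2]), 3)))
    return ResidueRecord(chain_id, seq_num, "", AA3.get(letter, "UNK"), letter,
                         tuple(atoms))


def build_toy_residues(
    spec: ToyComplexSpec,
) -> tuple[list[ResidueRecord], list[ResidueRecord]]:
    """Receptor and peptide residue lists realizing the contact plan."""
    n_rec, n_pep = len(spec.receptor_seq), len(spec.peptide_seq)
    if n_rec < 2 or n_pep < 2:
        raise ValueError("receptor and peptide sequences must have length >= 2")
    seen: dict[int, int] = {}
    for (r, j) in spec.contact_plan:
        if not (0 <= r < n_rec and 0 <= j < n_pep):
            raise ValueError(f"contact plan index ({r},{j}) out of range")
        if r in seen and seen[r] != j:
            raise InfeasibleContactPlan(
                f"receptor residue {r} planned against peptide positions "
                f"{seen[r]} and {j}: cannot satisfy both the 4.0 A contact and "
                "the 6.5 A separation from all other peptide residues")
        seen[r] = j

    rng = np.random.default_rng(spec.seed)
    # Peptide along the x axis at y = z = 0.
    pep_centers = [np.array([_SPACING * j, 0.0, 0.0]) for j in range(n_pep)]
    # Receptor on a parallel far row by default; planned contacts move the
    # residue onto a ring of radius _CONTACT_R around its peptide partner.
    per_position_count: dict[int, int] = {}
    rec_centers = []
    for r in range(n_rec):
        if r in seen:
            j = seen[r]
            i = per_position_count.get(j, 0)
            per_position_count[j] = i + 1
            theta = 0.5 + 1.7 * i  # distinct ring slots per contacting residue
            rec_centers.append(
                pep_centers[j]
                + _CONTACT_R * np.array([0.0, np.cos(theta), np.sin(theta)])
            )
        else:
            rec_centers.append(np.array([_SPACING * r, _FAR_Y, 0.0]))

    receptor = [
        _residue("A", r + 1, spec.receptor_seq[r], rec_centers[r], rng)
        for r in range(n_rec)
    ]
    peptide = [
        _residue("B", j + 1, spec.peptide_seq[j], pep_centers[j], rng)
        for j in range(n_pep)
    ]
    return receptor, peptide


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """PDB text of a synthetic complex (receptor chain A, peptide chain B)."""
    receptor, peptide = build_toy_residues(spec)
    return write_pdb([("A", receptor), ("B", peptide)])


def make_planted_query(
    binder_seq: str,
    total_length: int,
    seed: int = 0,
    mutate_positions: int = 0,
) -> tuple[str, int]:
    """Random background sequence with the binder planted at a known offset.

    Returns (sequence, 1-based start of the planted binder). With
    ``mutate_positions`` > 0 that many distinct binder positions are mutated
    to a different residue before planting.
    """
    binder_seq = binder_seq.upper()
    if total_length < len(binder_seq) + 2:
        raise ValueError("total_length must be at least binder length + 2")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    planted = list(binder_seq)
    if mutate_positions:
        sites = rng.choice(len(planted), size=mutate_positions, replace=False)
        for s in sites:
            choices = [c for c in STANDARD_AA if c != planted[s]]
            planted[s] = choices[rng.integers(len(choices))]
    background_len = total_length - len(binder_seq)
    background = "".join(rng.choice(letters, size=background_len))
    offset = int(rng.integers(0, background_len + 1))
    seq = background[:offset] + "".join(planted) + background[offset:]
    return seq, offset + 1


def make_benchmark_pair(
    spec_template: ToyComplexSpec,
    target_peptide_seq: str,
    displacement: float,
) -> tuple[str, str]:
    """Template and target PDB texts sharing a receptor.

    The target peptide backbone equals the template peptide backbone
    translated by ``displacement`` Angstrom along +z and relabeled to
    ``target_peptide_seq`` (left-anchored; must not exceed the template
    peptide length). After receptor superposition, the peptide C-alpha RMSD
    over aligned positions equals the displacement by construction.
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    target_peptide_seq = target_peptide_seq.upper()
    receptor, peptide = build_toy_residues(spec_template)
    if len(target_peptide_seq) > len(peptide):
        raise ValueError("target peptide longer than the template peptide")
    shift = np.array([0.0, 0.0, displacement])
    target_peptide = []
    for j, letter in enumerate(target_peptide_seq):
        src = peptide[j]
        atoms = tuple(
            (name,
             round(x + shift[0], 3),
             round(y + shift[1], 3),
             round(z + shift[2], 3))
            for (name, x, y, z) in src.heavy_atoms
            if not (name == "CB" and letter == "G")
        )
        target_peptide.append(
            ResidueRecord(src.chain_id, src.seq_num, src.icode,
                          AA3.get(letter, "UNK"), letter, atoms)
        )
    template_pdb = write_pdb([("A", receptor), ("B", peptide)])
    target_pdb = write_pdb([("A", receptor), ("B", target_peptide)])
    return template_pdb, target_pdb
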