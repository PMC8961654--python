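"""Structure input and interface-contact bookkeeping.

Reads a receptor-peptide complex from PDB, keeps heavy-atom coordinates per
residue, and computes the interface contact structure that the threading score
consumes: for every template-peptide position j, ``n_inter[j]`` counts the
hydrophobic or ionic receptor residues whose minimum heavy-atom distance to
that peptide residue is within the contact threshold (5.0 A by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from pepspot.constants import CONTACT_THRESHOLD, HYDROPHOBIC, IONIC

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or inconsistent user input (bad chain id, bad sequence...)."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue with its heavy-atom coordinates.

    ``heavy_atoms`` excludes hydrogens and is never empty; ``name1`` is one of
    the 20 standard letters or 'X' for residues without a standard parent.
    """

    chain_id: str
    seq_num: int
    icode: str
    name3: str
    name1: str
    heavy_atoms: tuple[tuple[str, float, float, float], ...]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1:] for a in self.heavy_atoms], dtype=float)

    def atom(self, name: str) -> np.ndarray | None:
        for a in self.heavy_atoms:
            if a[0] == name:
                return np.array(a[1:], dtype=float)
        return None

    def with_coords(self, coords: np.ndarray) -> "ResidueRecord":
        atoms = tuple(
            (a[0], float(x), float(y), float(z))
            for a, (x, y, z) in zip(self.heavy_atoms, coords)
        )
        return ResidueRecord(self.chain_id, self.seq_num, self.icode, self.name3, self.name1, atoms)


@dataclass(frozen=True)
class ContactMap:
    """Set of (receptor_residue_index, peptide_position) contact pairs.

    Indices are 0-based positions into the receptor / peptide residue lists.
    """

    entries: frozenset[tuple[int, int]]
    threshold: float = CONTACT_THRESHOLD

    def receptor_partners(self, j: int) -> set[int]:
        return {r for (r, jj) in self.entries if jj == j}

    def receptor_residues(self) -> set[int]:
        """All receptor residue indices involved in at least one contact."""
        return {r for (r, _) in self.entries}


@dataclass(frozen=True)
class TemplateComplex:
    """Receptor + bound template peptide with per-position interface counts."""

    receptor: tuple[ResidueRecord, ...]
    peptide: tuple[ResidueRecord, ...]
    n_inter: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.peptide) != len(self.n_inter):
            raise ValueError("n_inter length must equal peptide length")

    @property
    def k(self) -> int:
        return len(self.peptide)

    @property
    def peptide_seq(self) -> str:
        return "".join(r.name1 for r in self.peptide)

    @property
    def receptor_seq(self) -> str:
        return "".join(r.name1 for r in self.receptor)


def one_letter(name3: str) -> str:
    """Map a three-letter residue name to a standard one-letter code or 'X'.

    Nonstandard residues with a tabulated standard parent (MSE -> M, ...) map
    to the parent letter.
    """
    info = gemmi.find_tabulated_residue(name3.strip().upper())
    if info is None or not info.is_amino_acid():
        return "X"
    letter = info.one_letter_code.upper()
    return letter if letter in "ACDEFGHIKLMNPQRSTVWY" else "X"


def _residues_from_chain(chain: gemmi.Chain) -> list[ResidueRecord]:
    out: list[ResidueRecord] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue  # waters, ligands, nucleotides
        # Altloc: keep the highest-occupancy conformer per atom name,
        # ties broken toward blank/'A'.
        best: dict[str, tuple[float, str, gemmi.Atom]] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            alt = atom.altloc or ""
            key = (atom.occ, "" if alt in ("", "A") else alt)
            prev = best.get(atom.name)
            # prefer higher occupancy; on ties prefer blank/'A'
            if prev is None or key[0] > prev[0] or (key[0] == prev[0] and key[1] < prev[1]):
                best[atom.name] = (key[0], key[1], atom)
        if not best:
            logger.warning(
                "residue %s %s%s has no heavy atoms; skipped",
                res.name, chain.name, res.seqid.num,
            )
            continue
        atoms = tuple(
            (name, a.pos.x, a.pos.y, a.pos.z)
            for name, (_, _, a) in sorted(best.items(), key=lambda kv: kv[1][2].serial)
        )
        out.append(
            ResidueRecord(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name3=res.name,
                name1=one_letter(res.name),
                heavy_atoms=atoms,
            )
        )
    return out


def parse_pdb(pdb_source: str | Path) -> gemmi.Structure:
    """Parse PDB text or a path to a PDB file; first model only."""
    if isinstance(pdb_source, Path) or (
        isinstance(pdb_source, str) and "\n" not in pdb_source and Path(pdb_source).exists()
    ):
        structure = gemmi.read_pdb(str(pdb_source))
    else:
        structure = gemmi.read_pdb_string(str(pdb_source))
    if len(structure) == 0:
        raise InputError("PDB source contains no models")
    return structure


def load_chain(pdb_source: str | Path, chain_id: str) -> list[ResidueRecord]:
    """Amino-acid residues of one chain (first model, heavy atoms only)."""
    structure = parse_pdb(pdb_source)
    model = structure[0]
    for chain in model:
        if chain.name == chain_id:
            return _residues_from_chain(chain)
    raise InputError(f"chain '{chain_id}' not found in PDB (have: "
                     f"{', '.join(c.name for c in model)})")


MAX_PEPTIDE_LEN = 50


def load_complex(
    pdb_source: str | Path,
    receptor_chains: Sequence[str],
    peptide_chain: str,
    threshold: float = CONTACT_THRESHOLD,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC,
    ionic_set: frozenset[str] = IONIC,
    contact_min_pairs: int = 1,
) -> TemplateComplex:
    """Assemble a template complex from a PDB file or PDB text.

    ``receptor_chains`` may name several chains; their residues are
    concatenated in the given order. HETATM-only residues without a standard
    amino-acid parent are dropped; the first model is used; per atom the
    highest-occupancy altloc wins.
    """
    structure = parse_pdb(pdb_source)
    model = structure[0]
    chains = {c.name: c for c in model}

    receptor: list[ResidueRecord] = []
    for cid in receptor_chains:
        if cid not in chains:
            raise InputError(f"receptor chain '{cid}' not found in PDB (have: "
                             f"{', '.join(chains)})")
        receptor.extend(_residues_from_chain(chains[cid]))
    if peptide_chain not in chains:
        raise InputError(f"peptide chain '{peptide_chain}' not found in PDB (have: "
                         f"{', '.join(chains)})")
    peptide = _residues_from_chain(chains[peptide_chain])
    if len(peptide) < 2:
        raise InputError(
            f"peptide chain '{peptide_chain}' has fewer than 2 residues with resolved heavy atoms"
        )
    if len(peptide) > MAX_PEPTIDE_LEN:
        raise InputError(
            f"peptide chain '{peptide_chain}' has {len(peptide)} residues: "
            "peptide chain too long, did you swap receptor/peptide?"
        )

    contacts = residue_contacts(receptor, peptide, threshold, min_pairs=contact_min_pairs)
    n_inter = count_n_inter(contacts, receptor, hydrophobic_set, ionic_set,
                            peptide_len=len(peptide))
    return TemplateComplex(tuple(receptor), tuple(peptide), tuple(n_inter))


def residue_contacts(
    receptor: Sequence[ResidueRecord],
    peptide: Sequence[ResidueRecord],
    threshold: float = CONTACT_THRESHOLD,
    min_pairs: int = 1,
) -> ContactMap:
    """Residue-pair contact map at a heavy-atom distance threshold.

    A receptor residue r and peptide position j are in contact when at least
    ``min_pairs`` heavy-atom pairs (one atom from each residue) lie within
    ``threshold`` Angstrom. The default ``min_pairs=1`` makes the predicate
    "minimum inter-residue heavy-atom distance <= threshold".
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    entries: set[tuple[int, int]] = set()
    pep_coords: list[np.ndarray | None] = []
    for j, res in enumerate(peptide):
        if len(res.heavy_atoms) == 0:
            logger.warning("peptide position %d has no heavy atoms; skipped", j + 1)
            pep_coords.append(None)
        else:
            pep_coords.append(res.coords)
    for r, rres in enumerate(receptor):
        if len(rres.heavy_atoms) == 0:
            logger.warning("receptor residue index %d has no heavy atoms; skipped", r)
            continue
        rc = rres.coords
        for j, pc in enumerate(pep_coords):
            if pc is None:
                continue
            d = cdist(rc, pc)
            if np.count_nonzero(d <= threshold) >= min_pairs:
                entries.add((r, j))
    return ContactMap(frozenset(entries), threshold)


def count_n_inter(
    contacts: ContactMap,
    receptor: Sequence[ResidueRecord],
    hydrophobic_set: Iterable[str] = HYDROPHOBIC,
    ionic_set: Iterable[str] = IONIC,
    peptide_len: int | None = None,
) -> list[int]:
    """Per-peptide-position count of contacting hydrophobic/ionic receptor residues.

    Receptor residues outside both classes contribute nothing even when in
    contact. ``peptide_len`` fixes the output length; defaults to 1 + the
    largest peptide index present in the map (0 for an empty map).
    """
    hset, iset = frozenset(hydrophobic_set), frozenset(ionic_set)
    if hset & iset:
        raise ValueError(f"hydrophobic and ionic sets overlap: {sorted(hset & iset)}")
    if peptide_len is None:
        peptide_len = (max((j for (_, j) in contacts.entries), default=-1)) + 1
    counts = [0] * peptide_len
    relevant = hset | iset
    for (r, j) in contacts.entries:
        if receptor[r].name1 in relevant:
            counts[j] += 1
    return counts


# --- PDB / FASTA writing -------------------------------------------------

def format_atom_record(
    serial: int,
    atom_name: str,
    res_name3: str,
    chain_id: str,
    seq_num: int,
    x: float,
    y: float,
    z: float,
    icode: str = "",
    element: str | None = None,
) -> str:
    """One fixed-width ATOM record (PDB v3.3 columns)."""
    if element is None:
        element = atom_name.strip()[0]
    name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else atom_name
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{'':1s}{res_name3:>3s} {chain_id:1s}"
        f"{seq_num:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(chains: Sequence[tuple[str, Sequence[ResidueRecord]]]) -> str:
    """Serialize residue lists to PDB text (ATOM/TER/END records)."""
    lines: list[str] = []
    serial = 1
    for chain_id, residues in chains:
        for res in residues:
            for (name, x, y, z) in res.heavy_atoms:
                lines.append(
                    format_atom_record(serial, name, res.name3, chain_id,
                                       res.seq_num, x, y, z, res.icode)
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file, in file order."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records
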