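"""Decoy building and structure-based reranking.

Top sequence-stage hits are turned into 3D receptor-fragment complexes and
rescored with a structure-based potential; the rerank orders them by their
best (lowest) decoy energy. Decoy building and scoring both sit behind
registries so that external engines (a comparative-modeling backend, SOAP /
DOPE / VoroMQA potentials) plug in as adapters with the same signatures.

The built-in "graft" backend copies the template peptide backbone (N, CA, C,
O) and CB positions onto the fragment, relabels residue identities, and
optionally jitters atoms with Gaussian noise. The built-in
"contact-potential" scorer is a coarse residue-class pair potential
(hydrophobic-hydrophobic and opposite-charge contacts favorable, like-charge
contacts penalized); it is a deliberately simple stand-in at the same
interface as the external statistical potentials.
"""

from __future__ import annotations

import logging
import math
import re
import shutil
import subprocess
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from pepspot.constants import CONTACT_THRESHOLD, HYDROPHOBIC, NEGATIVE, POSITIVE
from pepspot.structio import ContactMap, ResidueRecord, TemplateComplex, residue_contacts
from pepspot.threading import PeptideFragment, SequenceHit

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


class ConfigError(ValueError):
    """Unknown backend/scorer name."""


class AdapterUnavailableError(RuntimeError):
    """An external engine adapter was requested but its tool is not present."""


class ScorerParseError(RuntimeError):
    """External scorer produced output the adapter could not parse."""

    def __init__(self, message: str, raw_output: str):
        super().__init__(f"{message}\n--- raw tool output ---\n{raw_output}")
        self.raw_output = raw_output


@dataclass(frozen=True)
class ComplexModel:
    """One receptor-fragment decoy."""

    receptor: tuple[ResidueRecord, ...]
    peptide: tuple[ResidueRecord, ...]
    fragment: PeptideFragment
    backend: str
    decoy_index: int
    seed: int

    @property
    def peptide_seq(self) -> str:
        return "".join(r.name1 for r in self.peptide)


@dataclass(frozen=True)
class StructureHit:
    """A sequence hit carried through the structure stage.

    ``rerank`` is None for hits outside the reranked top-T window or left
    unscored after a backend/scorer failure.
    """

    fragment: PeptideFragment
    seq_rank: int
    decoy_scores: dict[str, tuple[float, ...]] = field(default_factory=dict)
    best_score: float = math.nan
    rerank: int | None = None
    unscored: bool = False


# --- decoy backends ------------------------------------------------------

def _graft_backend(
    tpl: TemplateComplex,
    fragment: PeptideFragment,
    n_decoys: int,
    seed: int,
    sigma: float = 0.2,
) -> list[ComplexModel]:
    """Copy template peptide backbone+CB, relabel to the fragment sequence.

    The fragment is left-anchored on the template; a fragment of length m < k
    occupies template positions 1..m. Per decoy, atoms are jittered with
    isotropic Gaussian noise of width ``sigma`` (Angstrom), seeded
    deterministically per (seed, decoy_index); sigma=0 reproduces the
    template geometry exactly.
    """
    if len(fragment) > tpl.k:
        raise ValueError("fragment longer than template peptide")
    models = []
    for d in range(n_decoys):
        rng = np.random.default_rng(np.random.SeedSequence((seed, d)))
        peptide: list[ResidueRecord] = []
        for j, letter in enumerate(fragment.sequence):
            src = tpl.peptide[j]
            atoms = []
            for (name, x, y, z) in src.heavy_atoms:
                if name not in BACKBONE_ATOMS:
                    continue
                if name == "CB" and letter == "G":
                    continue  # glycine has no beta carbon
                atoms.append((name, x, y, z))
            if not atoms:
                raise ValueError(
                    f"template peptide position {j + 1} has no backbone atoms to graft")
            coords = np.array([a[1:] for a in atoms], dtype=float)
            if sigma > 0:
                coords = coords + rng.normal(0.0, sigma, size=coords.shape)
            atoms = [
                (a[0], float(cx), float(cy), float(cz))
                for a, (cx, cy, cz) in zip(atoms, coords)
            ]
            peptide.append(
                ResidueRecord(
                    chain_id=src.chain_id,
                    seq_num=src.seq_num,
                    icode=src.icode,
                    name3=AA3.get(letter, "UNK"),
                    name1=letter,
                    heavy_atoms=tuple(atoms),
                )
            )
        models.append(
            ComplexModel(
                receptor=tpl.receptor,
                peptide=tuple(peptide),
                fragment=fragment,
                backend="graft",
                decoy_index=d,
                seed=seed,
            )
        )
    return models


class ModellerBackend:
    """Adapter slot for a comparative-modeling engine.

    Raises :class:`AdapterUnavailableError` unless the engine's Python
    package is importable; never falls back silently.
    """

    name = "modeller"

    def __call__(self, tpl, fragment, n_decoys, seed, sigma=None):
        try:
            import modeller  # noqa: F401
        except ImportError:
            raise AdapterUnavailableError(
                "adapter unavailable: comparative-modeling backend 'modeller' "
                "requires the 'modeller' Python package"
            ) from None
        raise NotImplementedError("modeller adapter requires a licensed engine")


BACKENDS: dict[str, Callable[..., list[ComplexModel]]] = {
    "graft": _graft_backend,
    "modeller": ModellerBackend(),
}


def build_models(
    tpl: TemplateComplex,
    fragment: PeptideFragment,
    n_decoys: int,
    backend: str = "graft",
    seed: int = 0,
    sigma: float = 0.2,
) -> list[ComplexModel]:
    """Build ``n_decoys`` 3D decoys of the receptor-fragment complex."""
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    if backend not in BACKENDS:
        raise ConfigError(
            f"unknown backend '{backend}'; available: {sorted(BACKENDS)}")
    return BACKENDS[backend](tpl, fragment, n_decoys, seed, sigma=sigma)


# --- scorers -------------------------------------------------------------

def _residue_class(letter: str) -> str | None:
    if letter in HYDROPHOBIC:
        return "hydrophobic"
    if letter in NEGATIVE:
        return "negative"
    if letter in POSITIVE:
        return "positive"
    return None


def pair_weight(class_r: str | None, class_p: str | None) -> float:
    """Residue-class contact weight: lower = more favorable."""
    if class_r is None or class_p is None:
        return 0.0
    if class_r == "hydrophobic" and class_p == "hydrophobic":
        return -1.0
    ionic = {"negative", "positive"}
    if class_r in ionic and class_p in ionic:
        return -1.0 if class_r != class_p else +1.0
    return 0.0


def contact_potential(model: ComplexModel, threshold: float = CONTACT_THRESHOLD) -> float:
    """Sum of residue-class pair weights over receptor-peptide contacts."""
    contacts = residue_contacts(model.receptor, model.peptide, threshold)
    total = 0.0
    for (r, j) in contacts.entries:
        total += pair_weight(
            _residue_class(model.receptor[r].name1),
            _residue_class(model.peptide[j].name1),
        )
    return total


@dataclass
class ExternalScorerAdapter:
    """Shell out to an external statistical-potential tool and parse a float.

    The adapter writes the model to a temporary PDB file, substitutes it into
    ``args_template`` (``{pdb}`` placeholder), and extracts the first group of
    ``parse_regex`` from stdout. Missing executable -> AdapterUnavailableError;
    unparseable output -> ScorerParseError carrying the raw output. ``negate``
    flips the sign for tools where higher = better, so that lower is always
    better at this interface.
    """

    name: str
    executable: str
    args_template: tuple[str, ...] = ("{pdb}",)
    parse_regex: str = r"(-?\d+\.?\d*(?:[eE][+-]?\d+)?)"
    negate: bool = False

    def __call__(self, model: ComplexModel) -> float:
        import tempfile

        from pepspot.structio import write_pdb

        exe = shutil.which(self.executable)
        if exe is None:
            raise AdapterUnavailableError(
                f"adapter unavailable: scorer '{self.name}' requires executable "
                f"'{self.executable}' on PATH"
            )
        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
            fh.write(write_pdb([("A", model.receptor), ("B", model.peptide)]))
            pdb_path = fh.name
        args = [exe] + [a.format(pdb=pdb_path) for a in self.args_template]
        proc = subprocess.run(args, capture_output=True, text=True)
        out = proc.stdout + proc.stderr
        m = re.search(self.parse_regex, proc.stdout)
        if m is None:
            raise ScorerParseError(
                f"scorer '{self.name}' output did not match /{self.parse_regex}/", out)
        value = float(m.group(1))
        return -value if self.negate else value


SCORERS: dict[str, Callable[[ComplexModel], float]] = {
    "contact-potential": contact_potential,
    "soap-pep": ExternalScorerAdapter("soap-pep", "soap_pep_score"),
    "soap-ppi": ExternalScorerAdapter("soap-ppi", "soap_ppi_score"),
    "dope": ExternalScorerAdapter("dope", "dope_score"),
    "voromqa": ExternalScorerAdapter("voromqa", "voronota-voromqa", negate=True),
    "voromqa-interface": ExternalScorerAdapter(
        "voromqa-interface", "voronota-voromqa",
        args_template=("--score-inter-chain", "{pdb}"), negate=True),
}


def score_model(model: ComplexModel, scorer: str = "contact-potential") -> float:
    """Structure-based score of one decoy; lower = better for every scorer."""
    if scorer not in SCORERS:
        raise ConfigError(f"unknown scorer '{scorer}'; available: {sorted(SCORERS)}")
    return SCORERS[scorer](model)


# --- rerank --------------------------------------------------------------

def _score_one(tpl, hit, n_decoys, backend, scorer, seed_pair, sigma):
    """Build + score decoys for one hit; returns (scores tuple | None)."""
    seed = int(np.random.SeedSequence(seed_pair).generate_state(1)[0] % (2**31))
    try:
        models = build_models(tpl, hit.fragment, n_decoys, backend=backend,
                              seed=seed, sigma=sigma)
        return tuple(score_model(m, scorer) for m in models)
    except (AdapterUnavailableError, ConfigError):
        raise
    except Exception as exc:  # per-fragment failure -> unscored, ranked last
        logger.warning("fragment %s left unscored: %s", hit.fragment.sequence, exc)
        return None


def rerank_hits(
    hits: Sequence[SequenceHit],
    tpl: TemplateComplex,
    top_T: int = 25,
    n_decoys: int = 4,
    backend: str = "graft",
    scorer: str = "contact-potential",
    seed: int = 0,
    sigma: float = 0.2,
    jobs: int = 1,
) -> list[StructureHit]:
    """Structure-based rerank of the top-T sequence hits.

    Per fragment, ``n_decoys`` decoys are built and the best (minimum) decoy
    score represents it; reranked ascending best score with ties broken by
    prior sequence rank then start. Hits beyond top-T are returned with
    ``rerank=None``; fragments whose backend or scorer failed are marked
    unscored and ranked after all scored ones.
    """
    if top_T < 1:
        raise ValueError("top_T must be >= 1")
    ordered = sorted(hits, key=lambda h: h.rank)
    head, tail = ordered[:top_T], ordered[top_T:]

    tasks = [
        delayed(_score_one)(tpl, h, n_decoys, backend, scorer, (seed, i), sigma)
        for i, h in enumerate(head)
    ]
    if jobs == 1:
        score_lists = [t[0](*t[1], **t[2]) for t in tasks]
    else:
        score_lists = Parallel(n_jobs=jobs)(tasks)

    scored: list[StructureHit] = []
    for h, scores in zip(head, score_lists):
        if scores is None:
            scored.append(StructureHit(h.fragment, h.rank, {}, math.inf, None, True))
        else:
            scored.append(
                StructureHit(h.fragment, h.rank, {scorer: scores}, min(scores), None, False)
            )
    scored.sort(key=lambda sh: (sh.unscored, sh.best_score, sh.seq_rank, sh.fragment.start))
    result = [replace(sh, rerank=i + 1) for i, sh in enumerate(scored)]
    result.extend(StructureHit(h.fragment, h.rank) for h in tail)
    return result
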