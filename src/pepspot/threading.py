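"""Sequence-stage threading: fragmentation, interface-weighted scoring, ranking.

The query sequence is cut into k-mers by a sliding window and every fragment
is threaded position-by-position onto the template peptide. Each aligned pair
(query letter a at template position j carrying template letter b) scores

    raw:               B(a, b)
    galaxy / modified: (1 + n_inter[j] * Theta) * B(a, b)

where B is a substitution matrix, ``n_inter[j]`` is the number of hydrophobic
or ionic receptor residues contacting template-peptide position j, and Theta
gates the interface weight: in *galaxy* mode Theta = 1 only for B(a, b) > 0
(conserved pairs), in *modified* mode Theta = 1 always. The fragment score is
the sum over aligned positions; fragments are ranked by descending score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from pepspot.constants import STANDARD_AA
from pepspot.structio import InputError, TemplateComplex


class MatrixFormatError(ValueError):
    """Substitution-matrix file is asymmetric or incomplete."""


class MatrixMode(enum.Enum):
    """Interface-weight regime applied on top of the substitution matrix."""

    RAW = "raw"
    GALAXY = "galaxy"
    MODIFIED = "modified"

    @classmethod
    def coerce(cls, value: "MatrixMode | str") -> "MatrixMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown matrix mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair score lookup over the 20-letter alphabet.

    Letters outside the standard alphabet (including 'X') score 0 against
    everything, so unknown residues never dominate a ranking.
    """

    name: str
    scores: dict[tuple[str, str], float]

    def __call__(self, a: str, b: str) -> float:
        return self.scores.get((a, b), 0.0)

    def save(self, path: str | Path) -> None:
        letters = STANDARD_AA
        lines = ["   " + " ".join(f"{c:>5s}" for c in letters)]
        for a in letters:
            row = " ".join(f"{self.scores[(a, b)]:5.1f}" for b in letters)
            lines.append(f"{a:<3s}{row}")
        Path(path).write_text("\n".join(lines) + "\n")


def _builtin_blosum62() -> SubstitutionMatrix:
    from Bio.Align import substitution_matrices

    table = substitution_matrices.load("BLOSUM62")
    scores: dict[tuple[str, str], float] = {}
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            scores[(a, b)] = float(table[a, b])
    return SubstitutionMatrix("BLOSUM62", scores)


def load_matrix(name_or_path: str | Path) -> SubstitutionMatrix:
    """Built-in "BLOSUM62" or a whitespace-delimited square matrix file.

    The file format is a header row of one-letter codes followed by one row
    per letter (with or without a leading row label). Symmetry is validated
    to 1e-9 and all 20 standard letters must be covered.
    """
    if str(name_or_path).upper() == "BLOSUM62":
        return _builtin_blosum62()

    path = Path(name_or_path)
    if not path.exists():
        raise InputError(f"matrix '{name_or_path}' is not built-in and no such file exists")
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    letters = [c.upper() for c in header]
    if any(len(c) != 1 for c in letters):
        raise MatrixFormatError(f"header row must be one-letter codes, got {header!r}")
    missing = set(STANDARD_AA) - set(letters)
    if missing:
        raise MatrixFormatError(f"matrix does not cover letters {sorted(missing)}")

    scores: dict[tuple[str, str], float] = {}
    rows = lines[1:]
    if len(rows) < len(letters):
        raise MatrixFormatError(
            f"expected {len(letters)} data rows, found {len(rows)}")
    for i, ln in enumerate(rows[: len(letters)]):
        fields = ln.split()
        row_letter = letters[i]
        if len(fields) == len(letters) + 1:
            row_letter = fields[0].upper()
            fields = fields[1:]
        if len(fields) != len(letters):
            raise MatrixFormatError(
                f"row {i + 1} ('{row_letter}') has {len(fields)} values, "
                f"expected {len(letters)}")
        for j, f in enumerate(fields):
            try:
                scores[(row_letter, letters[j])] = float(f)
            except ValueError:
                raise MatrixFormatError(
                    f"cell ({row_letter},{letters[j]}) is not numeric: {f!r}") from None
    for a in letters:
        for b in letters:
            if abs(scores[(a, b)] - scores[(b, a)]) > 1e-9:
                raise MatrixFormatError(
                    f"matrix is asymmetric at cell ({a},{b}): "
                    f"{scores[(a, b)]} != {scores[(b, a)]}")
    scores = {(a, b): v for (a, b), v in scores.items()
              if a in STANDARD_AA and b in STANDARD_AA}
    return SubstitutionMatrix(path.stem, scores)


@dataclass(frozen=True)
class PeptideFragment:
    """A window of the query sequence; coordinates are 1-based inclusive."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceHit:
    fragment: PeptideFragment
    seq_score: float
    rank: int


def fragment_sequence(
    seq: str,
    k: int,
    source_id: str = "query",
    allow_short_tail: bool = True,
    min_len: int = 2,
) -> list[PeptideFragment]:
    """Sliding-window k-mers of the query sequence.

    With ``allow_short_tail`` (the default) a window starts at every position,
    C-terminal windows shrinking from k down to ``min_len``; a sequence of
    length L > k therefore yields exactly L - 1 fragments. Without it, only
    the L - k + 1 full-length windows are produced.
    """
    seq = seq.upper()
    bad = sorted({c for c in seq if not c.isalpha()})
    if bad:
        raise InputError(f"sequence contains non-letter characters: {bad}")
    L = len(seq)
    if L < min_len:
        raise InputError(f"sequence length {L} is below min_len={min_len}")
    if k < min_len:
        raise InputError(f"window length k={k} is below min_len={min_len}")
    fragments: list[PeptideFragment] = []
    for start in range(1, L + 1):  # 1-based
        length = min(k, L - start + 1)
        if length < min_len:
            break
        if not allow_short_tail and length < k:
            break
        fragments.append(
            PeptideFragment(source_id, start, start + length - 1,
                            seq[start - 1 : start - 1 + length])
        )
    return fragments


def eq1_score(
    B: SubstitutionMatrix,
    a: str,
    b: str,
    n_inter_j: int,
    mode: MatrixMode | str,
) -> float:
    """Interface-weighted substitution score for one aligned letter pair.

    raw -> B(a,b); galaxy/modified -> (1 + n_inter_j * Theta) * B(a,b), with
    Theta = [B(a,b) > 0] in galaxy mode and Theta = 1 in modified mode.
    """
    if n_inter_j < 0:
        raise ValueError("n_inter_j must be non-negative")
    mode = MatrixMode.coerce(mode)
    base = B(a, b)
    if mode is MatrixMode.RAW:
        return base
    if mode is MatrixMode.GALAXY:
        theta = 1 if base > 0 else 0
    else:  # MODIFIED
        theta = 1
    return (1 + n_inter_j * theta) * base


def score_fragment(
    fragment: PeptideFragment,
    tpl: TemplateComplex,
    B: SubstitutionMatrix,
    mode: MatrixMode | str,
    normalize: bool = False,
) -> float:
    """Threading score of a fragment against the template peptide.

    Fragments shorter than the template are left-anchored (position 1 aligns
    with template position 1); the alignment is ungapped.
    """
    if len(fragment) > tpl.k:
        raise ValueError(
            f"fragment length {len(fragment)} exceeds template peptide length {tpl.k}")
    mode = MatrixMode.coerce(mode)
    tpl_seq = tpl.peptide_seq
    total = 0.0
    for j, a in enumerate(fragment.sequence):
        total += eq1_score(B, a, tpl_seq[j], tpl.n_inter[j], mode)
    if normalize:
        total /= len(fragment)
    return total


def rank_fragments(
    fragments: Sequence[PeptideFragment],
    tpl: TemplateComplex,
    B: SubstitutionMatrix,
    mode: MatrixMode | str,
    normalize: bool = False,
) -> list[SequenceHit]:
    """Score every fragment and rank by descending score.

    Ties break by fragment start (earlier wins), then source id. Ranks are a
    permutation of 1..n with no sharing.
    """
    if not fragments:
        raise InputError("no fragments to rank")
    mode = MatrixMode.coerce(mode)
    scored = [
        (score_fragment(f, tpl, B, mode, normalize=normalize), f) for f in fragments
    ]
    scored.sort(key=lambda sf: (-sf[0], sf[1].start, sf[1].source_id))
    return [
        SequenceHit(fragment=f, seq_score=s, rank=i + 1)
        for i, (s, f) in enumerate(scored)
    ]


def hits_to_dataframe(
    hits: Sequence[SequenceHit], matrix_name: str, mode: MatrixMode | str
) -> pd.DataFrame:
    """Ranked hit table with the TSV column layout used by the CLI."""
    mode = MatrixMode.coerce(mode)
    return pd.DataFrame(
        {
            "rank": [h.rank for h in hits],
            "start": [h.fragment.start for h in hits],
            "end": [h.fragment.end for h in hits],
            "sequence": [h.fragment.sequence for h in hits],
            "seq_score": [h.seq_score for h in hits],
            "matrix": matrix_name,
            "mode": mode.value,
        }
    )
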