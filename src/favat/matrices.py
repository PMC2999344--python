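"""Residue substitution matrices.

Ships the canonical NCBI BLOSUM62 table (integer half-bit units) and reads
any matrix in the NCBI flat format used by BLAST: ``#``-prefixed comment
lines, a whitespace-separated header row of symbols, and one labelled score
row per symbol.

Gap symbols (``-`` and ``.``) are never part of a matrix alphabet; how gaps
score is a decision of the alignment and voting layers, not of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import MatrixError

#: Symbols accepted in protein sequences: the 20 standard amino acids plus
#: the ambiguity codes B, Z, X and the stop symbol '*'.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

GAP_CHARS = ("-", ".")

_BUILTINS = ("BLOSUM62",)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair score table.

    Parameters
    ----------
    name:
        Free-text label (e.g. ``"BLOSUM62"``).
    alphabet:
        Ordered residue symbols. Uppercase, no gap characters.
    scores:
        Square integer array, ``scores[i, j]`` being the score of
        ``alphabet[i]`` against ``alphabet[j]``. Must be symmetric.
    """

    name: str
    alphabet: str
    scores: np.ndarray
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores)
        n = len(self.alphabet)
        if arr.shape != (n, n):
            raise MatrixError(
                f"matrix {self.name!r}: score table is {arr.shape}, expected "
                f"({n}, {n}) for a {n}-symbol alphabet"
            )
        if not np.array_equal(arr, arr.T):
            bad = np.argwhere(arr != arr.T)[0]
            a, b = self.alphabet[bad[0]], self.alphabet[bad[1]]
            raise MatrixError(
                f"matrix {self.name!r} is asymmetric: "
                f"score({a},{b}) != score({b},{a})"
            )
        if len(set(self.alphabet)) != n:
            raise MatrixError(f"matrix {self.name!r}: duplicate alphabet symbols")
        for sym in self.alphabet:
            if sym in GAP_CHARS:
                raise MatrixError(
                    f"matrix {self.name!r}: gap symbol {sym!r} in alphabet"
                )
        object.__setattr__(self, "scores", arr)
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.alphabet)}
        )

    def score(self, a: str, b: str) -> int:
        """Return the (symmetric) score of residue ``a`` against ``b``.

        Symbols are uppercased before lookup; an unknown symbol raises
        :class:`MatrixError` naming it. Gap characters are deliberately not
        scorable here.
        """
        try:
            ia = self._index[a.upper()]
        except KeyError:
            raise MatrixError(
                f"symbol {a!r} is not in the {self.name} alphabet"
            ) from None
        try:
            ib = self._index[b.upper()]
        except KeyError:
            raise MatrixError(
                f"symbol {b!r} is not in the {self.name} alphabet"
            ) from None
        return int(self.scores[ia, ib])

    def index_of(self, symbol: str) -> int:
        """Position of ``symbol`` (uppercased) in the alphabet."""
        try:
            return self._index[symbol.upper()]
        except KeyError:
            raise MatrixError(
                f"symbol {symbol!r} is not in the {self.name} alphabet"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._index


def load_matrix(source: str | Path = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix.

    ``source`` is either the name of a built-in matrix (currently only
    ``"BLOSUM62"``) or a path to a file in NCBI flat layout.
    """
    if isinstance(source, str) and "/" not in source and "\\" not in source:
        if source.upper() in _BUILTINS:
            text = (
                resources.files("favat.data").joinpath(source.upper()).read_text()
            )
            return parse_ncbi_matrix(text, name=source.upper())
        if not Path(source).exists():
            raise MatrixError(
                f"unknown built-in matrix {source!r} "
                f"(built-ins: {', '.join(_BUILTINS)}) and no such file exists"
            )
    path = Path(source)
    try:
        text = path.read_text()
    except OSError as exc:
        raise MatrixError(f"cannot read matrix file {path}: {exc}") from exc
    return parse_ncbi_matrix(text, name=path.name)


def parse_ncbi_matrix(text: str, name: str = "matrix") -> SubstitutionMatrix:
    """Parse the NCBI flat matrix format into a validated matrix."""
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise MatrixError(f"matrix {name!r}: no content outside comments")
    header = lines[0].split()
    alphabet = "".join(s.upper() for s in header)
    for sym in header:
        if len(sym) != 1:
            raise MatrixError(
                f"matrix {name!r}: header symbol {sym!r} is not a single character"
            )
    n = len(alphabet)
    rows = lines[1:]
    if len(rows) != n:
        raise MatrixError(
            f"matrix {name!r} is not square: {n} header symbols but "
            f"{len(rows)} score rows"
        )
    scores = np.zeros((n, n), dtype=np.int64)
    seen: list[str] = []
    for row in rows:
        parts = row.split()
        label = parts[0].upper()
        if label not in alphabet:
            raise MatrixError(
                f"matrix {name!r}: row label {parts[0]!r} not in header"
            )
        if len(parts) - 1 != n:
            raise MatrixError(
                f"matrix {name!r}: row {label!r} has {len(parts) - 1} scores, "
                f"expected {n}"
            )
        try:
            values = [int(v) for v in parts[1:]]
        except ValueError as exc:
            raise MatrixError(
                f"matrix {name!r}: non-integer score in row {label!r}"
            ) from exc
        scores[alphabet.index(label), :] = values
        seen.append(label)
    if sorted(seen) != sorted(alphabet):
        raise MatrixError(f"matrix {name!r}: missing or duplicated score rows")
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=scores)


def write_ncbi_matrix(
    matrix: SubstitutionMatrix, path: str | Path, comments: Iterable[str] = ()
) -> None:
    """Write ``matrix`` in NCBI flat layout (round-trips bit-exactly)."""
    out = [f"# {c}" for c in comments]
    out.append("   " + "  ".join(matrix.alphabet))
    for i, a in enumerate(matrix.alphabet):
        out.append(
            a + " " + " ".join(f"{int(v):>2d}" for v in matrix.scores[i])
        )
    Path(path).write_text("\n".join(out) + "\n")
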