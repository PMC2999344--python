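"""Profiles: gapped multiple alignments of one sequence group.

A :class:`Profile` is the unit the three-way aligner works on — a fixed,
already-built multiple alignment of one property group (or a single target
sequence), carried with per-sequence weights. Group alignments are expected
to come from an external MSA tool; this package never re-aligns within a
group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ProfileError
from .matrices import GAP_CHARS, PROTEIN_ALPHABET

GAP = "-"

_LEGAL = set(PROTEIN_ALPHABET) | set(GAP_CHARS)


@dataclass(frozen=True)
class Profile:
    """An aligned group of sequences with per-sequence weights.

    ``sequences`` are uppercase gapped strings of identical length; ``'.'``
    gaps are normalized to ``'-'`` on construction. Weights are positive and
    aligned to sequences. ``label`` tags the group ("target", "A", "~A", ...).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    weights: tuple[float, ...]
    label: str = ""
    # Internal: alignment output inserts all-gap columns; ordinary profiles
    # must not contain any.
    allow_gap_columns: bool = False

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise ProfileError(f"profile {self.label!r}: no sequences")
        seqs = tuple(
            s.upper().replace(".", GAP) for s in self.sequences
        )
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "ids", tuple(self.ids))
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ProfileError(
                f"profile {self.label!r}: ragged alignment, record lengths "
                f"{sorted(lengths)}"
            )
        if len(self.ids) != len(seqs):
            raise ProfileError(
                f"profile {self.label!r}: {len(self.ids)} ids for "
                f"{len(seqs)} sequences"
            )
        for rid, s in zip(self.ids, seqs):
            bad = set(s) - _LEGAL
            if bad:
                raise ProfileError(
                    f"profile {self.label!r}, record {rid!r}: illegal "
                    f"character(s) {sorted(bad)}"
                )
        if self.length == 0:
            raise ProfileError(f"profile {self.label!r}: zero-length alignment")
        w = tuple(float(x) for x in self.weights)
        if len(w) != len(seqs):
            raise ProfileError(
                f"profile {self.label!r}: {len(w)} weights for {len(seqs)} sequences"
            )
        if any(x <= 0 for x in w):
            raise ProfileError(f"profile {self.label!r}: weights must be > 0")
        object.__setattr__(self, "weights", w)
        if not self.allow_gap_columns:
            for col in range(self.length):
                if all(s[col] == GAP for s in seqs):
                    raise ProfileError(
                        f"profile {self.label!r}: column {col + 1} is all gaps"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, index: int) -> list[str]:
        """Symbols of every sequence at 0-based column ``index``."""
        if not 0 <= index < self.length:
            raise ProfileError(
                f"profile {self.label!r}: column {index} out of range "
                f"[0, {self.length})"
            )
        return [s[index] for s in self.sequences]

    def ungapped(self) -> tuple[str, ...]:
        """The input sequences with all gap characters removed."""
        return tuple(s.replace(GAP, "") for s in self.sequences)


def make_profile(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    label: str = "",
    weights: Sequence[float] | None = None,
) -> Profile:
    """Convenience constructor with uniform (1/m) default weights."""
    m = len(sequences)
    if ids is None:
        ids = [f"{label or 'seq'}_{i + 1}" for i in range(m)]
    if weights is None:
        weights = [1.0 / m] * m if m else []
    return Profile(tuple(ids), tuple(sequences), tuple(weights), label=label)


def read_profile(path: str | Path, label: str = "") -> Profile:
    """Read an (aligned or plain) FASTA file into a Profile.

    Identifiers are the FASTA text up to the first whitespace. Default
    weights are uniform, 1/m per sequence.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise ProfileError(f"cannot read FASTA file {path}: {exc}") from exc
    if not records:
        raise ProfileError(f"FASTA file {path} contains no records")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return make_profile(seqs, ids=ids, label=label or path.stem)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Write a profile as aligned FASTA ('-' gaps)."""
    records = [
        SeqRecord(Seq(s), id=rid, description="")
        for rid, s in zip(profile.ids, profile.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def set_weights(profile: Profile, scheme: str) -> Profile:
    """Return a copy of ``profile`` reweighted by a named scheme.

    ``"uniform"`` gives each of m sequences weight 1/m (keeps profile-pair
    scores on the scale of a single substitution score regardless of group
    size); ``"unit"`` gives each weight 1.0 (plain unweighted sum of pairs).
    """
    m = profile.n_sequences
    if scheme == "uniform":
        w = (1.0 / m,) * m
    elif scheme == "unit":
        w = (1.0,) * m
    else:
        raise ProfileError(
            f"unknown weighting scheme {scheme!r} (known: uniform, unit)"
        )
    return replace(profile, weights=w)


def weight_array(profile: Profile) -> np.ndarray:
    return np.asarray(profile.weights, dtype=np.float64)
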