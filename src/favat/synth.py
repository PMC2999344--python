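"""Synthetic protein families with planted functional residues.

Emulates the study design the voting statistic is built for: a target
sequence, a functionally negative group (~A) of close homologs (high
identity to the target) whose planted "functional" positions have been
substituted away, and a functionally identical group (A) of remote homologs
(low identity) that conserve exactly those positions. Running the full
pipeline on such a family should rank the planted positions at the top.

The generator is deliberately simple — independent uniform substitutions at
a fixed count of positions, no phylogeny, no realistic substitution
process — so every property of the output is exactly analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import SynthError
from .matrices import SubstitutionMatrix, load_matrix
from .profile_io import GAP, Profile, make_profile

#: The 20 standard amino acids (no ambiguity codes in generated data).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyConfig:
    """Shape of one synthetic family.

    ``identity_a`` / ``identity_na`` are the target-vs-group identity
    fractions (matches over target length). The defaults mirror the
    amidohydrolase case this method was designed around: a remote
    functionally identical group near 35% identity and a close functionally
    negative group near 65%.
    """

    target_length: int = 120
    n_a: int = 4
    n_na: int = 4
    planted_positions: tuple[int, ...] = ()
    identity_a: float = 0.35
    identity_na: float = 0.65
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_length <= 0:
            raise SynthError("target_length must be positive")
        planted = tuple(sorted(set(int(p) for p in self.planted_positions)))
        object.__setattr__(self, "planted_positions", planted)
        if planted and not (1 <= planted[0] and planted[-1] <= self.target_length):
            raise SynthError(
                f"planted positions must lie in [1, {self.target_length}], "
                f"got {planted}"
            )
        if not (0 < self.identity_a < 1 and 0 < self.identity_na < 1):
            raise SynthError("identity fractions must be in (0, 1)")
        if self.identity_na < self.identity_a:
            raise SynthError(
                "identity_na must be at least identity_a: the ~A group is by "
                "definition the sequence-similar one"
            )
        if not (0 <= self.indel_rate < 1):
            raise SynthError("indel_rate must be in [0, 1)")
        if self.n_a < 1 or self.n_na < 1:
            raise SynthError("each group needs at least one sequence")


@dataclass(frozen=True)
class FamilyFixture:
    """A generated family plus its ground truth."""

    target: str
    a_group: tuple[str, ...]
    na_group: tuple[str, ...]
    truth: tuple[int, ...]
    config: FamilyConfig
    identities_a: tuple[float, ...] = field(default=())
    identities_na: tuple[float, ...] = field(default=())


def measure_identity(target: str, seq: str) -> float:
    """Exact matches over aligned non-gap positions, divided by target length.

    For gapless equal-length sequences this is the plain match fraction.
    """
    matches = sum(
        1 for a, b in zip(target, seq) if a == b and a != GAP and b != GAP
    )
    return matches / len(target.replace(GAP, ""))


def _mutate(
    base: list[str],
    positions: np.ndarray,
    rng: np.random.Generator,
    forbidden_like: dict[int, str] | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> list[str]:
    """Substitute ``base`` at ``positions`` (0-based) with random residues.

    Background substitutions are uniform over the 19 alternatives. Where
    ``forbidden_like`` names a position, the replacement is drawn only from
    residues scoring <= 0 against the original residue in ``matrix`` —
    used at planted positions of the ~A group to guarantee the contrast the
    voting statistic amplifies.
    """
    seq = base.copy()
    for pos in positions:
        pos = int(pos)
        orig = seq[pos]
        if forbidden_like is not None and pos in forbidden_like:
            assert matrix is not None
            choices = [
                r
                for r in AMINO_ACIDS
                if r != orig and matrix.score(orig, r) <= 0
            ]
        else:
            choices = [r for r in AMINO_ACIDS if r != orig]
        seq[pos] = choices[rng.integers(len(choices))]
    return seq


def _apply_indels(
    seq: list[str],
    keep: set[int],
    rate: float,
    rng: np.random.Generator,
) -> str:
    """Random deletions/insertions away from the positions in ``keep``."""
    out: list[str] = []
    for i, sym in enumerate(seq):
        if i in keep:
            out.append(sym)
            continue
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(sym)
        if r > 1 - rate / 2:
            out.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
    return "".join(out)


def generate_family(config: FamilyConfig) -> FamilyFixture:
    """Draw a reproducible synthetic family from ``config.seed``.

    The A group preserves the target residue at every planted position and
    is mutated at exactly round((1 - identity_a) * L) background positions;
    the ~A group is substituted at every planted position (to residues with
    BLOSUM62 score <= 0 against the target residue) plus enough background
    positions to reach its identity band.
    """
    rng = np.random.default_rng(config.seed)
    matrix = load_matrix("BLOSUM62")
    length = config.target_length
    target = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)]
    planted0 = [p - 1 for p in config.planted_positions]
    planted_set = set(planted0)
    background = np.array(
        [i for i in range(length) if i not in planted_set], dtype=np.int64
    )

    k_a = round((1 - config.identity_a) * length)
    if k_a > len(background):
        raise SynthError(
            f"identity band {config.identity_a} needs {k_a} mutable positions "
            f"but only {len(background)} are not planted"
        )
    k_na = round((1 - config.identity_na) * length)
    if k_na < len(planted0):
        raise SynthError(
            f"identity band {config.identity_na} allows only {k_na} "
            f"substitutions, fewer than the {len(planted0)} planted positions "
            f"that must all be substituted in the ~A group"
        )

    a_group: list[str] = []
    for _ in range(config.n_a):
        pos = rng.choice(background, size=k_a, replace=False)
        a_group.append("".join(_mutate(target, pos, rng)))

    na_group: list[str] = []
    forbidden = {p: target[p] for p in planted0}
    for _ in range(config.n_na):
        extra = rng.choice(background, size=k_na - len(planted0), replace=False)
        pos = np.concatenate([np.array(planted0, dtype=np.int64), extra])
        na_group.append(
            "".join(_mutate(target, pos, rng, forbidden_like=forbidden, matrix=matrix))
        )

    target_str = "".join(target)
    identities_a = tuple(measure_identity(target_str, s) for s in a_group)
    identities_na = tuple(measure_identity(target_str, s) for s in na_group)

    if config.indel_rate > 0:
        a_group = [
            _apply_indels(list(s), planted_set, config.indel_rate, rng)
            for s in a_group
        ]
        na_group = [
            _apply_indels(list(s), planted_set, config.indel_rate, rng)
            for s in na_group
        ]

    return FamilyFixture(
        target=target_str,
        a_group=tuple(a_group),
        na_group=tuple(na_group),
        truth=config.planted_positions,
        config=config,
        identities_a=identities_a,
        identities_na=identities_na,
    )


def profiles_from_fixture(
    fixture: FamilyFixture,
) -> tuple[Profile, Profile, Profile]:
    """Target / A / ~A profiles (only valid for indel-free fixtures)."""
    if fixture.config.indel_rate > 0:
        raise SynthError(
            "fixtures generated with indels are unaligned; pre-align the "
            "groups before building profiles"
        )
    target = make_profile([fixture.target], ids=["target"], label="target")
    a_prof = make_profile(
        list(fixture.a_group),
        ids=[f"A_{i + 1}" for i in range(len(fixture.a_group))],
        label="A",
    )
    na_prof = make_profile(
        list(fixture.na_group),
        ids=[f"nA_{i + 1}" for i in range(len(fixture.na_group))],
        label="~A",
    )
    return target, a_prof, na_prof


def write_fixture(fixture: FamilyFixture, directory: str | Path) -> dict[str, Path]:
    """Write target/A/~A FASTA files, the truth file, and a config echo."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SynthError(f"cannot create fixture directory {directory}: {exc}") from exc
    paths = {
        "target": directory / "target.fasta",
        "a_group": directory / "group_A.fasta",
        "na_group": directory / "group_notA.fasta",
        "truth": directory / "truth.txt",
        "config": directory / "config.yaml",
    }
    _write_fasta([fixture.target], ["target"], paths["target"])
    _write_fasta(
        fixture.a_group,
        [f"A_{i + 1}" for i in range(len(fixture.a_group))],
        paths["a_group"],
    )
    _write_fasta(
        fixture.na_group,
        [f"nA_{i + 1}" for i in range(len(fixture.na_group))],
        paths["na_group"],
    )
    paths["truth"].write_text(
        "".join(f"{p}\n" for p in fixture.truth)
    )
    cfg = fixture.config
    paths["config"].write_text(
        yaml.safe_dump(
            {
                "target_length": cfg.target_length,
                "n_a": cfg.n_a,
                "n_na": cfg.n_na,
                "planted_positions": list(cfg.planted_positions),
                "identity_a": cfg.identity_a,
                "identity_na": cfg.identity_na,
                "indel_rate": cfg.indel_rate,
                "seed": cfg.seed,
            },
            sort_keys=False,
        )
    )
    return paths


def read_truth(path: str | Path) -> tuple[int, ...]:
    """Parse a truth file (one 1-based position per line)."""
    lines = Path(path).read_text().split()
    return tuple(int(x) for x in lines)


def _write_fasta(seqs, ids, path: Path) -> None:
    """Plain FASTA writer (handles the ragged, indel-bearing case too)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=rid, description="") for rid, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
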