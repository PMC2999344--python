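"""The full align -> vote -> normalize -> select pipeline as a library call."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, ConfigError, VotingError
from .matrices import SubstitutionMatrix, load_matrix
from .profile_io import Profile, read_profile, set_weights
from .tripalign import AlignParams, ThreeAlignment, align_three
from .voting import (
    DEFAULT_THRESHOLD,
    ScoreTable,
    normalize,
    select_candidates,
    t_scores,
)

logger = logging.getLogger(__name__)

GROUP_TAG = "favat_group"


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    target_path: Path
    a_path: Path
    na_path: Path
    a2_path: Path | None = None
    matrix_source: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = False
    weight_scheme: str = "uniform"
    gap_rule: str = "any_gap_zero"
    threshold: float = DEFAULT_THRESHOLD
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 100):
            raise ConfigError(
                f"threshold must be in [0, 100], got {self.threshold}"
            )
        for name in ("target_path", "a_path", "na_path"):
            p = getattr(self, name)
            object.__setattr__(self, name, Path(p))
        if self.a2_path is not None:
            object.__setattr__(self, "a2_path", Path(self.a2_path))
        object.__setattr__(self, "output_dir", Path(self.output_dir))


@dataclass(frozen=True)
class RunResult:
    """Alignments, score tables, and candidate lists of one pipeline run."""

    alignment: ThreeAlignment
    table: ScoreTable
    candidates: list[tuple[int, str, float]]
    alignment2: ThreeAlignment | None = None
    table2: ScoreTable | None = None
    candidates2: list[tuple[int, str, float]] | None = None
    merged: list[int] | None = None


def _load_target(path: Path) -> Profile:
    profile = read_profile(path, label="target")
    if profile.n_sequences != 1:
        raise ConfigError(
            f"target FASTA {path} must contain exactly one record, "
            f"found {profile.n_sequences}"
        )
    return profile


def run_stage(
    target: Profile,
    a_prof: Profile,
    na_prof: Profile,
    matrix: SubstitutionMatrix,
    params: AlignParams,
    gap_rule: str,
    threshold: float,
) -> tuple[ThreeAlignment, ScoreTable, list[tuple[int, str, float]]]:
    """One vote: align the three profiles, score, normalize, select."""
    alignment = align_three(target, a_prof, na_prof, params)
    logger.info(
        "aligned %s/%s/%s: %d columns, score %.3f",
        target.label,
        a_prof.label,
        na_prof.label,
        alignment.length,
        alignment.score,
    )
    logger.debug("column shapes: %s", " ".join(alignment.column_types))
    table = normalize(
        t_scores(
            alignment,
            matrix,
            a_label=a_prof.label,
            na_label=na_prof.label,
            gap_rule=gap_rule,
        )
    )
    return alignment, table, select_candidates(table, threshold)


def run_favat(config: RunConfig) -> RunResult:
    """Run the full pipeline described by ``config`` (no file output)."""
    from .voting import merge_votes

    matrix = load_matrix(config.matrix_source)
    params = AlignParams(
        matrix=matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        end_gaps_free=config.end_gaps_free,
    )
    target = set_weights(_load_target(config.target_path), config.weight_scheme)
    a_prof = set_weights(read_profile(config.a_path, label="A"), config.weight_scheme)
    na_prof = set_weights(
        read_profile(config.na_path, label="~A"), config.weight_scheme
    )
    alignment, table, candidates = run_stage(
        target, a_prof, na_prof, matrix, params, config.gap_rule, config.threshold
    )
    if config.a2_path is None:
        return RunResult(alignment, table, candidates)
    a2_prof = set_weights(
        read_profile(config.a2_path, label="A"), config.weight_scheme
    )
    alignment2, table2, candidates2 = run_stage(
        target, a2_prof, na_prof, matrix, params, config.gap_rule, config.threshold
    )
    merged = merge_votes(table, table2, config.threshold)
    return RunResult(
        alignment, table, candidates, alignment2, table2, candidates2, merged
    )


def write_alignment_fasta(alignment: ThreeAlignment, path: str | Path) -> None:
    """Write a three-way alignment as one FASTA with group tags in headers."""
    records = []
    for profile in alignment.profiles:
        for rid, seq in zip(profile.ids, profile.sequences):
            records.append(
                SeqRecord(
                    Seq(seq),
                    id=rid,
                    description=f"{GROUP_TAG}={profile.label}",
                )
            )
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> ThreeAlignment:
    """Rebuild a three-way alignment from a group-tagged FASTA.

    The recovered alignment carries no score (scores are re-derivable with
    :func:`favat.tripalign.rescore`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"alignment FASTA {path} contains no records")
    groups: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for rec in records:
        tag = None
        for word in rec.description.split():
            if word.startswith(f"{GROUP_TAG}="):
                tag = word.split("=", 1)[1]
        if tag is None:
            raise AlignmentError(
                f"record {rec.id!r} in {path} lacks a {GROUP_TAG}= header tag"
            )
        if tag not in groups:
            groups[tag] = []
            order.append(tag)
        groups[tag].append((rec.id, str(rec.seq)))
    if len(order) != 3:
        raise AlignmentError(
            f"alignment FASTA must tag exactly three groups, found {order}"
        )
    profiles = []
    for tag in order:
        ids, seqs = zip(*groups[tag])
        m = len(seqs)
        profiles.append(
            Profile(
                ids,
                seqs,
                (1.0 / m,) * m,
                label=tag,
                allow_gap_columns=True,
            )
        )
    from .profile_io import GAP

    column_types = tuple(
        "".join(
            "-" if all(s[col] == GAP for s in p.sequences) else "r"
            for p in profiles
        )
        for col in range(profiles[0].length)
    )
    return ThreeAlignment(
        profiles=tuple(profiles), score=float("nan"), column_types=column_types
    )
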