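"""Substitution-matrix voting over a three-way alignment.

Each target residue collects one vote per (A-sequence, ~A-sequence) pair:

    V = M[t, a] - M[t, na]

positive when the target residue resembles the functional (A) group more
than the sequence-similar but functionally negative (~A) group. The m*n
votes at a column sum to the raw T-score; raw T-scores are min-max
normalized to 0..100 and ranked. Voting is an unweighted column
computation — alignment-stage sequence weights play no role here.

Gap handling is governed by ``gap_rule``:

* ``"any_gap_zero"`` (default): a column where any sequence of any group
  shows a gap scores exactly 0 and is flagged ``gap_zeroed``;
* ``"target_gap_skip"``: only target-gap columns are dropped; pairwise
  votes involving a group gap contribute 0 through the missing M term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import VotingError
from .matrices import SubstitutionMatrix
from .profile_io import GAP
from .tripalign import ThreeAlignment

logger = logging.getLogger(__name__)

GAP_RULES = ("any_gap_zero", "target_gap_skip")

DEFAULT_THRESHOLD = 60.0


@dataclass(frozen=True)
class ScoreEntry:
    """Scores of one target residue (1-based position in the ungapped target)."""

    position: int
    residue: str
    raw_t: float
    norm_t: float | None = None
    gap_zeroed: bool = False


@dataclass(frozen=True)
class ScoreTable:
    """Per-target-residue raw and normalized T-scores."""

    entries: tuple[ScoreEntry, ...]
    min_raw: float
    max_raw: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.entries:
            raise VotingError("empty score table")
        positions = [e.position for e in self.entries]
        if positions != sorted(set(positions)):
            raise VotingError("score-table positions must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [e.position for e in self.entries],
                "residue": [e.residue for e in self.entries],
                "raw_t": [e.raw_t for e in self.entries],
                "norm_t": [e.norm_t for e in self.entries],
                "gap_zeroed": [e.gap_zeroed for e in self.entries],
            }
        )


def v_score(
    t: str, a: str, na: str, matrix: SubstitutionMatrix
) -> float:
    """One vote: M[t, a] - M[t, na].

    ``t`` must be a residue; a gap in ``a`` or ``na`` zeroes the
    corresponding matrix term (used by the ``target_gap_skip`` rule —
    column-level zeroing is handled by :func:`t_scores`).
    """
    if t == GAP:
        raise VotingError("target symbol at a voted column must not be a gap")
    term_a = 0 if a == GAP else matrix.score(t, a)
    term_na = 0 if na == GAP else matrix.score(t, na)
    return float(term_a - term_na)


def t_scores(
    alignment: ThreeAlignment,
    matrix: SubstitutionMatrix,
    a_label: str = "A",
    na_label: str = "~A",
    gap_rule: str = "any_gap_zero",
) -> ScoreTable:
    """Accumulate raw T-scores for every target residue.

    Profile 1 of ``alignment`` must hold the single target sequence; the
    other two profiles are identified as A / ~A by their labels. The raw
    T-score of a column is the sum of all m*n V-scores; normalization is a
    separate step (:func:`normalize`).
    """
    if gap_rule not in GAP_RULES:
        raise VotingError(
            f"unknown gap rule {gap_rule!r} (known: {', '.join(GAP_RULES)})"
        )
    target, second, third = alignment.profiles
    if target.n_sequences != 1:
        raise VotingError(
            f"profile 1 must be the single target sequence, got "
            f"{target.n_sequences} sequences"
        )
    by_label = {second.label: second, third.label: third}
    if a_label not in by_label or na_label not in by_label:
        raise VotingError(
            f"alignment profiles are labelled {sorted(by_label)}; "
            f"expected A group {a_label!r} and ~A group {na_label!r}"
        )
    a_prof = by_label[a_label]
    na_prof = by_label[na_label]
    tseq = target.sequences[0]
    entries: list[ScoreEntry] = []
    position = 0
    for col in range(alignment.length):
        tsym = tseq[col]
        if tsym == GAP:
            continue
        position += 1
        a_col = a_prof.column(col)
        na_col = na_prof.column(col)
        any_gap = GAP in a_col or GAP in na_col
        if gap_rule == "any_gap_zero" and any_gap:
            entries.append(
                ScoreEntry(position, tsym, raw_t=0.0, gap_zeroed=True)
            )
            continue
        raw = 0.0
        for a_sym in a_col:
            for na_sym in na_col:
                raw += v_score(tsym, a_sym, na_sym, matrix)
        entries.append(ScoreEntry(position, tsym, raw_t=raw))
    if not entries:
        raise VotingError("target contributes no residue columns to the alignment")
    raws = [e.raw_t for e in entries]
    return ScoreTable(
        entries=tuple(entries), min_raw=min(raws), max_raw=max(raws)
    )


def normalize(table: ScoreTable) -> ScoreTable:
    """Min-max normalize raw T-scores to the 0..100 range.

    norm = (raw - min) / (max - min) * 100, with min/max over all reported
    entries, gap-zeroed ones included. A degenerate table (all raw scores
    equal) normalizes to all zeros with a logged warning.
    """
    span = table.max_raw - table.min_raw
    if span == 0:
        logger.warning(
            "all raw T-scores are equal (%g); normalized scores set to 0",
            table.min_raw,
        )
        entries = tuple(replace(e, norm_t=0.0) for e in table.entries)
    else:
        entries = tuple(
            replace(e, norm_t=(e.raw_t - table.min_raw) / span * 100.0)
            for e in table.entries
        )
    return replace(table, entries=entries, normalized=True)


def select_candidates(
    table: ScoreTable, threshold: float = DEFAULT_THRESHOLD
) -> list[tuple[int, str, float]]:
    """Entries with normalized T-score strictly above ``threshold``.

    Sorted by normalized score descending, ties by ascending position.
    """
    if not table.normalized:
        raise VotingError("table must be normalized before candidate selection")
    hits = [
        (e.position, e.residue, e.norm_t)
        for e in table.entries
        if e.norm_t > threshold
    ]
    hits.sort(key=lambda h: (-h[2], h[0]))
    return hits


def merge_votes(
    table1: ScoreTable, table2: ScoreTable, threshold: float = DEFAULT_THRESHOLD
) -> list[int]:
    """Positions whose normalized score exceeds ``threshold`` in BOTH votes.

    The two tables must describe the same target (same positions and
    residues). Returned sorted ascending.
    """
    if not (table1.normalized and table2.normalized):
        raise VotingError("both tables must be normalized before merging")
    res1 = {(e.position, e.residue) for e in table1.entries}
    res2 = {(e.position, e.residue) for e in table2.entries}
    if res1 != res2:
        raise VotingError(
            "score tables disagree on the target residues; they do not "
            "describe the same target sequence"
        )
    over1 = {e.position for e in table1.entries if e.norm_t > threshold}
    over2 = {e.position for e in table2.entries if e.norm_t > threshold}
    return sorted(over1 & over2)


def top_positions(table: ScoreTable, n: int) -> list[int]:
    """Positions of the ``n`` highest normalized scores (ties: lower position)."""
    if not table.normalized:
        raise VotingError("table must be normalized before ranking")
    ranked = sorted(table.entries, key=lambda e: (-e.norm_t, e.position))
    return [e.position for e in ranked[:n]]


def write_report(
    table: ScoreTable,
    path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write the per-residue TSV report.

    '#'-prefixed header lines record run parameters; data columns are
    position (1-based), residue, raw_t, norm_t, gap_zeroed, selected.
    """
    if not table.normalized:
        raise VotingError("table must be normalized before reporting")
    frame = table.to_frame()
    frame["selected"] = frame["norm_t"] > threshold
    lines = [f"# threshold: {threshold}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a TSV report back into a DataFrame (header comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
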