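"""Fuzzy repair of misspelled unit strings via Levenshtein distance.

A raw unit token is compared against every legitimate unit of the variable
and replaced by the closest one, unless even the best similarity falls
below a rejection threshold (default 0.5), in which case the unit is
treated as unrecognizable.

Two length-normalized similarity ratios are provided:

``matching_blocks`` (default)
    ``(|a| + |b| - D2) / (|a| + |b|)`` where ``D2`` is the edit distance
    with substitutions costing 2 (equivalently ``2*LCS/(|a|+|b|)``). This
    is the normalization used by the classic fuzzy-matching libraries and
    reproduces the worked unit-check scores this pipeline is calibrated
    against (e.g. "106/L" vs "X10exp6/L" -> 0.71).

``printed_formula``
    ``1 - Lev(a, b) / max(|a|, |b|)`` with unit-cost Levenshtein distance.
    The textbook normalization; gives 0.56 for the same pair. Kept
    selectable because some sources quote this form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "levenshtein",
    "indel_distance",
    "similarity_ratio",
    "match_unit",
    "MatchResult",
    "DEFAULT_THRESHOLD",
    "METHODS",
]

DEFAULT_THRESHOLD = 0.5
METHODS = ("matching_blocks", "printed_formula")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance: minimum deletions + insertions + substitutions.

    Classic dynamic program, O(len(a)*len(b)); symmetric, zero iff equal.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def indel_distance(a: str, b: str) -> int:
    """Edit distance with substitution cost 2 (insert/delete only).

    Equals ``len(a) + len(b) - 2*LCS(a, b)``; the distance underlying the
    ``matching_blocks`` similarity ratio.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur.append(prev[j - 1])
            else:
                cur.append(min(prev[j] + 1, cur[j - 1] + 1))
        prev = cur
    return prev[-1]


def similarity_ratio(a: str, b: str, method: str = "matching_blocks") -> float:
    """Length-normalized similarity in [0, 1]; 1 iff the strings are equal.

    Both strings empty is defined as ratio 1 (nothing to edit).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if not a and not b:
        return 1.0
    if method == "matching_blocks":
        total = len(a) + len(b)
        return (total - indel_distance(a, b)) / total
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one raw unit token against a candidate list."""

    raw_unit: str
    best_candidate: str | None
    ratio: float
    accepted: bool
    method: str = "matching_blocks"


def match_unit(
    raw_unit: str,
    candidates: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "matching_blocks",
) -> MatchResult:
    """Pick the candidate unit most similar to ``raw_unit``.

    Comparison is case-insensitive on whitespace-normalized tokens; an exact
    match returns that candidate with ratio 1. Otherwise the candidate with
    the largest similarity ratio wins (ties: smaller plain Levenshtein
    distance, then earlier position in ``candidates`` — callers put the
    standard unit first). The match is accepted iff the best ratio reaches
    ``threshold``; a rejected match still reports the best candidate for
    auditing.
    """
    if not candidates:
        raise ValueError("candidate unit list is empty")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    from .ckd import normalize_unit  # local import to avoid a cycle

    raw_norm = normalize_unit(raw_unit).casefold()
    best: tuple[float, int, int] | None = None  # (-ratio, lev, index)
    best_ratio = -1.0
    best_idx = 0
    best_lev = 0
    for idx, cand in enumerate(candidates):
        cand_norm = normalize_unit(cand).casefold()
        if cand_norm == raw_norm:
            return MatchResult(raw_unit, cand, 1.0, True, method)
        ratio = similarity_ratio(raw_norm, cand_norm, method)
        lev = levenshtein(raw_norm, cand_norm)
        key = (-ratio, lev, idx)
        if best is None or key < best:
            best = key
            best_ratio, best_lev, best_idx = ratio, lev, idx
    accepted = best_ratio >= threshold
    return MatchResult(raw_unit, candidates[best_idx], best_ratio, accepted, method)
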