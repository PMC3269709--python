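"""Candidate pre-miRNA hairpin detection by weighted base-pair maximization.

Pre-miRNAs are ~70-90 nt RNAs folding into a stem-loop with the mature
sequence in one arm. This module triages windows of a genomic/EST source
around each mature occurrence with a Nussinov-style dynamic program that
maximizes a weighted count of Watson-Crick and wobble pairs (defaults
GC=3, AU=2, GU=1, minimum hairpin loop 3). The resulting pair score is a
structural plausibility score, not a thermodynamic free energy, and is not
comparable to energy-minimization outputs.

The O(n^3) fill is JIT-compiled with numba; traceback is a deterministic
Python routine (when co-optimal, the 3' base is paired rather than left
unpaired, with the 5'-most admissible partner).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .seqcore import NucSeq, dna_to_rna

DEFAULT_WEIGHTS: Mapping[str, float] = {"GC": 3.0, "AU": 2.0, "GU": 1.0}
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
_EPS = 1e-9


@dataclass(frozen=True)
class HairpinCandidate:
    """One folded window containing a mature occurrence."""

    source_id: str
    window_start: int  # 1-based inclusive on the source
    window_end: int
    seq: str           # RNA
    structure: str     # dot-bracket
    pair_score: float
    paired_fraction: float
    loop_len: int
    mature_start: int  # 1-based within the window
    mature_paired_fraction: float


def _weight_matrix(weights: Mapping[str, float]) -> np.ndarray:
    gc, au, gu = weights["GC"], weights["AU"], weights["GU"]
    if min(gc, au, gu) <= 0 or not (gu <= au <= gc):
        raise ValueError("pair weights must be positive with GU <= AU <= GC")
    W = np.zeros((4, 4))
    W[_ENC["G"], _ENC["C"]] = W[_ENC["C"], _ENC["G"]] = gc
    W[_ENC["A"], _ENC["U"]] = W[_ENC["U"], _ENC["A"]] = au
    W[_ENC["G"], _ENC["U"]] = W[_ENC["U"], _ENC["G"]] = gu
    return W


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-RNA character {exc.args[0]!r} in sequence") from exc


@njit(cache=True)
def _fill(x, W, min_loop):  # pragma: no cover - exercised via fold_maxpair
    n = x.size
    dp = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                w = W[x[k], x[j]]
                if w > 0.0:
                    s = w
                    if k > i:
                        s += dp[i, k - 1]
                    if k + 1 <= j - 1:
                        s += dp[k + 1, j - 1]
                    if s > best:
                        best = s
            dp[i, j] = best
    return dp


def _traceback(x: np.ndarray, W: np.ndarray, dp: np.ndarray, min_loop: int) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, x.size - 1)] if x.size else []
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = dp[i, j]
        paired = False
        for k in range(i, j - min_loop):
            w = W[x[k], x[j]]
            if w <= 0.0:
                continue
            s = w
            if k > i:
                s += dp[i, k - 1]
            if k + 1 <= j - 1:
                s += dp[k + 1, j - 1]
            if abs(s - target) < _EPS:
                pairs.append((k, j))
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                paired = True
                break
        if not paired:
            stack.append((i, j - 1))
    return pairs


def fold_maxpair(
    seq: str,
    min_loop: int = 3,
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> tuple[str, float]:
    """Optimal weighted-pair structure of an RNA string.

    Returns ``(dot_bracket, pair_score)``; every pair encloses at least
    ``min_loop`` unpaired bases. Deterministic.
    """
    if len(seq) < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {min_loop + 2}")
    x = _encode(seq.upper().replace("T", "U"))
    W = _weight_matrix(weights)
    dp = _fill(x, W, min_loop)
    pairs = _traceback(x, W, dp, min_loop)
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure), float(dp[0, len(seq) - 1])


def hairpin_stats(c: HairpinCandidate, mature_len: int | None = None) -> dict:
    """Summary statistics of a folded candidate (recomputed from dot-bracket)."""
    if len(c.structure) != len(c.seq):
        raise ValueError("candidate is not folded")
    paired = sum(1 for ch in c.structure if ch != ".")
    arm = "5p" if (c.mature_start - 1) + (mature_len or 0) / 2.0 <= len(c.seq) / 2.0 else "3p"
    return {
        "paired_fraction": paired / len(c.structure),
        "loop_len": c.loop_len,
        "mature_paired_fraction": c.mature_paired_fraction,
        "arm": arm,
    }


def _structure_stats(structure: str) -> tuple[float, int]:
    """(paired_fraction, terminal loop length) from a dot-bracket string.

    The terminal loop is the unpaired run enclosed by the most deeply nested
    base pair (the main hairpin loop); 0 when the structure has no pair.
    """
    paired = sum(1 for ch in structure if ch != ".")
    stack: list[int] = []
    best_depth, loop_len = -1, 0
    prev_open = None
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
            prev_open = idx
        elif ch == ")":
            i = stack.pop()
            if prev_open == i:  # innermost pair: encloses only dots
                depth = len(stack)
                if depth > best_depth:
                    best_depth = depth
                    loop_len = idx - i - 1
            prev_open = None
    return (paired / len(structure) if structure else 0.0), loop_len


def scan_precursors(
    source: NucSeq,
    mature: NucSeq,
    window_range: tuple[int, int] = (70, 90),
    step: int = 1,
    top_n: int = 5,
    min_loop: int = 3,
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> list[HairpinCandidate]:
    """Rank candidate precursor windows around each mature occurrence.

    For every exact occurrence of the mature in the source, every window of
    each size in ``window_range`` (inclusive, stepped by ``step``) that fully
    contains the occurrence is folded. Candidates are ranked by pair score,
    then paired fraction, then smaller window, then leftmost start. Returns
    the top ``top_n`` (all candidates when ``top_n`` is None); empty when the
    mature does not occur.
    """
    src = dna_to_rna(source).seq if source.alphabet == "DNA" else source.seq
    mat = dna_to_rna(mature).seq if mature.alphabet == "DNA" else mature.seq
    n, m = len(src), len(mat)
    lo, hi = window_range
    if lo < m:
        lo = m
    W = _weight_matrix(weights)

    occurrences = []
    i = src.find(mat)
    while i >= 0:
        occurrences.append(i)
        i = src.find(mat, i + 1)

    candidates: list[HairpinCandidate] = []
    for occ in occurrences:
        occ_end = occ + m - 1  # 0-based inclusive
        for w in range(lo, min(hi, n) + 1, step):
            start_lo = max(0, occ_end - w + 1)
            start_hi = min(occ, n - w)
            for s in range(start_lo, start_hi + 1):
                window = src[s:s + w]
                x = _encode(window)
                dp = _fill(x, W, min_loop)
                pairs = _traceback(x, W, dp, min_loop)
                structure = ["."] * w
                for a, b in pairs:
                    structure[a] = "("
                    structure[b] = ")"
                struct = "".join(structure)
                paired_fraction, loop_len = _structure_stats(struct)
                mstart = occ - s  # 0-based within window
                mpaired = sum(
                    1 for k in range(mstart, mstart + m) if struct[k] != "."
                ) / m
                candidates.append(HairpinCandidate(
                    source_id=source.id,
                    window_start=s + 1,
                    window_end=s + w,
                    seq=window,
                    structure=struct,
                    pair_score=float(dp[0, w - 1]),
                    paired_fraction=paired_fraction,
                    loop_len=loop_len,
                    mature_start=mstart + 1,
                    mature_paired_fraction=mpaired,
                ))
    candidates.sort(key=lambda c: (
        -c.pair_score, -c.paired_fraction, c.window_end - c.window_start, c.window_start
    ))
    return candidates if top_n is None else candidates[:top_n]
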