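"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's dynamic programs:
alignments and secondary structures are enumerated explicitly and scored by
straightforward summation, so they stay valid checks of the optimized code.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirloop import GROUP2, DesignConfig, NucSeq, design_assay


def pair_weight(a: str, b: str, weights=None) -> float:
    w = weights or {"GC": 3.0, "AU": 2.0, "GU": 1.0}
    duo = a + b
    if duo in ("GC", "CG"):
        return w["GC"]
    if duo in ("AU", "UA"):
        return w["AU"]
    if duo in ("GU", "UG"):
        return w["GU"]
    return 0.0


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid non-crossing pair set (tuples of (i, j), 0-based)."""

    def rec(i: int, j: int):
        if i > j:
            yield ()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pair_weight(seq[i], seq[k]) > 0:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield ((i, k),) + left + right

    yield from rec(0, len(seq) - 1)


def best_structure_score(seq: str, min_loop: int = 3, weights=None) -> float:
    """Maximum weighted pair score over all explicitly enumerated structures."""
    best = 0.0
    for struct in enumerate_structures(seq, min_loop):
        score = sum(pair_weight(seq[i], seq[j], weights) for i, j in struct)
        if score > best:
            best = score
    return best


def enumerate_alignments(a: str, b: str):
    """Yield (score_terms, matches, columns) for every global alignment.

    Score terms are counts (matches, mismatches, gaps) so any linear scoring
    scheme can be applied by the caller.
    """

    def rec(i: int, j: int, matches: int, mismatches: int, gaps: int):
        if i == len(a) and j == len(b):
            yield matches, mismatches, gaps
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            yield from rec(i + 1, j + 1, matches + hit, mismatches + (not hit), gaps)
        if i < len(a):
            yield from rec(i + 1, j, matches, mismatches, gaps + 1)
        if j < len(b):
            yield from rec(i, j + 1, matches, mismatches, gaps + 1)

    yield from rec(0, 0, 0, 0, 0)


def best_alignment_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0
) -> float:
    """Identity of the optimal global alignment by exhaustive enumeration.

    Ties on score are broken exactly as the implementation documents: most
    matches, then fewest columns.
    """
    best = None
    for matches, mismatches, gaps in enumerate_alignments(a, b):
        columns = matches + mismatches + gaps
        key = (match * matches + mismatch * mismatches + gap * gaps,
               matches, -columns)
        if best is None or key > best:
            best = key
    assert best is not None
    return round(100.0 * best[1] / -best[2], 1)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def random_design(rng: np.random.Generator, idx: int = 0):
    """A random mature and its auto-designed Group 2 assay."""
    n = int(rng.integers(18, 27))
    mature = NucSeq(f"rnd-{idx}", random_rna(rng, n), "RNA")
    cover = int(rng.integers(10, n - 7))  # leaves gap >= 1 with anchor 6
    ps = design_assay(mature, GROUP2,
                      DesignConfig(cover_len=cover, prefix="CGCACG"))
    return mature, ps


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
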