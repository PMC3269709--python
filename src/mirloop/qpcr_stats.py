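"""qPCR analytics: standard-curve efficiency, 2^-ddCt relative quantification
and Duncan multiple-range letter grouping.

Relative quantification follows the comparative-Ct convention: per replicate
dCt = Ct(target) - Ct(reference gene); per stage the mean dCt; ddCt =
mean dCt(stage) - mean dCt(calibrator stage); RQ = 2^-ddCt, so the
calibrator's RQ is exactly 1. Amplification efficiency is estimated from a
dilution series as E = 10^(-1/slope); an ideal doubling per cycle gives
E = 2 at slope -3.3219.

Duncan's multiple range test is run on replicate-level -dCt values (log2
expression scale, where variance is closer to homogeneous than on the RQ
scale); stages whose means are not significantly different share a letter,
with letters assigned in descending-expression order.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import lru_cache
from math import sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class QpcrError(ValueError):
    """Invalid qPCR input (degenerate curve, missing calibrator, bad Ct)."""


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit Ct = slope * log10(conc) + intercept."""

    target_id: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def fit_standard_curve(
    points: Sequence[tuple[float, float]], target_id: str = ""
) -> StandardCurve:
    """Ordinary least squares on (log10 concentration, Ct) pairs."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise QpcrError("standard curve needs >= 3 points")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise QpcrError("standard curve needs distinct concentrations")
    fit = sps.linregress(xs, ys)
    return StandardCurve(
        target_id=target_id,
        points=tuple(pts),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=round(float(fit.rvalue) ** 2, 4),
        efficiency=efficiency(float(fit.slope)),
    )


def efficiency(slope: float) -> float:
    """Per-cycle amplification factor E = 10^(-1/slope) for a negative slope."""
    if slope >= 0:
        raise QpcrError(f"dilution-series slope must be negative, got {slope}")
    return float(10.0 ** (-1.0 / slope))


# ---------------------------------------------------------------------------
# relative quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionDataset:
    """Stage x replicate Ct records for one target and one reference gene."""

    records: pd.DataFrame  # columns: stage, replicate, ct_target, ct_reference
    calibrator: str
    reference_id: str = "5S"

    def __post_init__(self) -> None:
        required = {"stage", "replicate", "ct_target", "ct_reference"}
        missing = required - set(self.records.columns)
        if missing:
            raise QpcrError(f"Ct table missing columns {sorted(missing)}")
        if self.calibrator not in set(self.records["stage"]):
            raise QpcrError(f"calibrator stage {self.calibrator!r} not in table")
        cts = self.records[["ct_target", "ct_reference"]].to_numpy(float)
        if not np.isfinite(cts).all():
            raise QpcrError("non-finite Ct values in table")

    @classmethod
    def from_tsv(cls, path: str | Path, calibrator: str,
                 reference_id: str = "5S") -> "ExpressionDataset":
        return cls(pd.read_csv(path, sep="\t"), calibrator, reference_id)


@dataclass(frozen=True)
class RQResult:
    """Per-stage relative quantification table.

    ``table`` columns: stage, n, mean_dct, ddct, rq, se, letters. Stage order
    follows first appearance in the input.
    """

    table: pd.DataFrame
    calibrator: str

    def rq(self, stage: str) -> float:
        return float(self.table.set_index("stage").loc[stage, "rq"])


def delta_delta_ct(
    data: ExpressionDataset,
    alpha: float = 0.05,
    efficiency_value: float | None = None,
    letters: bool = True,
) -> RQResult:
    """Comparative-Ct relative quantification with Duncan letters.

    RQ is computed from stage-mean dCt so the calibrator is exactly 1; the
    per-stage standard error is that of replicate-level 2^-ddCt values. When
    ``efficiency_value`` is given, E^-ddCt replaces 2^-ddCt
    (efficiency-corrected mode). ``letters=False`` skips the Duncan letter
    display (useful in large simulation sweeps).
    """
    df = data.records.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    stages = list(dict.fromkeys(df["stage"]))
    base = float(2.0 if efficiency_value is None else efficiency_value)

    mean_dct = df.groupby("stage", sort=False)["dct"].mean()
    cal_mean = float(mean_dct[data.calibrator])

    rows = []
    for stage in stages:
        reps = df.loc[df["stage"] == stage, "dct"].to_numpy(float)
        ddct = float(mean_dct[stage]) - cal_mean
        rq_reps = base ** -(reps - cal_mean)
        se = float(np.std(rq_reps, ddof=1) / sqrt(len(reps))) if len(reps) > 1 else float("nan")
        rows.append({
            "stage": stage,
            "n": len(reps),
            "mean_dct": float(mean_dct[stage]),
            "ddct": ddct,
            "rq": float(base ** -ddct),
            "se": se,
        })
    table = pd.DataFrame(rows)

    groups = {
        stage: (-df.loc[df["stage"] == stage, "dct"]).tolist() for stage in stages
    }
    if letters and len(stages) >= 2 and all(len(v) >= 2 for v in groups.values()):
        assigned = duncan_grouping(groups, alpha=alpha)
        table["letters"] = [assigned[s] for s in stages]
    else:
        table["letters"] = ""
    return RQResult(table=table, calibrator=data.calibrator)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_least_significant_ranges(
    k: int, df: int, mse: float, n_harmonic: float, alpha: float = 0.05
) -> dict[int, float]:
    """Duncan least significant ranges R_p for span p = 2..k.

    R_p = q_p * sqrt(MSE / n_h), where q_p is the studentized-range quantile
    at Duncan's protection level (1 - alpha)^(p - 1) with p means and the
    error degrees of freedom.
    """
    se = sqrt(mse / n_harmonic)
    return {p: _duncan_q(alpha, p, df) * se for p in range(2, k + 1)}


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level (cached)."""
    return float(sps.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df))


def duncan_grouping(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Letter display from Duncan's multiple range procedure.

    One-way ANOVA pooled MSE; means are rank-ordered (descending) and ranges
    tested from the widest span down, a non-significant range protecting all
    sub-ranges. Means sharing a letter are not significantly different;
    letters run alphabetically from the largest mean.
    """
    names = list(groups)
    if len(names) < 2:
        raise QpcrError("Duncan grouping needs >= 2 groups")
    values = {g: np.asarray(groups[g], float) for g in names}
    if any(v.size < 2 for v in values.values()):
        raise QpcrError("Duncan grouping needs >= 2 replicates per group")
    if not 0.0 < alpha < 1.0:
        raise QpcrError("alpha must be in (0, 1)")

    k = len(names)
    N = sum(v.size for v in values.values())
    df_err = N - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in values.values()) / df_err
    order = sorted(names, key=lambda g: -values[g].mean())
    means = [values[g].mean() for g in order]

    if mse == 0.0:
        # degenerate: no within-group noise; equal means share, others differ
        letters: dict[str, str] = {}
        letter_of_mean: dict[float, str] = {}
        for g, m in zip(order, means):
            if m not in letter_of_mean:
                letter_of_mean[m] = string.ascii_lowercase[len(letter_of_mean)]
            letters[g] = letter_of_mean[m]
        return letters

    n_h = k / sum(1.0 / values[g].size for g in names)
    R = duncan_least_significant_ranges(k, df_err, mse, n_h, alpha)

    # nonsig[i][j]: means i..j (ordered) declared homogeneous
    covered: list[tuple[int, int]] = []

    def is_covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in covered)

    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if is_covered(i, j):
                continue
            if means[i] - means[j] <= R[span] + 1e-12:
                covered.append((i, j))

    intervals = [iv for iv in covered
                 if not any(iv != other and other[0] <= iv[0] and iv[1] <= other[1]
                            for other in covered)]
    for i in range(k):
        if not any(a <= i <= b for a, b in intervals):
            intervals.append((i, i))
    intervals.sort()

    letters = {g: "" for g in names}
    for idx, (a, b) in enumerate(intervals):
        ch = string.ascii_lowercase[idx]
        for i in range(a, b + 1):
            letters[order[i]] += ch
    return letters
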