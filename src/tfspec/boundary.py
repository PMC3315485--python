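"""Specific/non-specific boundary from two regressions of ddG on Ri.

Plotting measured ddG against the additive model's predicted strength Ri
separates a variant's site universe into a specifically bound arm (Ri >= 0,
ddG rising as Ri falls) and a non-specific plateau (Ri < 0, ddG roughly
flat). Fitting ordinary least squares lines to the two arms and taking their
crossing approximates the non-specific binding energy dGns — the depth of
specific binding available to the variant above background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "BoundaryEstimate",
    "partition_by_ri",
    "fit_line",
    "nonspecific_energy",
    "estimate_boundary",
    "boundary_report",
]

#: below this r^2 (or fewer than this many specific points) the estimate is
#: flagged untrustworthy, mirroring the convention of asterisking variants
#: whose specific arm is too noisy to regress.
MIN_TRUSTWORTHY_R2 = 0.3
MIN_TRUSTWORTHY_POINTS = 4


@dataclass(frozen=True)
class RegressionFit:
    """One OLS line of ddG (kJ/mol) on Ri (bits)."""

    slope: float
    intercept: float
    r2: float
    n_points: int
    which: str  # "specific" | "nonspecific"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a regression fit needs >= 2 points")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 must lie in [0, 1]")

    def predict(self, ri: float) -> float:
        return self.slope * ri + self.intercept


@dataclass(frozen=True)
class BoundaryEstimate:
    """The two fits plus the derived non-specific energy dGns."""

    fit_pos: RegressionFit
    fit_neg: RegressionFit
    dg_ns: float
    method: str  # "intersection" | "ri0-intercept"
    trustworthy: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.dg_ns):
            raise ValueError("dg_ns must be finite")
        if self.method not in ("intersection", "ri0-intercept"):
            raise ValueError(f"unknown method {self.method!r}")


def partition_by_ri(
    scores: Mapping[str, float] | pd.Series, threshold: float = 0.0
) -> tuple[list[str], list[str]]:
    """Split sites into (specific, nonspecific) by Ri against a threshold.

    Sites exactly at the threshold count as specific (Ri >= 0 is the standard
    convention for a specifically bound site). The two lists are disjoint and
    exhaustive.
    """
    scores = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    specific = list(scores.index[scores >= threshold])
    nonspecific = list(scores.index[scores < threshold])
    return specific, nonspecific


def fit_line(
    ri: Sequence[float], ddg: Sequence[float], which: str = "specific"
) -> RegressionFit:
    """Ordinary least squares of ddG on Ri."""
    x = np.asarray(ri, dtype=float)
    y = np.asarray(ddg, dtype=float)
    if x.size != y.size:
        raise ValueError("ri and ddg must have equal length")
    if x.size < 2:
        raise ValueError("need >= 2 points to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all Ri values equal")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(r2, 1.0),
        n_points=int(x.size),
        which=which,
    )


def nonspecific_energy(
    fit_pos: RegressionFit,
    fit_neg: RegressionFit,
    method: str = "intersection",
    trustworthy: bool = True,
) -> BoundaryEstimate:
    """Derive dGns from the two regression lines.

    ``intersection``: the ddG value at the crossing point of the specific and
    non-specific lines. ``ri0-intercept``: the specific-site line evaluated at
    Ri = 0 (its intercept). Parallel lines under ``intersection`` fall back to
    ``ri0-intercept`` with a warning.
    """
    if fit_pos is None or fit_neg is None:
        raise ValueError("both regression fits are required")
    if method not in ("intersection", "ri0-intercept"):
        raise ValueError(f"unknown method {method!r}")
    if method == "intersection":
        denom = fit_pos.slope - fit_neg.slope
        if abs(denom) < 1e-12:
            warnings.warn(
                "regression lines are parallel; falling back to ri0-intercept",
                stacklevel=2,
            )
            method = "ri0-intercept"
        else:
            x_cross = (fit_neg.intercept - fit_pos.intercept) / denom
            dg_ns = fit_pos.predict(x_cross)
            return BoundaryEstimate(fit_pos, fit_neg, dg_ns, "intersection", trustworthy)
    return BoundaryEstimate(
        fit_pos, fit_neg, fit_pos.intercept, "ri0-intercept", trustworthy
    )


def estimate_boundary(
    scores: Mapping[str, float] | pd.Series,
    ddg: Mapping[str, float] | pd.Series,
    threshold: float = 0.0,
    method: str = "intersection",
) -> BoundaryEstimate:
    """Partition a site universe by Ri, fit both arms, and derive dGns.

    The estimate is flagged untrustworthy when the specific arm has fewer
    than 4 points or r^2 below 0.3 — too little structure to anchor the
    crossing.
    """
    scores = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    ddg = pd.Series(dict(ddg) if not isinstance(ddg, pd.Series) else ddg)
    if set(scores.index) != set(ddg.index):
        raise ValueError("Ri scores and ddG values cover different site sets")
    ddg = ddg.reindex(scores.index)
    specific, nonspecific = partition_by_ri(scores, threshold)
    if len(specific) < 2 or len(nonspecific) < 2:
        raise ValueError(
            f"need >= 2 sites on each side of the threshold "
            f"(got {len(specific)} specific, {len(nonspecific)} non-specific)"
        )
    fit_pos = fit_line(scores[specific], ddg[specific], which="specific")
    fit_neg = fit_line(scores[nonspecific], ddg[nonspecific], which="nonspecific")
    trustworthy = (
        fit_pos.r2 >= MIN_TRUSTWORTHY_R2 and fit_pos.n_points >= MIN_TRUSTWORTHY_POINTS
    )
    return nonspecific_energy(fit_pos, fit_neg, method=method, trustworthy=trustworthy)


def boundary_report(
    scores: Mapping[str, float] | pd.Series,
    ddg: Mapping[str, float] | pd.Series,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-site table of (Ri, ddG, class) mirroring the two-arm scatter."""
    scores = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    ddg = pd.Series(dict(ddg) if not isinstance(ddg, pd.Series) else ddg)
    ddg = ddg.reindex(scores.index)
    cls = np.where(scores >= threshold, "specific", "nonspecific")
    return pd.DataFrame(
        {"ri_bits": scores, "ddg_kj_mol": ddg, "class": cls}
    ).rename_axis("site")
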