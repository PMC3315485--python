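"""Cross-variant site overlap and expression-vs-affinity analysis.

Two variants' Ri scores over a shared site universe split the universe into
four quadrants: sites specific to both (shared), to neither, or to exactly
one — the picture that distinguishes a variant that merely binds a subset of
another's sites from a fully orthogonal regulator. Reporter-expression
measurements (tet transcript over transcription-factor transcript, reference-
normalised) are correlated against relative affinity to ask whether binding
strength predicts transcriptional output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuadrantSummary",
    "overlap_quadrants",
    "relative_expression",
    "expression_affinity_correlation",
]


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant partition of a site universe by two variants' Ri signs."""

    shared_specific: tuple[str, ...]
    neither: tuple[str, ...]
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    r2: float

    @property
    def universe_size(self) -> int:
        return (
            len(self.shared_specific) + len(self.neither)
            + len(self.only_a) + len(self.only_b)
        )


def overlap_quadrants(
    ri_a: Mapping[str, float] | pd.Series,
    ri_b: Mapping[str, float] | pd.Series,
    threshold: float = 0.0,
) -> QuadrantSummary:
    """Partition the shared site universe by the sign of each variant's Ri.

    Ties at the threshold count as specific, consistent with the boundary
    partition. ``r2`` is the squared Pearson correlation of the paired raw
    scores over the whole universe.
    """
    ri_a = pd.Series(dict(ri_a) if not isinstance(ri_a, pd.Series) else ri_a)
    ri_b = pd.Series(dict(ri_b) if not isinstance(ri_b, pd.Series) else ri_b)
    if set(ri_a.index) != set(ri_b.index):
        raise ValueError("the two score sets cover different site universes")
    ri_b = ri_b.reindex(ri_a.index)
    a_spec = ri_a >= threshold
    b_spec = ri_b >= threshold
    x, y = ri_a.to_numpy(), ri_b.to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in Ri scores; reporting r2 = 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(x, y).statistic ** 2)
    return QuadrantSummary(
        shared_specific=tuple(ri_a.index[a_spec & b_spec]),
        neither=tuple(ri_a.index[~a_spec & ~b_spec]),
        only_a=tuple(ri_a.index[a_spec & ~b_spec]),
        only_b=tuple(ri_a.index[~a_spec & b_spec]),
        r2=r2,
    )


def relative_expression(
    records: pd.DataFrame, reference: tuple[str, str]
) -> pd.DataFrame:
    """Reference-normalised expression: (tet/mara) over the reference's (tet/mara).

    ``records`` needs columns ``variant_id``, ``site``, ``tet_abundance`` and
    ``mara_abundance`` (all abundances > 0); the returned copy gains a
    ``relative_expression`` column in which the reference (variant, site)
    record is exactly 1. Rescaling all tet (or all mara) abundances by a
    constant leaves the output unchanged.
    """
    required = {"variant_id", "site", "tet_abundance", "mara_abundance"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["tet_abundance"] <= 0).any() or (records["mara_abundance"] <= 0).any():
        raise ValueError("abundances must be positive")
    ratio = records["tet_abundance"] / records["mara_abundance"]
    ref_variant, ref_site = reference
    mask = (records["variant_id"] == ref_variant) & (records["site"] == ref_site)
    if not mask.any():
        raise KeyError(f"reference record {reference!r} not found")
    ref_ratio = float(ratio[mask].iloc[0])
    out = records.copy()
    out["relative_expression"] = ratio / ref_ratio
    return out


def expression_affinity_correlation(
    records: pd.DataFrame,
    affinities: Mapping[str, float] | pd.Series,
    subset: Sequence[str] | None = None,
) -> float:
    """Pearson r^2 between relative affinity and relative expression.

    ``records`` must carry ``site`` and ``relative_expression``; ``subset``
    restricts to a site subset (e.g. only the tightly bound sites). Defined
    as 0 with a warning when either variable has zero variance.
    """
    if "relative_expression" not in records.columns:
        raise ValueError("records lack a relative_expression column (normalise first)")
    affinities = pd.Series(
        dict(affinities) if not isinstance(affinities, pd.Series) else affinities
    )
    rows = records
    if subset is not None:
        rows = records[records["site"].isin(set(subset))]
    missing = [s for s in rows["site"] if s not in affinities.index]
    if missing:
        raise KeyError(f"no affinity for sites: {sorted(set(missing))}")
    x = affinities[rows["site"]].to_numpy(dtype=float)
    y = rows["relative_expression"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 paired points, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation reported as 0", stacklevel=2)
        return 0.0
    return float(stats.pearsonr(x, y).statistic ** 2)
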