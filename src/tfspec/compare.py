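"""Kullback-Leibler divergence between motif probability matrices.

Pairwise motif similarity is quantified column-by-column: each aligned pair
of probability columns contributes a (by default symmetrised) KL divergence
in bits, and the matrix-level value aggregates the per-column values. Zero
means identical matrices; small values mean closely similar binding
preferences. Because the historical tool chain does not pin down every
normalisation detail, the symmetrisation, aggregation (mean vs sum) and log
base are explicit switches with documented defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .matrices import FrequencyMatrix

__all__ = ["KldResult", "column_kld", "matrix_kld", "pairwise_kld"]

DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class KldResult:
    """Matrix-level KLD plus the per-column values and alignment used."""

    value: float
    per_column: tuple[float, ...]
    shift: int = 0
    columns_compared: int = 0
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.value < -1e-12:
            raise ValueError("KLD must be non-negative")
        agg = np.mean if self.aggregate == "mean" else np.sum
        if abs(self.value - float(agg(self.per_column))) > 1e-9:
            raise ValueError("value inconsistent with per-column aggregation")


def _regularize(p: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount > 0:
        p = (p + pseudocount) / (1.0 + p.size * pseudocount)
    return p


def column_kld(
    p: Sequence[float],
    q: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    symmetrize: bool = True,
    log_base: float = 2.0,
) -> float:
    """Divergence between two probability columns, default 1/2[D(p||q)+D(q||p)] in bits."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors differ in length")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6 or (v < 0).any():
            raise ValueError(f"{name} is not a probability vector")
    p = _regularize(p, pseudocount)
    q = _regularize(q, pseudocount)
    scale = 1.0 / math.log(log_base)
    d_pq = float(rel_entr(p, q).sum()) * scale
    if not symmetrize:
        return max(d_pq, 0.0)
    d_qp = float(rel_entr(q, p).sum()) * scale
    return max(0.5 * (d_pq + d_qp), 0.0)


def matrix_kld(
    fm1: FrequencyMatrix,
    fm2: FrequencyMatrix,
    allow_shift: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    symmetrize: bool = True,
    log_base: float = 2.0,
    aggregate: str = "mean",
) -> KldResult:
    """Column-wise KLD between two matrices over aligned positions.

    Without shift search the matrices are aligned on their shared position
    labels. With ``allow_shift`` every integer offset leaving >= 2 overlapping
    columns is tried and the offset minimising the aggregated value is
    reported.
    """
    if fm1.alphabet != fm2.alphabet:
        raise ValueError("matrices use different alphabets")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    def _score(offset: int) -> tuple[float, list[float], int]:
        shifted = [p + offset for p in fm2.positions]
        common = [p for p in fm1.positions if p in shifted]
        if len(common) < 2 and (allow_shift or len(common) < 1):
            return math.inf, [], 0
        cols = []
        for pos in common:
            cols.append(
                column_kld(
                    fm1.probs.loc[pos].to_numpy(),
                    fm2.probs.loc[pos - offset].to_numpy(),
                    pseudocount=pseudocount,
                    symmetrize=symmetrize,
                    log_base=log_base,
                )
            )
        agg = float(np.mean(cols) if aggregate == "mean" else np.sum(cols))
        return agg, cols, len(common)

    offsets = [0]
    if allow_shift:
        span = len(fm1.positions) + len(fm2.positions)
        offsets = list(range(-span, span + 1))
    best = None
    for off in offsets:
        value, cols, ncols = _score(off)
        if best is None or value < best[0]:
            best = (value, cols, ncols, off)
    value, cols, ncols, off = best
    if not math.isfinite(value):
        raise ValueError("no offset leaves a valid column overlap")
    return KldResult(
        value=value,
        per_column=tuple(cols),
        shift=off,
        columns_compared=ncols,
        aggregate=aggregate,
    )


def pairwise_kld(
    matrices: Mapping[str, FrequencyMatrix],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    **kwargs,
) -> pd.DataFrame:
    """Symmetric table of matrix-level KLDs with a zero diagonal."""
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 matrices")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            v = matrix_kld(matrices[a], matrices[b], pseudocount=pseudocount, **kwargs).value
            out.at[a, b] = v
            out.at[b, a] = v
    return out
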