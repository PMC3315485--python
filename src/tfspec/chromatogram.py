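"""Pooled-chromatogram peak heights to population frequency matrices and logos.

After an in vivo selection, the surviving plasmid pool is sequenced in a
single Sanger reaction; at each randomised position the relative peak height
of each base approximates that base's frequency in the population. Dividing
each height by the summed heights at its position gives a semi-quantitative
frequency matrix (peak heights are biased by neighbouring bases, so the
matrices carry a provenance flag) from which a selection logo is built.
Unrandomised positions are carried as fixed, probability-1 columns and can
be blanked in the logo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .matrices import FrequencyMatrix, information_content, logo_table

__all__ = ["ChromatogramTable", "SelectionLogo", "frequencies_from_peaks", "selection_logo"]


@dataclass(frozen=True)
class ChromatogramTable:
    """Position x base -> peak height (arbitrary fluorescence units).

    ``heights`` covers the randomised positions (every row must have positive
    total height); ``fixed_positions`` maps unrandomised position labels to
    their forced base. A fixed position may also appear in ``heights``
    provided its only non-zero peak is the forced base.
    """

    heights: pd.DataFrame
    fixed_positions: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.heights.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("peak heights must be non-negative")
        positions = list(self.heights.index)
        if any(positions[i] >= positions[i + 1] for i in range(len(positions) - 1)):
            raise ValueError("position labels must be strictly increasing")
        for pos in self.heights.index:
            row = self.heights.loc[pos]
            if pos in self.fixed_positions:
                base = self.fixed_positions[pos]
                if base not in self.heights.columns:
                    raise ValueError(f"fixed base {base!r} outside the alphabet")
                nonzero = row.index[row > 0].tolist()
                if nonzero and nonzero != [base]:
                    raise ValueError(
                        f"fixed position {pos} has peaks other than its forced base"
                    )
            elif row.sum() <= 0:
                raise ValueError(f"all-zero peak column at randomised position {pos}")

    @property
    def alphabet(self) -> list[str]:
        return list(self.heights.columns)

    @property
    def positions(self) -> list[int]:
        """All positions, randomised and fixed, sorted."""
        return sorted(set(self.heights.index) | set(self.fixed_positions))


def frequencies_from_peaks(ct: ChromatogramTable) -> FrequencyMatrix:
    """Divide each peak height by its position's summed heights.

    Fixed positions become probability-1 columns on their forced base. The
    result has unknown n and is flagged semi-quantitative; rescaling all
    heights at a position by any positive constant leaves it unchanged.
    """
    alphabet = ct.alphabet
    rows = []
    for pos in ct.positions:
        if pos in ct.fixed_positions:
            row = pd.Series(0.0, index=alphabet)
            row[ct.fixed_positions[pos]] = 1.0
        else:
            heights = ct.heights.loc[pos].astype(float)
            total = heights.sum()
            if total <= 0:
                raise ValueError(f"all-zero peak column at position {pos}")
            row = heights / total
        rows.append(row.rename(pos))
    probs = pd.DataFrame(rows)
    probs.columns = alphabet
    return FrequencyMatrix(probs, n=None, semi_quantitative=True)


@dataclass(frozen=True)
class SelectionLogo:
    """Frequency matrix plus the letter-height table of a selection logo."""

    frequencies: FrequencyMatrix
    heights: pd.DataFrame
    information_bits: float


def selection_logo(ct: ChromatogramTable, blank_fixed: bool = False) -> SelectionLogo:
    """Build the selection logo for a chromatogram table.

    With ``blank_fixed`` the rows of unrandomised positions are set to NaN in
    the height table (rendered blank), while the frequency matrix still
    carries them as probability-1 columns. The reported information total is
    over the randomised positions only in that case.
    """
    fm = frequencies_from_peaks(ct)
    heights = logo_table(fm, apply_correction=False)
    randomized = [p for p in fm.positions if p not in ct.fixed_positions]
    if blank_fixed:
        heights = heights.copy()
        heights.loc[[p for p in fm.positions if p in ct.fixed_positions]] = np.nan
        info = information_content(fm, position_range=randomized, apply_correction=False)
    else:
        info = information_content(fm, apply_correction=False)
    return SelectionLogo(frequencies=fm, heights=heights, information_bits=info.total)
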