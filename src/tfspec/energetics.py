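"""Association constants to free energies, energy matrices and additivity checks.

Microfluidic affinity measurements (MITOMI) yield one relative association
constant Ka per binding site per protein variant. This module converts them
to binding free energies (dG = -RT ln Ka), expresses every site relative to
the variant's strongest site (ddG >= 0 for weaker binders), reads the
single-mutant ddG values off into a per-position energy matrix, and
diagnoses how well the independent-and-additive model behind that matrix
explains the full site table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DNA_ALPHABET, DEFAULT_TEMPERATURE_K, rt
from .matrices import EnergyMatrix

__all__ = [
    "BindingTable",
    "AdditivityReport",
    "free_energy_from_association",
    "relative_binding_energies",
    "energy_matrix_from_single_mutants",
    "additive_prediction",
    "additivity_report",
    "fold_affinity",
    "sites_matching",
]


def free_energy_from_association(ka, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """dG = -RT ln Ka in kJ/mol. Ka is relative (unitless) and must be > 0."""
    ka_arr = np.asarray(ka, dtype=float)
    if (ka_arr <= 0).any():
        raise ValueError("association constants must be > 0")
    out = -rt(temperature_K) * np.log(ka_arr)
    return float(out) if np.isscalar(ka) or ka_arr.ndim == 0 else out


@dataclass(frozen=True)
class BindingTable:
    """One variant's site -> Ka mapping with derived free energies.

    ``data`` is indexed by site sequence (unique, equal length) with columns
    ``ka`` (> 0, relative units) and ``dg`` (kJ/mol, equal to -RT ln Ka).
    """

    variant_id: str
    data: pd.DataFrame
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sites in binding table: {dups}")
        lengths = {len(s) for s in self.data.index}
        if len(lengths) > 1:
            raise ValueError("all sites in a binding table must have equal length")
        if (self.data["ka"] <= 0).any():
            raise ValueError("association constants must be > 0")
        expected = free_energy_from_association(
            self.data["ka"].to_numpy(), self.temperature_K
        )
        if np.abs(self.data["dg"].to_numpy() - expected).max() > 1e-9:
            raise ValueError("dg column inconsistent with -RT ln ka")

    @classmethod
    def from_ka(
        cls,
        variant_id: str,
        ka: Mapping[str, float] | pd.Series,
        temperature_K: float = DEFAULT_TEMPERATURE_K,
    ) -> "BindingTable":
        ka = pd.Series(dict(ka), name="ka", dtype=float)
        dg = pd.Series(
            free_energy_from_association(ka.to_numpy(), temperature_K),
            index=ka.index,
            name="dg",
        )
        return cls(variant_id, pd.DataFrame({"ka": ka, "dg": dg}), temperature_K)

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def strongest_site(self) -> str:
        """Site with the largest Ka; lexicographically smallest on exact ties."""
        ka = self.data["ka"]
        top = ka.max()
        winners = sorted(ka.index[ka == top])
        if len(winners) > 1:
            warnings.warn(
                f"{self.variant_id}: tie for strongest site among {winners}; "
                f"using {winners[0]}",
                stacklevel=2,
            )
        return winners[0]


def relative_binding_energies(bt: BindingTable) -> pd.Series:
    """ddG(site) = dG(site) - dG(strongest site), in kJ/mol; min is 0.

    Weaker binders get positive ddG. Invariant to any global rescaling of
    the Ka column (only ratios enter).
    """
    ref = bt.data.at[bt.strongest_site, "dg"]
    ddg = bt.data["dg"] - ref
    ddg.name = "ddg"
    return ddg


def energy_matrix_from_single_mutants(
    ddg: Mapping[str, float] | pd.Series,
    consensus: str,
    alphabet: Sequence[str] = DNA_ALPHABET,
    positions: Sequence[int] | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> EnergyMatrix:
    """Read single-mutant ddG values off into a per-position energy matrix.

    Cell (b, l) is ddG(consensus with b at l) minus ddG(consensus), so the
    consensus base sits at 0 in every column. If some single mutant binds
    tighter than the nominated consensus (a negative cell), the column is
    re-anchored to its true minimum with a warning — the matrix invariant
    requires the per-position minimum to be 0.
    """
    ddg = pd.Series(dict(ddg) if not isinstance(ddg, pd.Series) else ddg, dtype=float)
    if consensus not in ddg.index:
        raise ValueError(f"consensus site {consensus!r} missing from ddG table")
    alphabet = list(alphabet)
    length = len(consensus)
    if positions is None:
        positions = list(range(1, length + 1))
    positions = list(positions)

    missing = []
    matrix = np.zeros((length, len(alphabet)))
    base = float(ddg[consensus])
    for l in range(length):
        for j, b in enumerate(alphabet):
            mutant = consensus[:l] + b + consensus[l + 1:]
            if mutant not in ddg.index:
                missing.append(mutant)
                continue
            matrix[l, j] = float(ddg[mutant]) - base
    if missing:
        raise ValueError(f"missing single mutants of {consensus!r}: {missing}")
    mins = matrix.min(axis=1)
    if (mins < -1e-12).any():
        offending = [positions[i] for i in np.where(mins < -1e-12)[0]]
        warnings.warn(
            f"single mutants outrank the nominated consensus at positions "
            f"{offending}; re-anchoring those columns to their minimum",
            stacklevel=2,
        )
        matrix = matrix - np.minimum(mins, 0.0)[:, None]
    df = pd.DataFrame(matrix, index=positions, columns=alphabet)
    # exact re-anchor kills float dust so the column-minimum invariant holds at 1e-9
    df = df.sub(df.min(axis=1), axis=0)
    return EnergyMatrix(df, temperature_K=temperature_K)


def additive_prediction(em: EnergyMatrix, site: str) -> float:
    """Predicted ddG of a site under the independent-and-additive model."""
    if len(site) != len(em.positions):
        raise ValueError(
            f"site length {len(site)} != matrix length {len(em.positions)}"
        )
    cols = em.ddg.columns
    total = 0.0
    for pos, b in zip(em.positions, site):
        if b not in cols:
            raise ValueError(f"symbol {b!r} at position {pos} outside the alphabet")
        total += float(em.ddg.at[pos, b])
    return total


def sites_matching(pattern: str, alphabet: Sequence[str] = DNA_ALPHABET) -> list[str]:
    """Expand a pattern like 'GCN' ('N' = any base) in alphabet order.

    The expansion order is the alphabet order of the varying symbols, so two
    patterns differing only at fixed positions yield site lists matched
    index-by-index on the shared varying symbol — the ordering the grouped
    additivity correlations require.
    """
    alphabet = list(alphabet)
    choices = [alphabet if b == "N" else [b] for b in pattern]
    import itertools

    return ["".join(t) for t in itertools.product(*choices)]


@dataclass(frozen=True)
class AdditivityReport:
    """Residuals of the additive model plus grouped cross-correlations."""

    residuals: pd.Series
    group_r2: dict[str, float]


def additivity_report(
    em: EnergyMatrix,
    ddg_measured: Mapping[str, float] | pd.Series,
    groupings: Mapping[str, tuple[Sequence[str], Sequence[str]]] | None = None,
) -> AdditivityReport:
    """Residual(site) = measured - additive prediction; grouped Pearson r^2.

    ``groupings`` maps a label to a pair of equal-length site groups matched
    index-by-index (e.g. the 'GC-N' vs 'TA-N' dinucleotide families, ordered
    by the shared varying third base); the report carries the Pearson r^2
    between the two measured ddG vectors. High r^2 between families that the
    additive model says should be energetically identical — while their
    absolute energies differ — is the signature of a dinucleotide coupling.
    """
    ddg_measured = pd.Series(
        dict(ddg_measured) if not isinstance(ddg_measured, pd.Series) else ddg_measured,
        dtype=float,
    )
    predicted = pd.Series(
        {s: additive_prediction(em, s) for s in ddg_measured.index}, dtype=float
    )
    residuals = (ddg_measured - predicted).rename("residual")

    group_r2: dict[str, float] = {}
    for name, (group_a, group_b) in (groupings or {}).items():
        group_a, group_b = list(group_a), list(group_b)
        if len(group_a) != len(group_b):
            raise ValueError(f"grouping {name!r}: site groups differ in size")
        missing = [s for s in group_a + group_b if s not in ddg_measured.index]
        if missing:
            raise ValueError(f"grouping {name!r}: sites not measured: {missing}")
        x = ddg_measured[group_a].to_numpy()
        y = ddg_measured[group_b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r2 = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
        else:
            r2 = float(stats.pearsonr(x, y).statistic ** 2)
        group_r2[name] = r2
    return AdditivityReport(residuals=residuals, group_r2=group_r2)


def fold_affinity(bt: BindingTable, site_a: str, site_b: str) -> float:
    """Ka(site_a) / Ka(site_b) within one variant's table."""
    for s in (site_a, site_b):
        if s not in bt.data.index:
            raise KeyError(f"site {s!r} not in binding table for {bt.variant_id}")
    return float(bt.data.at[site_a, "ka"] / bt.data.at[site_b, "ka"])
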