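"""Readers and writers for the package's plain-text formats.

Matrices travel as TSV (header row = alphabet, first column = integer
position label), site lists as FASTA or one-sequence-per-line text, peak
tables as TSV with ``#fixed`` comment lines for unrandomised positions, and
binding tables as (site, ka[, dg]) TSV. The canonical multi-variant input is
a *bundle*: a directory of TSV sheets mirroring the supplementary-workbook
layout::

    sheet1_ka.tsv              site, one Ka column per variant
    sheet2_dg.tsv              optional; cross-checked against -RT ln Ka
    sheet4_energy_<V>.tsv      per-variant energy matrix
    sheet5_frequency_<V>.tsv   per-variant in vivo frequency matrix
    sheet6_kld.tsv             optional pairwise-KLD square table

An ``.xlsx`` workbook with sheets named ``Sheet1`` .. ``Sheet6`` in the same
layouts is read through openpyxl/pandas as an optional convenience.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .chromatogram import ChromatogramTable
from .constants import DEFAULT_TEMPERATURE_K
from .energetics import BindingTable
from .matrices import EnergyMatrix, FrequencyMatrix

__all__ = [
    "SupplementaryData",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "read_energy_matrix",
    "write_energy_matrix",
    "read_sites",
    "write_sites",
    "read_peak_table",
    "write_peak_table",
    "read_binding_table",
    "write_binding_table",
    "read_binding_workbook",
]


def _read_matrix_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: matrix TSV needs a position column and >= 2 symbols")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(int)
    df.index.name = "pos"
    return df.astype(float)


def read_frequency_matrix(path: str | Path, n: int | None = None) -> FrequencyMatrix:
    return FrequencyMatrix(_read_matrix_frame(Path(path)), n=n)


def write_frequency_matrix(fm: FrequencyMatrix, path: str | Path) -> None:
    fm.probs.rename_axis("pos").to_csv(path, sep="\t", float_format="%.10g")


def read_energy_matrix(
    path: str | Path, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> EnergyMatrix:
    return EnergyMatrix(_read_matrix_frame(Path(path)), temperature_K=temperature_K)


def write_energy_matrix(em: EnergyMatrix, path: str | Path) -> None:
    em.ddg.rename_axis("pos").to_csv(path, sep="\t", float_format="%.10g")


def read_sites(path: str | Path) -> list[str]:
    """Aligned site list from FASTA (leading '>') or one-sequence-per-line text."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        from Bio import SeqIO

        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip().upper() for line in text.splitlines() if line.strip()]


def write_sites(sites: list[str], path: str | Path, fasta: bool = False) -> None:
    path = Path(path)
    if fasta:
        path.write_text("".join(f">site_{i}\n{s}\n" for i, s in enumerate(sites, 1)))
    else:
        path.write_text("".join(f"{s}\n" for s in sites))


def write_peak_table(ct: ChromatogramTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pos, base in sorted(ct.fixed_positions.items()):
            fh.write(f"#fixed\t{pos}\t{base}\n")
        ct.heights.rename_axis("pos").to_csv(fh, sep="\t", float_format="%.10g")


def read_peak_table(path: str | Path) -> ChromatogramTable:
    path = Path(path)
    fixed: dict[int, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#fixed"):
            _, pos, base = line.split("\t")
            fixed[int(pos)] = base
    heights = _read_matrix_frame(path)
    return ChromatogramTable(heights=heights, fixed_positions=fixed)


def write_binding_table(bt: BindingTable, path: str | Path) -> None:
    bt.data.rename_axis("site").to_csv(path, sep="\t", float_format="%.10g")


def read_binding_table(
    path: str | Path,
    variant_id: str | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> BindingTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    if "site" not in df.columns or "ka" not in df.columns:
        raise ValueError(f"{path}: binding-table TSV needs 'site' and 'ka' columns")
    df = df.set_index("site")
    if variant_id is None:
        variant_id = path.stem
    bt = BindingTable.from_ka(variant_id, df["ka"], temperature_K=temperature_K)
    if "dg" in df.columns:
        drift = np.abs(df["dg"].to_numpy(float) - bt.data["dg"].to_numpy()).max()
        if drift > 1e-3:
            warnings.warn(
                f"{path}: stored dG drifts from -RT ln Ka by up to {drift:.3g} kJ/mol",
                stacklevel=2,
            )
    return bt


@dataclass(frozen=True)
class SupplementaryData:
    """Multi-variant affinity screen: binding tables plus derived matrices."""

    binding_tables: dict[str, BindingTable]
    energy_matrices: dict[str, EnergyMatrix] = field(default_factory=dict)
    frequency_matrices: dict[str, FrequencyMatrix] = field(default_factory=dict)
    kld_table: pd.DataFrame | None = None

    @property
    def variants(self) -> list[str]:
        return list(self.binding_tables)


def _tables_from_ka_frame(
    ka: pd.DataFrame,
    dg: pd.DataFrame | None,
    temperature_K: float,
    source: str,
) -> dict[str, BindingTable]:
    tables: dict[str, BindingTable] = {}
    for variant in ka.columns:
        col = ka[variant].astype(float)
        bad = col.index[~np.isfinite(col) | (col <= 0)].tolist()
        if bad:
            raise ValueError(f"{source}: non-positive or missing Ka for {variant} at {bad}")
        bt = BindingTable.from_ka(variant, col, temperature_K=temperature_K)
        if dg is not None and variant in dg.columns:
            drift = np.abs(
                dg[variant].astype(float).to_numpy() - bt.data["dg"].to_numpy()
            ).max()
            if drift > 1e-3:
                warnings.warn(
                    f"{source}: {variant} dG sheet drifts from -RT ln Ka "
                    f"by up to {drift:.3g} kJ/mol",
                    stacklevel=3,
                )
        tables[variant] = bt
    return tables


def read_binding_workbook(
    path: str | Path, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> SupplementaryData:
    """Load a TSV bundle directory (canonical) or an .xlsx workbook."""
    path = Path(path)
    if path.is_dir():
        return _read_bundle(path, temperature_K)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return _read_xlsx(path, temperature_K)
    raise ValueError(f"unrecognised workbook layout: {path}")


def _read_site_frame(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    if "site" not in df.columns:
        raise ValueError(f"{path}: expected a 'site' column")
    return df.set_index("site")


def _read_bundle(root: Path, temperature_K: float) -> SupplementaryData:
    ka_path = root / "sheet1_ka.tsv"
    if not ka_path.exists():
        raise FileNotFoundError(f"bundle {root} lacks sheet1_ka.tsv")
    ka = _read_site_frame(ka_path)
    dg_path = root / "sheet2_dg.tsv"
    dg = _read_site_frame(dg_path) if dg_path.exists() else None
    tables = _tables_from_ka_frame(ka, dg, temperature_K, str(ka_path))

    energy = {
        p.stem.removeprefix("sheet4_energy_"): EnergyMatrix(
            _read_matrix_frame(p), temperature_K=temperature_K
        )
        for p in sorted(root.glob("sheet4_energy_*.tsv"))
    }
    freq = {
        p.stem.removeprefix("sheet5_frequency_"): FrequencyMatrix(_read_matrix_frame(p))
        for p in sorted(root.glob("sheet5_frequency_*.tsv"))
    }
    kld_path = root / "sheet6_kld.tsv"
    kld = None
    if kld_path.exists():
        kld = pd.read_csv(kld_path, sep="\t", index_col=0)
    return SupplementaryData(tables, energy, freq, kld)


def _read_xlsx(path: Path, temperature_K: float) -> SupplementaryData:
    sheets = pd.read_excel(path, sheet_name=None)
    names = {name.lower().replace(" ", ""): name for name in sheets}

    def get(key: str) -> pd.DataFrame | None:
        return sheets.get(names.get(key))

    ka = get("sheet1")
    if ka is None:
        raise ValueError(f"{path}: no Sheet1 (Ka) found")
    ka = ka.set_index(ka.columns[0])
    dg = get("sheet2")
    if dg is not None:
        dg = dg.set_index(dg.columns[0])
    tables = _tables_from_ka_frame(ka, dg, temperature_K, f"{path}:Sheet1")
    return SupplementaryData(tables)
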