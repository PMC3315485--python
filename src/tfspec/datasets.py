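"""Small bundled datasets: the published MarA variant and specificity tables.

Two tables printed in the source study ship with the package:

* ``binding_domain_variants`` — the functional MarA binding-domain variants
  recovered by in vivo selection against the 'GCA', 'GAA' and 'GAC' target
  sites, with colony counts at two tetracycline stringencies. The residue
  triplets (positions 42-45-46) with their counts as weights are the input
  for the amino-acid selection logos.
* ``specificity_summary`` — per-variant non-specific binding energy dGns
  (kJ/mol), information content of the affinity-derived energy logo and of
  the in vivo selection logo (bits, positions -2..0), and the ratio of in
  vivo information to dGns. The SAR row is marked not confident: its
  specific arm was too noisy for a trustworthy boundary fit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_binding_domain_variants", "load_specificity_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("tfspec.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_binding_domain_variants() -> pd.DataFrame:
    """Selected binding-domain variants with per-stringency colony counts."""
    return _read("binding_domain_variants.tsv")


def load_specificity_summary() -> pd.DataFrame:
    """Published per-variant dGns, information contents, and their ratio."""
    return _read("specificity_summary.tsv")
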