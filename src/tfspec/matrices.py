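"""Frequency and energy matrices, information content, and individual-information scoring.

This is the mathematical core of the package. A :class:`FrequencyMatrix` holds
per-position base probabilities f(b, l) over a declared alphabet — the common
currency of sequence logos, individual-information (Ri) models and motif
divergences. An :class:`EnergyMatrix` holds per-position binding penalties
ddG(b, l) in kJ/mol relative to the consensus base (anchored at 0 in every
column); Boltzmann conversion turns it into the frequency matrix that an
energy logo renders. An :class:`RiModel` holds log-ratio weights in bits, so
that the score of a site, Ri = sum_l Riw(site[l], l), predicts whether the
site is specifically (Ri >= 0) or non-specifically (Ri < 0) bound.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .constants import DNA_ALPHABET, DEFAULT_TEMPERATURE_K, rt

__all__ = [
    "FrequencyMatrix",
    "EnergyMatrix",
    "RiModel",
    "InformationResult",
    "SmallSampleCorrection",
    "frequency_matrix_from_sites",
    "information_content",
    "small_sample_correction",
    "boltzmann_frequencies",
    "ri_weights",
    "score_site",
    "score_sites",
    "enumerate_sites",
    "logo_table",
]

_PROB_TOL = 1e-9
#: finite stand-in for log2(0) in Ri weights when no pseudocount is used
ZERO_PROB_WEIGHT_BITS = -50.0


def _validate_axes(df: pd.DataFrame) -> None:
    alphabet = list(df.columns)
    if len(alphabet) < 2:
        raise ValueError("alphabet must have at least 2 symbols")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet symbols must be unique")
    positions = list(df.index)
    if any(positions[i] >= positions[i + 1] for i in range(len(positions) - 1)):
        raise ValueError("position labels must be strictly increasing")


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base probabilities over a declared alphabet.

    ``probs`` is indexed by integer position label (strictly increasing, may
    be negative) with one column per alphabet symbol; every row sums to 1.
    ``n`` is the effective sample count behind the probabilities, or ``None``
    when unknown (energy- or chromatogram-derived matrices).
    ``semi_quantitative`` flags matrices built from pooled-chromatogram peak
    heights, which only approximate population frequencies.
    """

    probs: pd.DataFrame
    n: int | None = None
    semi_quantitative: bool = False

    def __post_init__(self) -> None:
        _validate_axes(self.probs)
        vals = self.probs.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("probabilities must be finite")
        if (vals < -_PROB_TOL).any():
            raise ValueError("probabilities must be non-negative")
        rowsums = vals.sum(axis=1)
        bad = np.abs(rowsums - 1.0) > _PROB_TOL
        if bad.any():
            pos = list(self.probs.index[bad])
            raise ValueError(f"probabilities do not sum to 1 at positions {pos}")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1 when known")

    @property
    def alphabet(self) -> list[str]:
        return list(self.probs.columns)

    @property
    def positions(self) -> list[int]:
        return list(self.probs.index)

    def select(self, position_range: Sequence[int]) -> "FrequencyMatrix":
        """Restrict to the given position labels (must all be present)."""
        missing = [p for p in position_range if p not in self.probs.index]
        if missing:
            raise KeyError(f"positions not in matrix: {missing}")
        return FrequencyMatrix(
            self.probs.loc[list(position_range)], n=self.n,
            semi_quantitative=self.semi_quantitative,
        )


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-position binding penalties ddG(b, l) in kJ/mol, consensus base = 0.

    The minimum over symbols at every position is exactly 0, so each column's
    zero entry marks that position's consensus base.
    """

    ddg: pd.DataFrame
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        _validate_axes(self.ddg)
        vals = self.ddg.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("ddG values must be finite")
        mins = vals.min(axis=1)
        if (np.abs(mins) > 1e-9).any():
            pos = list(self.ddg.index[np.abs(mins) > 1e-9])
            raise ValueError(
                f"ddG columns must be anchored at 0 (consensus); offending positions {pos}"
            )

    @property
    def alphabet(self) -> list[str]:
        return list(self.ddg.columns)

    @property
    def positions(self) -> list[int]:
        return list(self.ddg.index)

    @property
    def consensus(self) -> str:
        """Lowest-energy symbol at each position (first on ties)."""
        return "".join(self.ddg.idxmin(axis=1))


@dataclass(frozen=True)
class RiModel:
    """Individual-information weight matrix, Riw(b, l) in bits.

    ``correction_bits`` records the small-sample correction e(n) that was
    subtracted from every weight (0 when no correction was applied).
    """

    weights: pd.DataFrame
    correction_bits: float = 0.0

    def __post_init__(self) -> None:
        _validate_axes(self.weights)
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValueError("Ri weights must be finite")

    @property
    def alphabet(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def positions(self) -> list[int]:
        return list(self.weights.index)


def frequency_matrix_from_sites(
    sites: Sequence[str],
    weights: Sequence[float] | None = None,
    pseudocount: float | None = None,
    alphabet: Sequence[str] = DNA_ALPHABET,
    positions: Sequence[int] | None = None,
) -> FrequencyMatrix:
    """Tally an aligned, equal-length site list into a frequency matrix.

    Parameters
    ----------
    sites
        Aligned sequences, all the same length, symbols drawn from ``alphabet``.
    weights
        Optional positive per-site counts (e.g. colony counts for a selected
        binding-domain variant); defaults to 1 per site.
    pseudocount
        Added to every (symbol, position) cell before normalising. ``None``
        uses the Laplace-style default 0.5/|alphabet| appropriate for count
        data, which can contain structural zeros.
    positions
        Position labels; defaults to 1..L.
    """
    if not sites:
        raise ValueError("need at least one site")
    alphabet = list(alphabet)
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("ragged site list: all sites must have equal length")
    if weights is None:
        weights = [1.0] * len(sites)
    weights = [float(w) for w in weights]
    if len(weights) != len(sites):
        raise ValueError("weights must match sites in length")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    if pseudocount is None:
        pseudocount = 0.5 / len(alphabet)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if positions is None:
        positions = list(range(1, length + 1))
    positions = list(positions)
    if len(positions) != length:
        raise ValueError("positions must match site length")

    index = {b: j for j, b in enumerate(alphabet)}
    counts = np.zeros((length, len(alphabet)))
    for site, w in zip(sites, weights):
        for l, b in enumerate(site):
            j = index.get(b)
            if j is None:
                raise ValueError(
                    f"symbol {b!r} at position {positions[l]} is outside the alphabet"
                )
            counts[l, j] += w
    total = sum(weights)
    probs = (counts + pseudocount) / (len(alphabet) * pseudocount + total)
    df = pd.DataFrame(probs, index=positions, columns=alphabet)
    return FrequencyMatrix(df, n=round(total))


@dataclass(frozen=True)
class SmallSampleCorrection:
    """e(n) in bits and the sampling s.d. of a per-position information value."""

    e_bits: float
    sd_bits: float


def small_sample_correction(n: int, alphabet_size: int = 4) -> SmallSampleCorrection:
    """Expected upward bias e(n) of information estimated from n sequences.

    The plug-in entropy of n draws from an equiprobable background
    underestimates log2(k), inflating apparent information by
    e(n) = log2(k) - E[H_obs]. For n <= 12 the expectation (and the variance
    used for the "+/-" on totals) is computed exactly by enumerating
    multinomial outcomes; above that the chi-square asymptotics
    e(n) = (k - 1)/(2 n ln 2), sd = sqrt(k - 1)/(sqrt(2) n ln 2) are used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = int(alphabet_size)
    if k < 2:
        raise ValueError("alphabet_size must be >= 2")
    if n <= 12:
        log_nfact = gammaln(n + 1)
        e_h, e_h2 = 0.0, 0.0
        for comp in _compositions(n, k):
            c = np.asarray(comp, dtype=float)
            logp = log_nfact - gammaln(c + 1).sum() + n * math.log(1.0 / k)
            p = math.exp(logp)
            f = c / n
            h = -(xlogy(f, f).sum()) / math.log(2)
            e_h += p * h
            e_h2 += p * h * h
        e_bits = math.log2(k) - e_h
        var = max(e_h2 - e_h * e_h, 0.0)
        return SmallSampleCorrection(e_bits=e_bits, sd_bits=math.sqrt(var))
    ln2 = math.log(2)
    return SmallSampleCorrection(
        e_bits=(k - 1) / (2 * ln2 * n),
        sd_bits=math.sqrt(k - 1) / (math.sqrt(2) * n * ln2),
    )


def _compositions(n: int, k: int) -> Iterable[tuple[int, ...]]:
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


@dataclass(frozen=True)
class InformationResult:
    """Total information over a position range plus the per-position values."""

    total: float
    per_position: pd.Series
    correction_bits: float = 0.0
    sd_total: float | None = None


def information_content(
    fm: FrequencyMatrix,
    position_range: Sequence[int] | None = None,
    apply_correction: bool | None = None,
) -> InformationResult:
    """Rseq over a position range: sum_l [log2 k - H(l) - e(n)].

    H(l) is the plug-in entropy of column l with 0*log 0 = 0. The
    small-sample correction e(n) is applied per position when
    ``apply_correction`` is true; the default (``None``) applies it exactly
    when ``fm.n`` is known, matching the convention that site-count logos are
    corrected while energy- and chromatogram-derived matrices (n unknown) are
    not. Corrected values may be negative.
    """
    if position_range is None:
        position_range = fm.positions
    position_range = list(position_range)
    if not position_range:
        raise ValueError("position range must be non-empty")
    sub = fm.select(position_range)
    if apply_correction is None:
        apply_correction = fm.n is not None
    k = len(fm.alphabet)
    vals = sub.probs.to_numpy(dtype=float)
    entropy = -(xlogy(vals, vals).sum(axis=1)) / math.log(2)
    per_pos = math.log2(k) - entropy
    e_bits, sd_total = 0.0, None
    if apply_correction:
        if fm.n is None:
            raise ValueError("cannot apply small-sample correction: n is unknown")
        corr = small_sample_correction(fm.n, k)
        e_bits = corr.e_bits
        per_pos = per_pos - e_bits
        sd_total = corr.sd_bits * math.sqrt(len(position_range))
    series = pd.Series(per_pos, index=position_range, name="bits")
    return InformationResult(
        total=float(series.sum()),
        per_position=series,
        correction_bits=e_bits,
        sd_total=sd_total,
    )


def boltzmann_frequencies(em: EnergyMatrix) -> FrequencyMatrix:
    """Convert an energy matrix to frequencies: f(b,l) ~ exp(-ddG(b,l)/RT).

    This is the conversion that turns a measured energy matrix into the
    probability matrix an energy logo displays; the resulting matrix has
    unknown n (no site count stands behind it).
    """
    beta = 1.0 / rt(em.temperature_K)
    w = np.exp(-beta * em.ddg.to_numpy(dtype=float))
    probs = w / w.sum(axis=1, keepdims=True)
    return FrequencyMatrix(
        pd.DataFrame(probs, index=em.positions, columns=em.alphabet), n=None
    )


def ri_weights(
    fm: FrequencyMatrix,
    pseudocount: float = 0.0,
    apply_correction: bool | None = None,
) -> RiModel:
    """Individual-information weights Riw(b,l) = log2 k + log2 f'(b,l) - e(n).

    f' is the pseudocount-regularised frequency. With pseudocount 0, symbols
    of probability 0 get the finite floor ``ZERO_PROB_WEIGHT_BITS`` (-50)
    instead of -inf, preserving ordering while keeping sums finite. The
    correction default mirrors :func:`information_content`.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if apply_correction is None:
        apply_correction = fm.n is not None
    k = len(fm.alphabet)
    f = fm.probs.to_numpy(dtype=float)
    if pseudocount > 0:
        if fm.n is not None:
            f = (f * fm.n + pseudocount) / (fm.n + k * pseudocount)
        else:
            f = (f + pseudocount) / (1.0 + k * pseudocount)
    e_bits = 0.0
    if apply_correction:
        if fm.n is None:
            raise ValueError("cannot apply small-sample correction: n is unknown")
        e_bits = small_sample_correction(fm.n, k).e_bits
    with np.errstate(divide="ignore"):
        w = math.log2(k) + np.log2(f) - e_bits
    w = np.where(np.isneginf(w), ZERO_PROB_WEIGHT_BITS, w)
    return RiModel(
        pd.DataFrame(w, index=fm.positions, columns=fm.alphabet),
        correction_bits=e_bits,
    )


def score_site(rm: RiModel, site: str) -> float:
    """Ri of one site in bits: sum of the matrix weights along the sequence."""
    if len(site) != len(rm.positions):
        raise ValueError(
            f"site length {len(site)} != model length {len(rm.positions)}"
        )
    cols = rm.weights.columns
    total = 0.0
    for pos, b in zip(rm.positions, site):
        if b not in cols:
            raise ValueError(f"symbol {b!r} at position {pos} is outside the alphabet")
        total += float(rm.weights.at[pos, b])
    return total


def score_sites(rm: RiModel, sites: Sequence[str]) -> pd.Series:
    """Vectorised Ri over a site list; returns a Series indexed by site."""
    index = {b: j for j, b in enumerate(rm.weights.columns)}
    w = rm.weights.to_numpy(dtype=float)
    length = len(rm.positions)
    out = np.empty(len(sites))
    for i, site in enumerate(sites):
        if len(site) != length:
            raise ValueError(f"site {site!r} has length {len(site)}, expected {length}")
        try:
            out[i] = sum(w[l, index[b]] for l, b in enumerate(site))
        except KeyError as err:
            raise ValueError(f"symbol {err.args[0]!r} outside the alphabet") from None
    return pd.Series(out, index=list(sites), name="ri_bits")


def enumerate_sites(alphabet: Sequence[str] = DNA_ALPHABET, length: int = 3) -> list[str]:
    """All |alphabet|^length sites, in lexicographic (alphabet-order) order."""
    return ["".join(t) for t in itertools.product(list(alphabet), repeat=length)]


def logo_table(
    fm: FrequencyMatrix, apply_correction: bool | None = None
) -> pd.DataFrame:
    """Letter heights in bits: height(b,l) = f(b,l) * Rseq(l).

    Heights at a position sum to that position's information content; this is
    the table a stacked-letter logo renders.
    """
    info = information_content(fm, apply_correction=apply_correction)
    heights = fm.probs.mul(info.per_position, axis=0)
    return heights
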