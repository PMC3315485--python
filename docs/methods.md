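# Methods

## Model and assumptions

The package analyses a transcription factor's binding-site energy
distribution under the standard independent-and-additive approximation: the
free-energy penalty of a site relative to the factor's strongest (consensus)
site is the sum of independent per-position, per-base penalties,
ΔΔG(s) = Σ_l ΔΔG(s_l, l), with the consensus base contributing 0 at every
position. Binding degenerates with mutation until all sufficiently weak
sites are bound at a common non-specific energy ΔG_ns; the measured
two-state association constant is modelled as

    Ka(s) ∝ exp(−ΔΔG(s)/RT) + exp(−ΔG_ns/RT)

so that measured relative energies saturate at a plateau slightly above
ΔG_ns (the exact plateau is ΔG_ns + RT·ln(1 + exp(−ΔG_ns/RT)) relative to
the consensus; for ΔG_ns ≈ 3.3 kJ/mol at 295 K the saturation error is
≈ 0.57 kJ/mol, always below RT·ln 2 ≈ 1.70 kJ/mol once the consensus
normalisation is included).

Energies use R = 8.314×10⁻³ kJ/(mol·K) and T = 295 K unless a table
declares another temperature; a single constant avoids unit drift across
modules. Ka values are treated as relative (unitless): every derived
quantity depends only on Ka ratios, and ΔΔG rather than absolute ΔG is the
canonical energy throughout.

The sign convention is ΔΔG(s) = ΔG(s) − ΔG(strongest) ≥ 0 — weaker binders
have positive relative energy. If a nominated consensus is outranked by a
measured single mutant, the energy-matrix column is re-anchored to the true
minimum with a warning rather than violating the consensus-at-zero
invariant.

## Information quantities

Per-position information is R_seq(l) = log₂|A| − H(l) − e(n), with H the
plug-in entropy (0·log 0 = 0) and e(n) the small-sample bias correction.
e(n) is the exact expectation of log₂|A| − H over multinomial draws from an
equiprobable background, enumerated exactly for n ≤ 12 (the enumeration
also yields the variance reported as the "± " on totals); for larger n the
chi-square asymptotics e(n) = (|A|−1)/(2n ln 2),
sd = √(|A|−1)/(√2·n·ln 2) are used. The asymptotic sits ≈ 0.007 bits below
the exact expectation at n = 16, which is why the unit test comparing
against a Monte-Carlo oracle uses a 0.02-bit band rather than the oracle's
standard error. The correction is applied by default exactly when a matrix
has a known site count behind it: site-list logos are corrected, while
energy-derived and chromatogram-derived matrices (effective n unknown) are
not. Corrected totals may be negative.

Individual-information weights are Riw(b, l) = log₂|A| + log₂ f(b, l) −
e(n). With pseudocount 0, zero-probability symbols receive a finite −50-bit
floor instead of −∞, preserving site ordering while keeping sums finite.
Default pseudocounts: 0 for energy-derived frequencies (Boltzmann
probabilities are never zero) and 0.5/|A| for count-derived matrices, which
can contain structural zeros.

Position labels follow the binding-site coordinate frame of the assays: the
varied core triplet is −2, −1, 0, with fixed flanks (forced T and G) at
−4, −3 in selection constructs.

## Boundary regression

Sites are partitioned at Ri = 0 with ties assigned to the specific side
(Ri ≥ 0 is the conventional definition of a specifically bound site).
Ordinary least squares of ΔΔG on Ri is fit to each side; ΔG_ns is the ΔΔG
value at the crossing of the two lines ("intersection", the default), with
the specific line's Ri = 0 intercept ("ri0-intercept") as the documented
alternative and as the automatic fallback for parallel lines. The wording
of the original description is ambiguous between the two readings, so both
are implemented behind a recorded switch; resolving the ambiguity against
the published per-variant table requires the full measured screen (see
Limitations). Estimates are flagged untrustworthy when the specific arm has
fewer than 4 points or r² < 0.3. Plain OLS only — no robust or
errors-in-variables variants, since the quantity being replicated was
defined by plain regression.

## Motif divergence

Column divergence defaults to the symmetrised ½[D(p‖q) + D(q‖p)] in bits
after adding a 10⁻⁶ pseudocount and renormalising; the matrix value is the
mean over aligned columns. Because the historical comparison tool's exact
normalisation (sum vs mean, natural vs base-2 logarithm, one-sided vs
symmetrised) is not pinned down, all of these are explicit switches with
the defaults recorded in the pipeline configuration and manifest; no
numeric similarity cutoff is hardcoded. Shift search is off by default (all
matrices here share the −2..0 frame); when enabled it requires ≥ 2
overlapping columns per tested offset and reports the offset minimising the
aggregate.

## Synthetic study conditions

The generator's defaults are the package's canonical study conditions,
chosen once from the scale of the real system: a 3-position varied core
(64-site library), non-consensus penalties gamma-distributed with mean
4.0 kJ/mol and s.d. 1.5 kJ/mol (penalties of roughly 1–2 RT, giving
moderately specific energy logos), non-specific floor ΔG_ns = 3.3 kJ/mol
(mid-range of the measured per-variant boundary energies, 2.40–4.46
kJ/mol), and multiplicative log-normal Ka noise with σ = 0.1. Selections
survive sites with true ΔΔG below the stringency cutoff and weight
survivors by exp(−ΔΔG/RT); peak heights are survivor frequencies times a
scale, optionally multiplied by a preceding-base bias factor in
[1 − b, 1 + b] and perturbed by truncated Gaussian trace noise. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: cell growth and plasmid copy
number, arabinose induction dynamics, position-dependent measurement error
(noise is i.i.d. across sites), dye- and context-dependent Sanger peak
calibration beyond the single preceding-base factor, and any real
dinucleotide coupling unless explicitly injected. Passing round-trip tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to every artefact of the wet assays.

Note one structural subtlety the tests exploit: under an additive truth
model with no stringency truncation the survivor population factorises
across positions, so a preceding-base peak bias cancels out of per-position
marginals; the bias is only visible when truncation correlates neighbouring
positions.

## Verification conditions and observed recovery

The self-contained end-to-end checks run at the canonical conditions above
(truth matrix drawn at seed 0; 100 noise replicates; 1000 random column
pairs for the divergence axioms; full 64-site enumeration for Ri). Under
them, the noise-free floor-free round trip reproduces the truth matrix and
its Boltzmann-logo information to numerical precision; the noise-free
boundary estimate lands within the RT·ln 2 saturation bound of the true
floor; and the mean boundary estimate over the 100 noisy replicates stays
within 0.2 kJ/mol of it. The residual positive bias of the intersection
estimator comes from the two-state saturation plateau, not from noise, and
varies with the truth draw; the acceptance script reports it for
whatever truth matrix its seed generates.

## Numerical choices

Probability rows must sum to 1 within 10⁻⁹; energy columns must reach 0
within 10⁻⁹ (exact re-anchoring after construction kills float dust).
Lexicographically smallest site wins exact affinity ties, with a warning.
Grouped additivity correlations define r² = 1 for two zero-variance vectors
that match after centring and 0 otherwise; expression–affinity correlation
is defined as 0 (with a warning) when either variable has zero variance.
Degenerate regressions (no Ri variance) and empty survivor sets raise
informative errors rather than producing NaNs.

## Limitations

The four acceptance checks tied to the published five-variant × 64-site
screen (per-variant information contents and ΔG_ns, printed divergences,
the RQR site ordering, and the in vivo overlap structure) need the
supplementary workbook, which is deposited separately from the text; they
run against a local TSV mirror under `data/supplementary_s1/` and fail
with an explanatory message in its absence. Chromatogram-derived matrices
are flagged semi-quantitative and should be read as such: peak height is
only a proxy for population frequency. The amino-acid logo support uses
the same machinery as DNA logos (generic alphabets), but no
structure-aware analysis is attempted.
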