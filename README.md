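# tfspec

Thermodynamic and information-theoretic analysis of transcription-factor
binding specificity, built around the kind of data a protein-variant binding
study produces: relative association constants for a small helix-turn-helix
factor (MarA and its binding-domain variants) against a complete library of
binding-site variants, and pooled-population Sanger chromatograms from in
vivo survival selections.

## What it computes

Given one variant's association constants Ka over a site library, the
package derives

* binding free energies, ΔG = −RT ln Ka (R = 8.314×10⁻³ kJ/(mol·K),
  T = 295 K by default), and relative energies
  ΔΔG(s) = ΔG(s) − ΔG(s*) ≥ 0 with s* the strongest site;
* the single-mutant **energy matrix** ΔΔG(b, l) (consensus base anchored at
  0 in every column) and its additivity diagnostics, including grouped
  dinucleotide correlations that expose coupling between positions;
* the **energy logo**: Boltzmann conversion
  f(b, l) ∝ exp(−ΔΔG(b, l)/RT) and the information content
  R_seq = Σ_l [log₂|A| − H(l) − e(n)], with the small-sample correction
  e(n) computed by exact multinomial enumeration for n ≤ 12;
* **individual information** weights Riw(b, l) = log₂|A| + log₂ f(b, l) −
  e(n), site scores Ri = Σ_l Riw(site_l, l), and the two-regression
  estimate of the **non-specific binding energy** ΔG_ns: ordinary least
  squares of ΔΔG on Ri fit separately to specific (Ri ≥ 0) and non-specific
  (Ri < 0) sites, with ΔG_ns read off at the crossing of the two lines;
* symmetrised, column-averaged **Kullback–Leibler divergences** between
  motif models, and quadrant **overlap summaries** of two variants' Ri
  scores over the full site library;
* **selection logos** from chromatogram peak heights (peak height divided
  by summed heights per position), with unrandomised positions carried as
  fixed columns;
* reference-normalised reporter **expression ratios** (tet/marA) and their
  correlation with binding strength.

A seeded synthetic generator (`tfspec.simulate`) emulates the whole
measurement process — an additive ground-truth energy matrix, a two-state
Ka with a flat non-specific floor, log-normal measurement noise, and
Boltzmann-weighted survival selections rendered as peak tables — so every
stage of the pipeline is testable against known ground truth.

## Worked example

```python
from tfspec import (SyntheticTruth, analyze_binding_table, random_energy_matrix,
                    simulate_mitomi)

truth = SyntheticTruth(truth_matrix=random_energy_matrix(seed=0),
                       dg_ns_true=3.3, noise_sigma=0.1, seed=0)
table = simulate_mitomi(truth, variant_id="SYN")     # 64-site Ka table
va = analyze_binding_table(table)                    # full single-variant chain

print("consensus site:   ", va.energy_matrix.consensus)
print("energy-logo bits: ", round(va.information_bits, 2))
print("dGns estimate:    ", round(va.boundary.dg_ns, 2), "kJ/mol   (truth 3.3)")
print("specific-arm r2:  ", round(va.boundary.fit_pos.r2, 2))
```

prints

```
consensus site:    TGG
energy-logo bits:  0.35
dGns estimate:     3.28 kJ/mol   (truth 3.3)
specific-arm r2:   0.83
```

The boundary regression recovers the 3.3 kJ/mol non-specific floor to
within 0.02 kJ/mol here. The apparent energy logo (0.35 bits) is flatter
than the truth logo (1.21 bits) because measured single-mutant penalties
saturate near the floor — exactly the distortion the two-regression
boundary analysis is designed to quantify.

A `tfspec` command-line tool exposes the same chain as subcommands
(`energetics`, `boundary`, `compare`, `logos`, `overlap`, `simulate`,
`run`); `tfspec run --binding-input <bundle>` writes per-variant boundary
reports, energy matrices, divergence tables, overlap summaries and a
manifest with input hashes and every convention switch.

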