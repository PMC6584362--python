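# ovimorph

Cell-resolution morphometrics, intercalation statistics and a closed-form
length model for epithelial plates, built around the question of how the
*Drosophila suzukii* ovipositor became ~1.6× longer than that of
*D. melanogaster* without any change in cell number.

The package is aimed at quantitative developmental biologists who have
segmented apical cell outlines (polygon tables or labeled-mask TIFFs) of a
flat epithelium and want to decompose the tissue's dimensions into cellular
parameters, plus a fully synthetic ground-truth generator so that every
stage of the analysis can be validated without microscope data.

## The model at the core

A plate of `N` cells — `n` per row along the proximo-distal (PD) axis, `m`
per column (`N = nm`) — with tissue anisotropy `σ = n/m` has
`n = √(Nσ)` cells along its length. Cells are summarized by the
moment-equivalent ellipse of each outline: apical area `a`, axis ratio
`s = l₂/l₁ ≥ 1`, with `l₁ = 2√(a/πs)` and `l₂ = 2√(as/π)`. With about half
the cells presenting their long axis to the PD direction, the mean cell
extent along the plate is `Lc = √(a/πs) + √(as/π)`, and the plate length is

```
L = √(N σ a / π) · (√s + 1/√s)
```

Between-species divergence is expressed by coefficients
`k_N, k_σ, k_a, k_s` (target/reference parameter ratios); applying subsets
of them to the reference parameters ranks each cellular process's
contribution to the length change. Around this model the package provides:

- **`ovimorph.synthetic`** — exact hexagonal tessellations with
  controllable `n, m, a, s`, PD-aligned fraction and vertex jitter; growth
  series with scheduled area expansion and row/column count changes;
  tracked movies with scripted stable/oscillating T1 events; SMA-consistent
  log-log allometry tables; labeled-mask rasterization.
- **`ovimorph.morphometrics`** — exact polygon areas and interior-moment
  ellipse fits, PD-alignment classification (45° rule), density-corrected
  total counts, three-transect row/column counts, tissue anisotropy.
- **`ovimorph.intercalation`** — shared-boundary neighbor graphs, T1
  neighbor-exchange detection with stable/oscillating classification,
  convergence/divergence axes and the average nematic tensor
  `θn = ½·atan2(Q2, Q1)`.
- **`ovimorph.allometry`** — standardized major axis fits with slope CIs
  and the between-group common-slope likelihood-ratio test.
- **`ovimorph.length_model`** — the equation above, coefficient derivation
  and the contribution decomposition.
- **`ovimorph.io` / `ovimorph.cli`** — CSV/TIFF/JSON round-trips and a thin
  `ovimorph` command with `simulate-plate`, `simulate-movie`, `measure`,
  `t1`, `allometry` and `model` subcommands.

## Worked example

`examples/` contains one short script per capability. Generating a plate at
the *D. melanogaster* 54 h APF study conditions and measuring it back
(`python examples/01_synthetic_plate.py`) prints:

```
cells segmented:        1305
corrected total N:      1305
mean cells per row n:   45.0
mean cells per col m:   29.3
tissue anisotropy sigma: 1.53   (n/m; target 45/29 = 1.55)
mean apical area a:     11.68 um^2 (target 11.68)
mean shape ratio s:     1.58    (target 1.57)
PD-aligned fraction:    52%   (target ~52%)
```

i.e. the measurement pipeline recovers the generator's ground truth. The
length-model decomposition (`python examples/05_length_model.py`) prints:

```
model length, D. melanogaster 54 h APF:  196.8 um
model length, D. suzukii      54 h APF:  328.9 um
fold change: 1.67

melanogaster parameters transformed by coefficient subset:
     reference:  196.8 um ( 59.9% of the suzukii estimate)
   N+sigma+a+s:  326.6 um ( 99.3% of the suzukii estimate)
       a+sigma:  331.4 um (100.8% of the suzukii estimate)
             N:  195.3 um ( 59.4% of the suzukii estimate)
         sigma:  249.1 um ( 75.7% of the suzukii estimate)
             a:  261.9 um ( 79.6% of the suzukii estimate)
             s:  195.5 um ( 59.4% of the suzukii estimate)
```

Reading: cell-area expansion (`a`) and anisotropic reorganization (`σ`)
together transform the *D. melanogaster* plate into the *D. suzukii*
length; cell number and cell shape contribute essentially nothing.

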