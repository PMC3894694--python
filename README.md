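# qpiscreen

Label-free quantitative phase imaging (QPI) for phenotypic drug screening:
a simulation and analysis toolkit covering the whole chain from physical
image formation to assay-quality statistics.

Transparent cells barely absorb light but delay its phase. Digital
holographic microscopy (DHM) and transport-of-intensity (TIE) imaging turn
that delay into a quantitative map of the **optical path difference**

```
OPD(x, y) = d(x, y) · (n_c − n_m)
```

where `d` is the cell thickness, `n_c` the mean intracellular refractive
index and `n_m` the index of the culture medium. Because OPD is an absolute
physical quantity — proportional to cell thickness and dry-mass density —
it supports threshold segmentation and unbiased morphological readouts that
qualitative contrast techniques (phase contrast, DIC) cannot provide.

The package is aimed at people developing or validating high-content
screening analysis on QPI data: it generates seeded synthetic plates with
drug-induced phenotypes, images them through physical forward models,
reconstructs phase, and evaluates screen quality, so every analysis step can
be checked against known ground truth.

## What's inside

| Module | Purpose |
| --- | --- |
| `qpiscreen.synth` | Seeded OPD phantoms: 96-well plates, 4 fields/well, 12–16 wells/condition, 25–60% confluency, three phenotypes (elongated control, round high-OPD, vesicle-bearing), two cell-type contrast regimes, 4PL dose structure, 10-min/24-h time-lapse |
| `qpiscreen.optics` | Angular-spectrum propagation; off-axis hologram synthesis (684 nm); 3-plane defocused bright-field stacks (740 nm, z = −5/0/+5 µm) |
| `qpiscreen.dhm` | Hologram demodulation: carrier detection, sideband filtering, numerical refocus, unwrapping, background flattening |
| `qpiscreen.tie` | Transport-of-intensity solver (regularized spectral inverse Laplacian, mirror padding) and modality comparison metrics |
| `qpiscreen.metrics` | Confluency mask, cell counting (3-px Gaussian blur + prominent maxima), total/average OPD |
| `qpiscreen.phenotype` | Per-cell segmentation (threshold + watershed), intensity/shape/texture/granularity features, boosted-tree phenotype classifier, error-corrected phenotype fractions |
| `qpiscreen.stats` | Well aggregation, Z'-factor, time-lapse AUC, 4PL dose-response fits (EC50), onset detection |
| `qpiscreen.pipeline` / `qpiscreen.cli` | YAML-configured end-to-end screen driver and the `qpiscreen` command line |
| `qpiscreen.experiments` | Reference screen experiments (endpoint Z', dual-phenotype EC50 comparison, onset recovery) |

Key statistics, in the field's notation: the assay window is judged by the
Z'-factor `Z' = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|` over 12–16 replicate
wells; dose-response is the variable-slope four-parameter logistic
`y = bottom + (top − bottom)/(1 + 10^((log EC50 − log c)·hill))` fitted by
least squares to per-well time-lapse AUCs, with the vehicle plotted two
logs below the lowest dose.

## Worked example

```python
import numpy as np
from qpiscreen import (synthesize_hologram, reconstruct_hologram,
                       place_cells, render_field, field_metrics)
from qpiscreen.experiments import endpoint_zprime

# 1. simulate a field mixing control and rounded cells, and measure it
cells = place_cells(["control"] * 12 + ["round"] * 6, field_size=(256, 256),
                    rng=0, min_separation_um=27.0)
phase = render_field(cells, field_size=(256, 256), seed=0)
fm = field_metrics(phase)
print(f"cells placed: {len(cells)}   counted: {fm.cell_count}")
print(f"confluency: {fm.confluency:.3f}   average OPD: {fm.average_opd_nm:.1f} nm")

# 2. image it through the holographic forward model and reconstruct
recon = reconstruct_hologram(synthesize_hologram(phase))
err = (recon.opd - phase.opd)[32:-32, 32:-32]
print(f"reconstruction RMSE: {np.sqrt(((err - err.mean())**2).mean()):.2f} nm")

# 3. assay quality of an endpoint screen (16 wells x 4 fields per arm)
z = endpoint_zprime("hela", seed=1)
print(f"Z' (high-contrast line): {z.z_prime:.2f}   "
      f"window {z.mu_neg:.1f} -> {z.mu_pos:.1f} nm")
```

prints

```
cells placed: 17   counted: 17
confluency: 0.072   average OPD: 54.1 nm
reconstruction RMSE: 3.00 nm
Z' (high-contrast line): 0.81   window 45.9 -> 76.9 nm
```

The 17 resolvable cells are all recovered by blur-and-find-maxima counting;
the average OPD of 54 nm reflects the mix of flat control cells (~46 nm)
and rounded ones; the holographic round trip returns the field to 3 nm
(about the injected read noise); and the endpoint screen of a strong
rounding phenotype yields an excellent screening window (Z' > 0.5) on the
average-OPD readout.

The same steps are available from the shell:

```bash
qpiscreen simulate --seed 3 --out sim/
qpiscreen reconstruct dhm --in holo.tif --out phase.tif
qpiscreen metrics --in sim/plate1_A01_0_0.tif
qpiscreen train --cell-type hela --out model.pkl
qpiscreen classify --model model.pkl --in sim/plate1_A01_0_0.tif
qpiscreen screen --config screen.yaml --out out/
```

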