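# ramangt

Quantification of the physical state of intracellular lipids from
silent-region Raman hyperspectral images of cells treated with deuterated
fatty acids.

## The problem

Carbon-deuterium (C-D) stretch bands of deuterated palmitate sit in the
Raman "silent region" (~1800-2600 cm⁻¹), where endogenous cellular signals
are negligible. The shape of the C-D band reports the conformational state
of the labeled acyl chains: looser lipid packing (lower viscosity) raises
the fraction of C-C-C-C dihedral positions in *gauche* (φ ≈ ±60°) rather
than *trans* (φ ≈ 180°) conformation. `ramangt` turns hyperspectral C-D
images into per-pixel maps of

1. a **lipid mixing ratio** *x* — the unsaturated/saturated phospholipid
   ratio (PC18:1/PC16:0) whose in vitro reference spectrum best explains the
   pixel, and
2. the **gauche/trans ratio** of the labeled chains, obtained from *x*
   through a kinetic saturation model calibrated on model-membrane
   simulations,

together with quality masking, scan-line artifact removal, and lipid
droplet (LD) / non-LD segmentation with per-region statistics. It is aimed
at microscopists and image analysts working with deuterium-labeled Raman or
SRS data. No public dataset accompanies the original measurement campaign,
so the package ships a first-class synthetic-data module that generates
every input with known ground truth.

## The model

**Reference family.** Normalized in vitro spectra of phospholipid mixtures
at ratios x′ = 0.0, 0.5, …, 8.0 (9-10 replicates each) define, per spectral
channel *s*, a regression fₛ(x): a piecewise-cubic Hermite interpolant
(PCHIP, shape-preserving derivative rule) with five free knot values at
x̃ = [0, 2, 4, 6, 8], fitted by least squares (RSS₁). Stacking channels
gives a continuous reference spectrum **y**ₓ on the 210-channel
2000-2300 cm⁻¹ window.

**Unmixing.** Each measured pixel spectrum **m** is decomposed as

    m ≈ α·y_x + β·b + γ·s + δ·1,   α, β ≥ 0,

with background spectrum **b** (a designated background pixel), channel
ramp **s**, and offset **1**. The amplitudes are profiled out exactly for
any x (active-set enumeration of the two sign constraints); x minimizes the
profiled residual RSS₂ via a 0.05-step grid plus bounded refinement. Pixel
quality is gated on SNR₂ = ‖α·y_x‖²/RSS₂ > 100.

**Conformational conversion.** Treating gauche/trans interconversion of
saturated chains as two competing pseudo-reactions catalysed by the two
lipid species gives, at equilibrium,

    g/t(x) = p + r·xⁿ/(q + xⁿ),

fitted to (composition, gauche/trans) points from bilayer simulations at 12
compositions. A coordinate-level dihedral analyzer (signed two-plane
convention, gauche iff |φ| ≤ 120°, pooled counts) supplies such points from
chain geometries.

**Image quantification.** Scan-line artifacts are detected by windowed
cosine similarity (3×31 row template, threshold 0.7, flagged pixels
extended ±10 px); LDs are segmented from the signal-intensity image by
median-background subtraction (kernel 21), a fixed 5×5 center-surround
convolution, a 2-5 px Fourier bandpass, and a threshold of 5× the modal
intensity of the 0-255-rescaled result.

## Worked example

```python
import numpy as np
from ramangt import synthetic_data as sd, reference_builder as rb
from ramangt import gauche_trans as gt, image_quant as iq

# in vitro reference family (17 ratio levels x 10 replicates) and its fit
family = sd.make_reference_family(sd.ReferenceFamilySpec(seed=0))
dataset = rb.ReferenceDataset.from_family(family)
model = rb.build_reference_model(dataset)

# kinetic saturation model from simulated composition points
x_md, y_md = sd.make_kinetic_points(p=0.15, q=0.8, r=0.26, n=1.0)
kinetic = gt.fit_kinetic(x_md, y_md)
print(f"kinetic fit: p={kinetic.p:.3f}  q={kinetic.q:.3f}  r={kinetic.r:.3f}")

# 64x64x210 phantom with three LD discs and one scan-line artifact
cube, truth = sd.make_phantom_cube(sd.PhantomSpec(seed=0), model)
result = iq.run_pipeline(cube, model, kinetic, truth.bg_pixel)
print(result.stats.round(3).to_string(index=False))
```

prints

```
kinetic fit: p=0.150  q=0.800  r=0.260
region  n_pixels  mean_x  median_x  sd_x  mean_gt  median_gt  sd_gt  area_fraction
    ld        39   0.599     0.504 0.143    0.260      0.250  0.014           0.01
non_ld      3908   3.031     3.030 0.056    0.356      0.356  0.001           0.99
```

The kinetic parameters are recovered exactly from the noiseless points. The
LD region (39 px, the three discs) averages a saturated-lipid-rich mixing
ratio near its ground truth of 0.6 and a low gauche/trans ratio (~0.26,
tighter chain packing), while the cytosol sits at x ≈ 3.0 with a
gauche/trans ratio of ~0.36, near the curve's plateau — the LD/non-LD
contrast the method is designed to expose. The scan-line row is excluded
from both regions by the artifact mask.

A thin CLI mirrors the library:
`ramangt simulate refs|cube|chain|kinetic`, `ramangt build-ref`,
`ramangt fit-kinetic`, `ramangt gt-ratio`, `ramangt quantify`,
`ramangt convert`, `ramangt crop`.

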