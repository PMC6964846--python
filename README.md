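# fiberorient

Quantification of fiber orientation distributions in noisy greyscale images
by uncertainty-adaptive Fourier filtering.

Images of fibrous structures — collagen in second-harmonic-generation (SHG)
microscopy of skin, electrospun scaffolds, textiles — carry their directional
information in the 2D power spectrum: a fiber oriented at angle θ produces a
spectral streak perpendicular to it. Extracting a quantitative orientation
distribution from the spectrum of a *noisy* image requires deciding which
spectrum bins are signal and which are noise. `fiberorient` makes that
decision from the measurement uncertainty itself: the per-pixel
photon-counting uncertainty ΔI = √I is propagated through the discrete
Fourier transform (including the real–imaginary covariance) into an
uncertainty ΔP of every power-spectrum bin, and only bins whose *relative*
uncertainty ΔP/P stays below a cutoff δ_cut are kept. The filter is
anisotropic and adaptive by construction — no assumptions about fiber
diameter or band-pass radii.

The full pipeline for one image is

1. **periodic–smooth decomposition** (Moisan) — removes the cross-shaped DFT
   boundary artifact without windowing away image content;
2. **DFT with uncertainty propagation** — Δℜ, Δℑ, their covariance, and
   ΔP = 2√(ℜ²Δℜ² + ℑ²Δℑ² + 2ℜℑ·Cov);
3. **adaptive mask** — keep bins with ΔP/P ≤ δ_cut (default 2.1%) at radius
   ≥ 3 px from the DC bin;
4. **angular distribution** — area-weighted radial summation of the masked
   spectrum into 1° orientation wedges, each wedge amplified by N^α
   (N = kept bins in the wedge, α = 1.5 by default), normalized to
   ΣI(θ) = 1;
5. **quantification** — fit the circularized sigmoid
   S_circ(θ; b, θ̄) = S(θ) + S(θ+180°) − S(180°) + S(θ−180°) − S(−180°),
   with S the logistic with slope b, to the cumulative distribution C(θ).
   θ̄ is the mean fiber orientation, b the dispersion (larger b = tighter
   alignment).

A Monte-Carlo simulator of greyscale fiber images (von Mises-distributed
orientations, controlled width, aspect ratio, and speckle noise, with exact
ground truth) supports calibration of (δ_cut, α) and validation of the
recovered θ̄ and b, and a Monte-Carlo noise-replication harness verifies
every step of the uncertainty propagation empirically.

## Worked example

Simulate one 256×256 image of width-4, aspect-ratio-20 fibers with von Mises
concentration k = 3 and medium noise, then analyze it:

```sh
fiberorient simulate --k 3 --width 4 --ar 20 --nf 0.5 --n 1 --size 256 \
    --seed 5 --out demo/
fiberorient analyze demo/fibers_0000.tif --out demo/
```

The analyze step prints

```
theta_bar = 53.10 deg, b = 0.0938 /deg, R^2 = 0.9989, kept bins = 1596
```

and writes the angular distribution (CSV) and the fit (JSON). For this image
the simulator's ground truth (`demo/fibers_0000_reference.json`) gives a
reference orientation θ̄_ref = 52.05° and dispersion b_ref = 0.0944 /deg,
fitted to the sampled fiber angles: the pipeline recovered the mean
orientation within ~1° and the dispersion within ~1%, keeping only 1596 of
65536 spectrum bins. R² ≈ 0.999 says the circular sigmoid describes the
cumulative distribution almost perfectly.

The same `analyze` command applies unchanged to real 8/16-bit greyscale
TIFF/PNG images (e.g. 512×512 SHG recordings of dermal collagen).

## Library use

```python
from fiberorient import SimulationConfig, simulate, analyze_image

bundle = simulate(SimulationConfig(k=5.0, theta_bar=30.0, seed=42))
result = analyze_image(bundle.image)          # delta_cut=2.1%, alpha=1.5
print(result.fit.theta_bar, result.fit.b, result.fit.r_squared)
```

All intermediates (power spectrum, mask, angular and cumulative
distributions) are exposed on the result object; see `docs/methods.md` for
the model, parameter meanings, and numerical choices.

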