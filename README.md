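# msmdenoise

Feature-based denoising of fluorescence microscopy images.

Fluorescence microscopy images suffer from mixed Poisson–Gaussian noise:
photon shot noise scaled by the detector gain `g0` plus additive Gaussian
read-out noise of standard deviation `σ`,

    b = g0·z + ε,   z ~ Poisson(v/g0),   ε ~ N(0, σ²),

so `E[b] = v` and `Var[b] = g0·v + σ²`.  This package denoises such
images in two stages:

1. **Multifractal feature extraction.**  A multiscale measure
   `μ(x, r) ≈ α(x)·r^d(x)` of the noisy image is computed by convolving
   its gradient magnitude with unnormalised radial kernels
   `Ψ_γ(x) = (1 + |x/r|²)^(−γ)`, γ = 1…4, at small scales
   `r ∈ {1,…,5}` px.  The per-pixel singularity exponent `d(x)` is the
   slope of a log–log regression across scales; the pixels with the
   smallest exponents form the **most singular manifold (MSM)** — an
   edge-like set carrying the sharpest, least noise-corrupted
   transitions of the image.
2. **Gradient-domain reconstruction.**  The image gradients are zeroed
   outside the MSM and the denoised image is recovered by solving the
   tensor-weighted discrete Poisson equation
   `div(J∇v) = div(J·ĝ)` with homogeneous Neumann boundary conditions,
   where `J` is a per-pixel SPD diffusion tensor (from the structure
   tensor of the presmoothed image) that diffuses along, not across,
   edges.

The package also ships the noise simulator, a synthetic multichannel
cell-image phantom generator (clustered elliptical cells with nuclei
and subcellular particles — so everything is testable without
downloads), evaluation metrics (MSE, PSNR, radially averaged residual
power spectral density) and a CLI.  See `docs/methods.md` for the full
model description and numerical choices.

## Worked example

```python
import numpy as np
import msmdenoise as md

spec = md.PhantomSpec(height=128, width=128, n_cells=8, n_clusters=3,
                      cell_radius_range=(10.0, 16.0), seed=1)
truth = md.generate_phantom(spec)
clean = truth.image.channels                          # (3, 128, 128) in [0, 1]

noisy = md.add_noise_multichannel(clean, g0=0.1, sigma=0.1, seed=7)
den = md.denoise(noisy, md.DenoiseConfig())           # MSM quantile 0.25

for c, name in enumerate(truth.image.channel_names):
    print(f"{name:10s}  noisy {md.psnr(clean[c], noisy[c]):5.2f} dB"
          f" -> denoised {md.psnr(clean[c], den[c]):5.2f} dB")
```

prints

```
cytoplasm   noisy 13.53 dB -> denoised 14.40 dB
nucleus     noisy 17.44 dB -> denoised 19.26 dB
particles   noisy 18.89 dB -> denoised 21.03 dB
```

i.e. at the highest benchmark noise level (`g0 = σ = 0.1`) the pipeline
improves PSNR by 1–2 dB per channel on this phantom; the corresponding
residual PSD curves (see `md.residual_psd`) drop below the noisy input's
across most of the upper frequency range, where noise lives.  With a
full mask and the identity tensor (`msm_quantile=1.0`,
`use_identity_tensor=True`) the pipeline reproduces its input to
machine precision — the self-consistency check of the whole
discretisation.

The same pipeline from the shell:

```sh
msmdenoise simulate-phantom --width 512 --height 512 --cells 20 \
    --clusters 3 --particles 4 --seed 1 --out clean.tif
msmdenoise add-noise --g0 0.1 --sigma 0.1 --seed 7 --in clean.tif --out noisy.tif
msmdenoise denoise --in noisy.tif --out denoised.tif
msmdenoise evaluate --truth clean.tif --test denoised.tif --out-json report.json
msmdenoise benchmark --size 128 --n-datasets 5 --seed 0 --out bench.json
```

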