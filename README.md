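# dwdc

Extraction of filament-like cytoskeletal structures — e.g. microtubule
networks — from noisy, blurred confocal fluorescence z-stacks.

Confocal images of fine cytoskeletal filaments suffer simultaneously from
diffraction blur (the PSF is wider than the ~25–63 nm structures) and strong
fluorescence background noise. Denoising and deconvolution algorithms each
address one of these; applied alone to a low-SNR image, deconvolution tends
to amplify noise into spurious structure. This package implements a
composite chain that does both, for researchers processing fluorescence
z-stacks of filamentous structures:

1. **Gaussian-interpolation expansion** — the stack is up-sampled (typically
   4× per axis) by normalized Gaussian-weighted interpolation with lateral
   radius r⊥ = 0.61 λₑ/NA and axial radius r∥ = 4 n λₑ/(2 NA²), reducing the
   pixel pitch (250 nm → 62.5 nm for the reference system).
2. **Wavelet scale-band extraction** — a 2D discrete wavelet transform
   (Coiflet-3, 6 orders) decomposes each slice; only the detail orders
   n ∈ [n_l, n_h] whose dyadic scales 2^n span the filament width are kept
   (orders 4–6 for 16–64 px structures). High-frequency noise and
   low-frequency illumination gradients are discarded with the other bands.
3. **Probability-density binarization** — the band image is thresholded at
   the value χ retaining the brightest fraction (default 15%) of its
   structure pixels, giving the logic matrix of the filament outline.
4. **Accelerated damped Richardson–Lucy deconvolution** — the *logic matrix*
   (not the intensity image) is deconvolved against a Gaussian PSF of radius
   Δr = ξ·r⊥ (ξ ≈ 2.5, k_max = 10 iterations, damping 0.01), shrinking the
   outline toward the filament skeleton. Deconvolving the binary outline
   prevents bright structures from bleeding into faint ones.
5. **Secondary binarization and masking** — the deconvolved matrix is
   thresholded at χ = 1 and the final image is the elementwise product
   M_F = M_e × mask: extraction, never rescaling.

The package also ships a synthetic ground-truth generator (sparse bundles of
curved 63 nm filaments, degraded by 270 nm Gaussian blur plus additive
Gaussian noise) so the whole chain is verifiable without microscope data.

## Worked example

```python
import dwdc

# a synthetic field of six 63 nm filaments at 63 nm pitch, and its corruption
truth = dwdc.generate_ground_truth(dwdc.PhantomSpec(seed=1))
degraded = dwdc.degrade(truth, dwdc.DegradationSpec(
    blur_radius_nm=270, noise_mean=40, noise_std=10, seed=10008))

# the full chain as a scikit-learn transformer (phantom already at fine
# pitch, so the expansion stage is bypassed)
est = dwdc.DWDC(expansion_factor_xy=1, expansion_factor_z=1, pitch_xy_nm=63.0)
restored = est.fit(degraded.data).transform(degraded.data)

t, d, r = truth.data[0], degraded.data[0], restored[0]
print(f"PSNR {dwdc.psnr(t, d):.2f} -> {dwdc.psnr(t, r):.2f} dB")
print(f"SSIM {dwdc.ssim(t, d):.4f} -> {dwdc.ssim(t, r):.4f}")
```

prints

```
PSNR 15.31 -> 24.55 dB
SSIM 0.0028 -> 0.9372
```

i.e. at the harshest noise condition (background mean 40, STD 10 on the
8-bit-equivalent scale) the restored image gains ~9 dB of PSNR and its
structural similarity to the clean truth rises from essentially zero to
above 0.93, because the noise floor is removed entirely while the surviving
pixels keep their measured intensities.

The same chain is available from the shell:

```sh
dwdc phantom --size 1024 --seed 1 --noise-mean 40 --noise-std 10 \
     --out-truth truth.tif --out-degraded degraded.tif
dwdc run --input degraded.tif --pitch-xy-nm 63 --out restored.tif
dwdc metrics --ref truth.tif --test restored.tif
dwdc benchmark --seeds 1,2,3,4,5 --out report.tsv
```

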