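# fpmnet

Fourier ptychographic microscopy (FPM) in Python: a physics-based image
formation simulator, classical iterative phase retrieval, and a residual
hybrid attention network (RHAN) that maps one-sweep low-resolution complex
amplitude reconstructions to high-resolution intensity and phase images.

## The problem

FPM trades acquisition time for space-bandwidth product: a low-NA objective
keeps a wide field of view while a programmable LED array (here 13 × 13,
λ = 505 nm, 100 mm below the sample) illuminates the sample from many
angles. Each LED shifts the sample spectrum, so each low-resolution
intensity capture samples a different disc (radius NA/λ, NA = 0.13) of
frequency space. Spectrum-stitching phase retrieval then recovers the
high-resolution *complex* transmission — amplitude and quantitative phase —
by iteratively replacing estimated sub-aperture moduli with measured ones:

    for each LED i:   ψ_i ← √I_i · ψ_i/|ψ_i|,
                      Ô[k_i] ← P · F{ψ_i}   (inside the pupil P)

Iterative solvers are slow and degrade under noise. The RHAN alternative
runs the iterative solver for a *single* sweep, encodes the result as a
2-channel (intensity, phase) image, and feeds it to a residual network whose
blocks combine spatial attention (multi-dilation convolutions, sigmoid
spatial gate) with channel attention (squeeze-and-excitation with Leaky
ReLU), trained with an SSIM loss. This package implements the whole
pipeline — simulator, GS/AS classical baselines, procedural dataset
generator, network (with RCN/RSN ablation variants), training, and the
optimizer / ablation / noise-robustness experiment harnesses — in plain
numpy/scipy, including a compact gradient-checked autodiff engine for the
network. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from fpmnet import (OpticsGeometry, generate_hr_pair, channels_to_complex,
                    bandlimit_field, simulate_stack, gs_reconstruct,
                    initialize_spectrum, stack_error, spectral_overlap,
                    ssim, align_global_phase)

geom = OpticsGeometry(hr_size=64)            # 13x13 LEDs, NA 0.13, 505 nm
print(f"adjacent-pupil overlap: {spectral_overlap(geom):.2f}")

# procedural complex object, limited to the synthetic-aperture passband
hr = generate_hr_pair(64, seed=3, style="blobs")
obj = bandlimit_field(channels_to_complex(hr, geom.hr_pixel), geom)

stack = simulate_stack(obj, geom, noise_sigma=3e-4, seed=0)
print(f"captures: {stack.images.shape}")

recon = gs_reconstruct(stack, n_iter=50)
e0 = stack_error(initialize_spectrum(stack), stack)
print(f"data-fidelity error: {e0:.2e} -> {recon.error_history[-1]:.2e}")

amp_t, amp_r = np.abs(obj.values), np.abs(recon.field.values)
s = np.sum(amp_r * amp_t) / np.sum(amp_r ** 2)
print(f"amplitude SSIM: {ssim(s * amp_r / amp_t.max(), amp_t / amp_t.max()):.3f}")
ph = align_global_phase(recon.field.values, obj.values)
print(f"phase SSIM: {ssim(np.angle(ph), np.angle(obj.values), data_range=2*np.pi):.3f}")
```

Output:

```
adjacent-pupil overlap: 0.81
captures: (169, 16, 16)
data-fidelity error: 8.07e-02 -> 4.35e-04
amplitude SSIM: 0.962
phase SSIM: 0.995
```

The 169 noisy 16 × 16 captures are stitched into a 64 × 64 complex field:
50 sweeps cut the data-fidelity error by two orders of magnitude and recover
both amplitude and (gauge-aligned) phase with SSIM > 0.95. With
`noise_sigma=0` the error drops to ~1e-24 and both SSIMs reach 1.000.

The same pipeline from the shell:

```bash
fpmnet simulate  --preset desk --seed 1 --out stack.npz
fpmnet reconstruct --method gs --iters 50 --in stack.npz --out recon.npz
fpmnet make-dataset --preset desk --seed 1 --out data/
fpmnet train --preset desk --data data/ --seed 1 --out model.npz
fpmnet evaluate --model model.npz --data data/ --out report.json
fpmnet experiment ablation --preset desk --seed 1 --out ablation.csv
```

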