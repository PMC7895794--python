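# mrnlm — multiple-reconstruction non-local means for emission tomography

PET (and SPECT) images are noisy, and the standard clinical remedy —
post-reconstruction Gaussian smoothing — buys noise suppression with
signal loss and quantification bias. Non-local means (NLM) filtering does
better by averaging voxels whose surrounding *patches* look alike, but its
performance hinges on finding genuinely similar patches inside a single
image. Because raw PET data can be reconstructed many times with different
iteration/subset settings, one can instead harvest patches from multiple
*reconstructions of the same acquisition*: each auxiliary image shows the
same anatomy under a different noise realisation. This package implements
that multiple-reconstruction NLM filter (MR-NLM) together with the
conventional NLM, Gaussian and bilateral baselines, a digital hot-sphere
(Jaszczak) phantom with a pseudo-reconstruction emulator, and the
image-quality metrics used to compare them. It is aimed at researchers in
PET image processing who want a reproducible, scriptable test bed for
patch-based post-filtering.

## The filter

For voxel $n$ the denoised value is the normalised weighted mean

$$V_n = \frac{1}{N_n}\sum_{m\in\Omega_n} f_m\,
        \exp\!\left(-\frac{\lVert P(v_n)-P(v_m)\rVert^2}{h^2}\right),
\qquad
\lVert P(v_n)-P(v_m)\rVert^2=\sum_{k=1}^{|v|}\left(f_{n(k)}-f_{m(k)}\right)^2,$$

with $P(v)$ the patch of intensities around a voxel (default 5×5 in-plane),
$h$ the smoothing parameter and $N_n$ the sum of the weights.

* **Conventional NLM:** $\Omega_n$ is a spatial search window centred on
  $n$ (default 11×11×3 voxels, clipped to the volume).
* **MR-NLM:** $\Omega_n$ is replaced by the *co-located* position in each
  auxiliary reconstruction — every auxiliary contributes one candidate
  (its voxel at $n$) weighted by the similarity of its patch to the
  target's patch; the target's own voxel enters with weight 1.

Patch distances are computed on intensities normalised by the target's
global maximum; the averaging acts on raw intensities, so every output is
a convex combination of observed values.

Evaluation uses the usual VOI statistics: contrast-to-noise ratio
$\mathrm{CNR}=|\mu_s-\mu_{bg}|/\sqrt{(\sigma_s^2+\sigma_{bg}^2)/2}$,
signal-to-noise ratio
$\mathrm{SNR}=\frac{1}{N_s}\sum_k(\mu_{s(k)}-\mu_{bg(k)})/\sigma_{bg(k)}$,
and quantification bias in percent against the known activity (phantom) or
the unfiltered image (clinical-style), plus a paired t-test across VOIs.

## Worked example

```python
from mrnlm.config import RunConfig
from mrnlm.experiment import run_phantom_experiment

reports, cal = run_phantom_experiment(1, config=RunConfig(seed=1))
for name, rep in reports.items():
    print(f"{name:12s} SNR={rep.snr:6.2f}  smallest-sphere bias={rep.rows['bias'].iloc[0]:7.2f}%")
```

prints (seed 1):

```
none         SNR= 24.79  smallest-sphere bias= -32.70%
gaussian     SNR= 65.61  smallest-sphere bias= -53.95%
nlm          SNR= 89.69  smallest-sphere bias= -32.71%
mrnlm        SNR= 88.18  smallest-sphere bias= -32.98%
mr_average   SNR= 90.53  smallest-sphere bias= -32.86%
```

The driver generates the 5:1 hot-sphere phantom (six spheres,
11.89–33.27 mm, 2×2×3 mm voxels), emulates the 2i:21s target plus twelve
auxiliary reconstructions, then calibrates the Gaussian FWHM (from the
conventional 2–9 mm range) and the NLM `h` so both reach the same
background-VOI noise as MR-NLM before comparing. Read: the unfiltered
image has SNR ≈ 25 and a −33 % partial-volume bias on the smallest sphere;
at matched residual noise the Gaussian filter more than doubles SNR but
drags the small-sphere bias past −50 %, while the patch-based filters
suppress noise without additional signal loss. (In this stationary
synthetic noise world the windowed NLM averages more samples than 13
co-located reconstructions, so MR-NLM does not out-SNR it here; see
`docs/methods.md` for why that differs from real scanner data.)

The same pipeline is scriptable from the shell:

```sh
mrnlm run --config config.yaml --out out/ --seed 1      # full pipeline
mrnlm generate-phantom --out data/ --seed 1             # volumes + masks only
mrnlm denoise --target data/target.nii.gz --aux-dir data/ --method mrnlm --h 0.3 --out f.nii.gz
mrnlm evaluate --target data/target.nii.gz --aux-dir data/ \
    --masks data/masks.nii.gz --truth data/truth.nii.gz --out report.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the default phantom dataset from scratch at the given seed,
runs the matched-smoothing method comparison, prints the SNR/bias table
and writes the machine-readable results file.
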