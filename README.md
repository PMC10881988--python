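# prmsrs — penalized reference matching for hyperspectral Raman/SRS images

`prmsrs` identifies chemical subtypes — primarily lipids — in label-free
hyperspectral stimulated Raman scattering (SRS) images by scoring every
pixel spectrum against a library of pure-standard reference spectra. It is
aimed at microscopists and image analysts who have (a) a hyperspectral
stack (rows × cols × bands, typically the CH-stretching window
2700–3150 cm⁻¹ sampled every ~6 cm⁻¹) and (b) reference spectra of the
compounds they expect (cholesterol, triacylglycerides, phospholipids, ...),
and who want per-pixel subtype score maps, ratiometric images, and
unmixing baselines without any staining or instrument-specific software.

## The method

Plain spectral angle mapping scores a pixel spectrum against a reference
by cosine similarity, but small wavenumber calibration offsets between
instruments (and chemical-environment peak shifts) depress true matches
and — worse — unrestricted re-alignment inflates false ones. Penalized
reference matching (PRM) scores over an explicit grid of spectral offsets
Δx with a quadratic penalty:

    score = max_i ( u · v_i − α Δx_i² )

where **u** is the pixel spectrum and **v**_i the reference displaced by
Δx_i along the wavenumber axis (zero-padded/trimmed at the edges), both
preprocessed identically: optional arPLS baseline correction, linear
interpolation to a common 1 cm⁻¹ grid, min–max scaling
I₁ = (I − I_min)/(I_max − I_min), then division by the Euclidean norm.
The penalty coefficient α (units cm², default 1 × 10⁻⁴) makes a 21 cm⁻¹
offset cost exactly α·21² = 0.0441 score units: genuine matches survive
small calibration drift while distant spurious alignments are suppressed.
For nonnegative spectra the score lies in [0, 1] — unlike pseudo-inverse
(PINV) least-squares unmixing coefficients, which are unbounded and may be
negative; PINV is included as a comparison baseline.

The scorer is exposed as a scikit-learn transformer (`PRMScorer.fit` on a
reference library, `.transform` on an (n_pixels, n_bands) matrix), with
thin functional wrappers (`prm_score`, `score_stack`, `score_stack_multi`)
and a CLI (`prm`). Downstream products: ratiometric maps, threshold masks,
top-percentile pixel-spectrum extraction, channel merges, structural
similarity / NMSE agreement metrics, and four-Gaussian CH-band
decomposition of reference spectra (canonical centers 2850, 2880, 2935,
3065 cm⁻¹).

## Worked example

Everything runs on synthetic fixtures with known ground truth — no
downloads. A two-phase stack (left half one lipid-like phase, right half
another, 1% noise, 2 cm⁻¹ spectral jitter) scored against three built-in
standards:

```python
import prmsrs as P

pcfg = P.PreprocessConfig()                 # 2700-3150 cm^-1 grid, 1 cm^-1
lib = P.make_library()                      # three lipid-like standards

spec = P.SimSpec(seed=0, shape=(16, 16), layout="two_phase",
                 noise_sd=0.01, jitter_sd=2.0)
stack, truth = P.make_stack(spec)           # 16x16x75 bands at 6 cm^-1

images = P.score_stack_multi(stack, lib, pcfg, P.PRMConfig(alpha=1e-4))
for name, img in images.items():
    print(f"{name:10s} mean score {img.scores.mean():.3f} "
          f"(left half {img.scores[:, :8].mean():.3f}, "
          f"right half {img.scores[:, 8:].mean():.3f})")

ratio = P.ratio_image(images["tag_like"], images["pe_like"])
print(f"tag/pe ratio: left {ratio.values[:, :8].mean():.2f}, "
      f"right {ratio.values[:, 8:].mean():.2f}")
```

prints

```
tag_like   mean score 0.897 (left half 0.998, right half 0.795)
pe_like    mean score 0.900 (left half 0.802, right half 0.999)
chol_like  mean score 0.934 (left half 0.963, right half 0.905)
tag/pe ratio: left 1.24, right 0.80
```

The left phase was generated from the CH₂-dominant `tag_like` standard and
scores ~1.0 against it despite per-pixel brightness randomization, noise
and jitter (shape, not intensity, drives the score); the right phase
matches `pe_like`. The ratiometric image separates the phases
independently of overall signal strength. The same pipeline from the
shell:

```sh
prm --seed 0 simulate --layout two_phase --shape 16x16 --noise 0.01 --jitter 2 --out fix/
prm score --stack fix/stack.tif --axis fix/axis.json --ref fix/tag_like.csv \
    --alpha 1e-4 --out tag_score.tif
prm score --stack fix/stack.tif --axis fix/axis.json --ref fix/pe_like.csv \
    --alpha 1e-4 --out pe_score.tif
prm ratio --num tag_score.tif --den pe_score.tif --out tag_over_pe.tif
```

Every CLI run writes a JSON manifest (config, input hashes, version, seed)
next to its output; reruns are byte-identical.

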