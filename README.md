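# mnfstream

Line-by-line **minimum noise fraction (MNF)** denoising for push-broom
(line-scanning) hyperspectral images, alongside the conventional
full-image transform.

Push-broom cameras build an image one cross-track line at a time.  MNF is
the standard covariance-based denoiser for hyperspectral data, but it
normally needs the *whole* image before it can estimate the image and
noise covariances.  `mnfstream` removes that requirement: per arriving
line it merges numerically stable incremental statistics, re-solves the
MNF eigenproblem on a configurable cadence, and denoises the line with the
current matrix — so denoised spectra are available *during* the scan, and
the per-line matrices converge to exactly the batch solution by the end of
the image.  Intended users: people processing line-scan hyperspectral data
(biomedical imaging, remote sensing, industrial inspection) who want
noise-free spectra in a streaming pipeline.

## The transform

For a `B x P` image `Y` with additive noise, zero-meaned to `Z`, the MNF
basis solves the generalized eigenproblem on the noise and image
covariances

```
Σ_N ā = λ Σ ā ,        SNR_j = 1/λ_j − 1
```

with eigenpairs sorted by ascending λ (descending SNR).  Keeping the first
`r` components in the inverse transform gives the denoising matrix

```
D = (A⁻¹)ᵀ R Aᵀ ,      Z* = D Z
```

where `R` zeroes the last `B − r` diagonal entries.  `D` acts on each
pixel spectrum independently, which is what makes a streaming variant
possible: the stream maintains running means and co-moment matrices
(merged with cancellation-safe pairwise updates), estimates `Σ_N` from
within-line differences of adjacent samples, and applies the current `D_i`
to each line.  See `docs/methods.md` for the full model, conventions and
numerical details.

## Worked example

Simulate the block-structured skin phantom (a 200 x 240 x 80 cube of
twelve smooth skin-like reflectance spectra in a 4 x 3 block grid, with
Gaussian noise of variance 1e-4), stream-denoise it, and score the result:

```console
$ mkdir demo && mnfstream simulate --out demo --scale ci --sigma2 0.0001 --seed 1
wrote demo/noisy_sigma2_0.0001.img
wrote demo/clean.img and 1 noisy cube(s)

$ mnfstream denoise --input demo/noisy_sigma2_0.0001.img --output demo/denoised.img \
      --mode stream --r 3 --k 1 --eigentable demo/eig.csv --report demo/report.json
denoised 200 lines -> demo/denoised.img (r=3 of 80)

$ mnfstream eval --a demo/noisy_sigma2_0.0001.img --b demo/clean.img
{"mean_sam_rad": 0.019537192756217063, "median_sam_rad": 0.019499632932374257, "lines": 200}

$ mnfstream eval --a demo/denoised.img --b demo/clean.img --out demo/profile.csv
{"mean_sam_rad": 0.00320132699262358, "median_sam_rad": 0.0030453079558511132, "lines": 200}
```

Reading the numbers: the noisy cube sits a mean spectral angle of
~0.0195 rad from the noise-free reference; after streaming MNF with the
three high-SNR components retained the mean angle drops to ~0.0032 rad —
about a 6x improvement, most of which is reached within the first tens of
lines of the stream.  `demo/eig.csv` lists every component's eigenvalue,
SNR and cumulative conserved-signal fraction (the three retained
components conserve ~99.3% of the signal); `demo/profile.csv` holds the
per-line SAM profile, where transient peaks right after each 50-line block
boundary show the stream adapting to newly appearing spectra.

Batch mode (`--mode batch`) runs conventional full-image MNF; `--warmup N
--freeze-after-warmup` accumulates N lines, solves the eigenproblem once
and streams with that fixed matrix; `--k 10` re-solves every 10th line.
The same functionality is available as a library
(`mnfstream.denoise_batch`, `mnfstream.LineByLineDenoiser`,
`mnfstream.stream_lines` / `write_lines` for ENVI I/O).

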