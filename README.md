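# dmif — deep medical image fusion

`dmif` fuses two registered medical images of the same anatomy — CT with
MRI, MR-T1 with MR-T2, or grayscale MRI with pseudo-color PET/SPECT —
into a single image that keeps the complementary content of both: bone
and implant structure from CT, soft-tissue detail from MRI, functional
activity and its color from PET/SPECT.  It is aimed at people building
or evaluating fusion pipelines who need a self-contained, deterministic
reference implementation with objective quality metrics and synthetic
test data, entirely offline.

## Method

Each source image `X` (intensities on [0, 1]) is decomposed by latent
low-rank representation,

    min ||Z||* + ||L||* + λ||E||₁   s.t.  X = XZ + LX + E,

solved by inexact ALM with singular value thresholding.  `XZ` is the
structural (low-rank) part, `LX` the salient detail part, `E` sparse
noise.  The structural parts of the two sources are fused by a
weighted average whose per-pixel weights come from multi-layer
convolutional features (channel ℓ1 norm, 3×3 block average, ratio
normalization across sources, nearest-neighbor upsampling), with a
pixel-wise maximum over the three layer candidates.  The salient parts
are fused by a sum rule, `H = I₁ˢ + I₂ˢ`.  The fused image is
`R = clip(G + H)`; the noise parts are dropped.  A color source is
handled by fusing its BT.601 luma and re-attaching its chroma.

Four quality indexes are included: **SD** (contrast), **EN** (entropy,
bits), **Q_MI** (entropy-normalized mutual information, range [0, 2]),
and **Q_PC** (product of correlations between phase-congruency maps of
the fused image and of the sources, range [−1, 1]).  Phase congruency
is computed with a 4-scale, 6-orientation log-Gabor bank.

See `docs/methods.md` for the full model, parameter meanings and
limitations.

## Worked example

```sh
dmif phantom --pair ct_mri --size 128 --seed 7 --out pair/
dmif fuse -a pair/ct_mri_7_1.png -b pair/ct_mri_7_2.png -o fused.png --report report.json
dmif metrics -a pair/ct_mri_7_1.png -b pair/ct_mri_7_2.png -f fused.png
```

The `metrics` command prints:

```
SD    83.6978
EN    5.2493
Q_MI  0.8258
Q_PC  0.5058
```

Read: the fused image has higher contrast (SD 83.7) and more histogram
information (EN 5.25 bits) than either phantom source (SD 74.8/59.0,
EN 4.19/4.98 for this seed), carries a Q_MI of 0.83 out of 2 from its
sources, and preserves phase-congruency detail with Q_PC 0.51.  The
same numbers land in `report.json`.  In Python:

```python
from dmif import FusionConfig, fuse_pair, make_phantom_pair, PhantomSpec, metric_report

ct, mri = make_phantom_pair(PhantomSpec(size=(128, 128), modality_pair="ct_mri", seed=7))
result = fuse_pair(ct, mri, FusionConfig(lambda_=0.8))
print(metric_report(ct, mri, result.fused).as_dict())
```

`result` also exposes the per-source decompositions, the weight maps
and the fused structural/salient components.

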