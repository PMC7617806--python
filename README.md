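# colocq

Quantification pipeline for two-channel 3D confocal fluorescence stacks and
gel-lane densitometry, built around the analysis used to ask whether two
proteins — e.g. the LINE-1 retrotransposon protein ORF2p and the cytoplasmic
poly(A)-binding protein PABPC — occupy the same cytoplasmic puncta, and
whether a binding-interface mutant (such as the 5xPIE alanine substitutions)
abolishes that colocalization.

## What it computes

**Segmentation.** Each channel `I` of a z-stack is band-pass filtered with a
difference of Gaussians, `f = G_{σ₁}(I) − G_{σ₂}(I)` with σ₁ = 1 and σ₂ = 4
pixels (applied per z-slice by default), and thresholded globally at

    t = mean(f) + 2·sd(f)

over all voxels of the filtered stack, giving a 3D binary mask of blob-like
regions per channel. No morphological cleanup is applied.

**Colocalization.** From the two raw channels A, B and their masks the
intensity-weighted Manders overlap coefficients are

    M_A = Σ_{v ∈ mask_A ∩ mask_B} I_A(v) / Σ_{v ∈ mask_A} I_A(v)
    M_B = Σ_{v ∈ mask_A ∩ mask_B} I_B(v) / Σ_{v ∈ mask_B} I_B(v)

— the fraction of each channel's in-mask intensity lying in the mask
intersection. Per-condition results (n = 10 fields by default) are summarized
as boxplot statistics (mean, median, SD, SEM, min, max).

**Densitometry.** 1D gel-lane profiles are integrated per band (trapezoid
rule over a user-supplied window, after subtracting a linear baseline joining
the window endpoints and clipping at zero), the band of interest (e.g. PCNA)
is normalized to a reference band (e.g. ORF2p), and replicate ratios are
reported as mean ± SEM (sample SD / √n, triplicate design).

**Synthetic scenes.** Because the pipeline's correctness can only be judged
against known ground truth, the package includes a generator that renders
two-channel stacks of Gaussian puncta with a programmable colocalized
fraction, background, noise and positional jitter, plus synthetic gel lanes
with bands of known integrated area. Every generated dataset carries its
ground truth, so the whole chain is testable end to end.

## Worked example

Run the built-in two-condition experiment (10 scenes per condition; a
wild-type-like condition with colocalized fraction 0.9 against a 5xPIE-like
condition with 0.1):

```sh
$ colocq run-experiment --seed 1 --out results/demo
5xPIE-like: mean m_a=0.091 mean m_b=0.091 (n=10)
wild-type-like: mean m_a=0.808 mean m_b=0.807 (n=10)
outputs in results/demo
```

The high-colocalization condition yields mean Manders coefficients near 0.8
while the low-colocalization condition stays near 0.09 — the synthetic
analogue of colocalization being lost in a binding-deficient mutant. The
output directory contains `results.csv` (per-scene coefficients, mask sizes,
thresholds, flags), `summary.csv` (per-group boxplot statistics),
`boxplot.png` and a `run_record.json` whose config snapshot reproduces the
run bit-identically.

Single stacks work the same way from files:

```sh
$ colocq simulate --shape 8,128,128 --n-a 12 --n-b 12 --coloc-fraction 0.9 \
      --seed 7 --out sim
$ colocq coloc --in sim/scene.ome.tif --out coloc
scene.ome: m_a=0.829546219571076 m_b=0.8225893152561085 flags=[]
```

and `colocq segment` / `colocq gelquant` expose the segmentation and
densitometry stages individually. From Python:

```python
from colocq import SyntheticSceneSpec, generate_scene, analyze_pair

pair, truth = generate_scene(SyntheticSceneSpec(coloc_fraction=0.9, seed=1))
result = analyze_pair(pair)      # result.m_a, result.m_b, mask sizes, flags
```

A coefficient with a zero denominator (no in-mask signal) is reported as
undefined with a reason flag, never silently coerced to 0.

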