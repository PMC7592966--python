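# hepaseg

Automatic segmentation of the liver and of liver tumors in
contrast-enhanced abdominal CT, for researchers who need reproducible
liver/lesion masks (surgical-planning research, tumor-burden studies,
segmentation-method benchmarking) without a GPU.

The method is a two-stage cascade that combines learning with a
model-based refinement:

1. **Liver:** axial slices are windowed to −50…250 HU and
   median-filtered, then a 2D U-Net (19 convolutional layers at the
   default configuration, sigmoid output, trained with the soft Dice
   loss) predicts a per-pixel liver probability; the thresholded
   prediction is refined per slice by a localized region-based
   (Chan-Vese-type) level set.
2. **Tumors:** the liver region of interest is cropped, enhanced with 3D
   edge-enhancing diffusion (EED), and a second U-Net predicts tumors
   inside the liver envelope, again refined by the localized level set.

The refinement evolves the embedding φ of the predicted contour by

    φ ← φ + dt · δ_ε(φ) · [ (I − u_x)² − (I − v_x)² + μ·κ ]

where `u_x`, `v_x` are local interior/exterior mean intensities within a
ball of radius `r` around each boundary point and `κ` is curvature — the
localized form of the Chan-Vese energy
`E = μ·length(C) + ∬_in (I−c1)² + ∬_out (I−c2)²`. Accuracy is reported
as Dice per case, `Dice(A,B) = 2|A∩B| / (|A|+|B|)`.

Everything is testable without external data: a phantom generator
renders synthetic abdominal CT volumes (bright quasi-ellipsoidal liver,
darker lesions, air/soft-tissue/bone surroundings, noise) with exact
ground-truth masks. See `docs/methods.md` for the full model and
parameter account.

## Worked example

```python
from hepaseg.phantom import PhantomSpec, generate_phantom
from hepaseg.levelset import evolve, LevelSetParams
from hepaseg.evaluation import dice
from hepaseg.preprocess import hu_window
from scipy import ndimage

vol, liver, tumor = generate_phantom(PhantomSpec(seed=5))
print(vol.shape, int(liver.sum()), int(tumor.sum()))
# (128, 128, 48) 64258 1248

# refine a deliberately 3-px-dilated liver outline on one windowed slice
k = 24
img = hu_window(vol).voxels[:, :, k]
coarse = ndimage.binary_dilation(liver.voxels[:, :, k], iterations=3)
refined = evolve(img, coarse, LevelSetParams(max_iters=200))
print(round(dice(coarse, liver.voxels[:, :, k]), 3),
      round(dice(refined, liver.voxels[:, :, k]), 3))
# 0.907 1.0
```

The first line reports the phantom grid and the liver/tumor voxel
counts; the second shows the level set pulling a coarse (dilated)
contour back onto the true liver boundary, raising the slice Dice from
0.907 to 1.0.

The same machinery scales to the full cascade:

```bash
hepaseg phantom --n 50 --seed 7 --out data/
hepaseg train --stage liver --data data/ --out liver.npz
hepaseg train --stage tumor --data data/ --out tumor.npz
hepaseg segment --input data/case_0000/volume.nii.gz --out-dir pred/case_0000
hepaseg evaluate --pred pred/ --truth data/ --out report.csv
```

`segment` writes `liver.nii.gz`, `tumor.nii.gz`, the unrefined
`*_unet.nii.gz` masks and a `provenance.json` with every parameter used.

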