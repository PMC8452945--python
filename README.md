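# coro3d

Automatic 3D reconstruction of a coronary artery from two single-plane
X-ray angiography (XCA) views.

Invasive angiography delivers high-resolution 2D projections of the
contrast-filled coronary lumen, but physiological indices such as computed
FFR need the 3D vessel. Reconstructing it from two views acquired at
different gantry angles (LAO/RAO, CRA/CAU) requires knowing, for every
centerline point in view 1, its partner in view 2 — and the classic epipolar
constraint is ambiguous exactly where it matters most: foreshortened or
overlapping vessel segments. `coro3d` implements a template-model approach
to that correspondence problem, embedded in a complete pipeline for
interventional-imaging researchers:

1. **2D segmentation** — multiscale Hessian (Frangi) vesselness enhances the
   dark vessel, a threshold + connected-component step yields a mask, and a
   fast-marching minimal path between the vessel's two endpoints, with front
   speed `F(x) = D(x) + ε` (`D` = distance to the wall), extracts a centered
   centerline; diameters come from normal ray-casting to the two borders.
2. **Template correspondence** — an averaged, length-normalized 3D
   centerline of the artery type (LAD / LCX / RCA) is projected into both
   acquisition geometries; the fraction of projected arc length
   `r_k(i) = s_k(i) / L_k` at each of its `n = 100` equidistant points picks
   the matching points on the two segmented centerlines.
3. **Back-projection triangulation** — each pair `(p₁, p₂)` is lifted to 3D
   as the point on the view-1 source ray whose view-2 projection is closest
   to `p₂` (closed form: foot of the perpendicular on the epipolar line).
   Patient table panning between the acquisitions is a rigid in-table-plane
   shift `(t_x, t_z)` estimated by least squares; 2D diameters are converted
   to millimetres via the local perspective magnification `M = SDD / depth`.
   The mean ± SD of the view-2 residuals is the ADPS2 accuracy metric.

A synthetic phantom module generates coronary-like 3D centerlines, template
libraries, and rendered biplane image pairs with known ground truth,
table panning, and noise — the package needs no external data.

## Worked example

Generate a synthetic LAD case (20 mm lateral / 10 mm axial table panning,
image noise SD 0.02) and reconstruct it:

```bash
coro3d phantom --artery LAD --seed 7 --panning 20 10 --noise-sd 0.02 -o demo
coro3d run --config demo/case.yaml
```

prints

```json
{
  "n_points": 100,
  "length_mm": 66.346,
  "adps2": {
    "mean_px": 4.586919398374162,
    "sd_px": 3.9503522847613066,
    "n": 100
  },
  "panning": {
    "tx_mm": 19.999999999971543,
    "tz_mm": 9.999999999978964,
    "residual_rms_px": 6.05352068972264,
    "fitted": true
  },
  "output_dir": "/tmp/demo/out"
}
```

(the output directory is resolved relative to the config file's location).

The injected table shift is recovered essentially exactly (the vessel's two
endpoints are exact correspondences and pin it down), the reconstructed
centerline has 100 points over 66 mm, and the ADPS2 of ~4.6 px reflects the
residual mismatch between the population template and this particular
vessel's foreshortening — the intrinsic accuracy limit of template matching.
`demo/out/` contains the per-view masks and centerlines (CSV), the 3D
centerline `centerline3d.csv` (mm, isocenter-origin frame), STL/OBJ surface
meshes, and `report.json` with all parameters used.

Other subcommands: `coro3d segment` (one view), `coro3d template build`
(average a model library into a template CSV), `coro3d reconstruct`
(run a case config). The YAML case schema is written by `coro3d phantom`
and documented by example in `demo/case.yaml`.

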