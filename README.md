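# knottrack

Segmentation and tracking of single, highly curved, **self-intersecting**
filaments in fluorescence-microscopy time series.

In gliding assays where one end of a microtubule (or actin filament) is
clamped while surface motors drive the rest, the filament beats in
flagella-like waves and its 2-D projection can cross itself. Standard
filament trackers assume simple, often rod-like contours and lose the
filament at the crossing. `knottrack` resolves such "knots": it maps
each thinned skeleton to a graph of junction (Vb) and segment (Vf)
vertex groups, enumerates candidate start-to-end walks under a physical
traversal rule, converts them to ordered contours, and selects the one
closest — under dynamic time warping — to the previous frame's resolved
contour (the template).

The package is self-contained for testing: it includes a synthetic
image-formation model (traveling-wave filament contours, diamond
dilation, Gaussian PSF, SNR-controlled noise) and the accuracy metrics
used to score results against ground truth.

## Method at a glance

Per frame:

1. **Segment** — saturate 1% intensity tails, 3x3 median filter, Otsu
   (or fixed) threshold, largest component, Chan–Vese active-contour
   refinement, medial-axis skeletonization with spur pruning and tip
   restoration.
2. **Classify** — branch pixels are skeleton pixels whose 3x3 Moore
   sum (center included) is ≥ 4. Unbranched skeletons are ordered
   directly by geodesic distance from the tracked tip.
3. **Map to a graph** — 8-connected groups of branch / non-branch
   pixels become Vb / Vf vertices; edges record their adjacency, with
   parallel edges where the filament merges with itself.
4. **Resolve** — enumerate walks (each segment once, junctions
   revisitable, edges once per direction; beam-capped at 10 per
   expansion), convert to contours, and minimize the DTW cost

       D(i,j) = |S_i − R_j| + min(D(i−1,j−1), D(i−1,j), D(i,j−1))

   against the template R.

Track-level analysis yields per-frame filament length, tip tangent
angle, and end-to-end distance; tip-angle dynamics are summarized by a
tangent-angle kymograph and an FFT amplitude spectrum (clamped
filaments beat at a few millihertz).

Accuracy is quantified by a tolerance-based Dice index (true positive
= detected pixel within 2 px of truth), per-pixel position error, and
the discrete Fréchet distance, which is sensitive to contour ordering
and is exactly zero only for identically ordered duplicates.

## Worked example

Simulate a 30-frame beating filament (12 µm, amplitude 2.2 rad, period
200 s, 10 s frame interval, SNR 10 dB), then track it:

```
$ knotsim --length-um 12 --amplitude 2.2 --wavelength-um 15 \
          --period-s 200 --frames 30 --dt-s 10 --curl 0.6 \
          --snr-db 10 --seed 1 --out demo.tif
wrote 30 frames to demo.tif
```

Write a parameter file (one ROI per line) and run the resolver:

```
$ cat myParams_optimized.csv
image_path,out_dir,intensity_threshold,ac_iterations,contraction_bias,smooth_factor,start_x,start_y,manual_check,pixel_size_um,dt_s
demo.tif,demo_out,auto,10,0.0,0.2,60.0,60.0,,0.1,10.0
$ knotresolve --params myParams_optimized.csv
processed 1 ROI(s)
```

`demo_out/demo_statsSummary.txt` holds the input parameters followed by
one row per resolved frame — frame number, filament length (µm), tip
angle (rad), end-to-end distance (µm):

```
# columns: frame length tip_angle_rad end_to_end
0 11.9604 -1.6753 8.3180
1 11.9724 -1.6545 8.5322
2 11.8430 -1.2596 8.9926
3 11.8326 -0.8507 9.2859
4 11.8975 -0.3238 9.3589
```

The length column stays at the true 12 µm to within ~1%, and the tip
angle and end-to-end distance oscillate with the generator's 200 s
period (20 frames). Because the simulator wrote a ground-truth CSV
alongside the stack, a benchmark report is produced too; it can also
be computed explicitly:

```
$ knotbench --pred demo_out/demo_contours.csv --truth demo_truth.csv
frame 0: dice=1.0000 frechet=1.052 mean_err=0.347
frame 1: dice=1.0000 frechet=0.856 mean_err=0.288
...
mean dice over 30 frames: 0.9998
```

Mean position error ~0.3 px (sub-pixel) and Fréchet distance ~1 px per
frame at SNR 10.

The same pipeline is available as a library:

```python
from knottrack import (WaveParams, synthesize_series, segment_frame,
                       track_series, TrackConfig)

params = WaveParams(length_um=12, amplitude_rad=2.2, curl_rad=0.6, seed=1)
frames = synthesize_series(params, snr_db=10)
skeletons = [segment_frame(f.image) for f in frames]
track = track_series(skeletons, TrackConfig(start_xy=params.base_xy))
```

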