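# diaflow

Quantitative tracking of diaphragm motion and strain in B-mode ultrasound
cine loops, using Lucas-Kanade optical flow.

The diaphragm is the main respiratory muscle; its excursion and deformation
are clinically useful markers of respiratory function, e.g. for patients
under mechanical ventilation. In B-mode ultrasound it appears as a bright
curved band. `diaflow` turns a cine loop of 3–5 breathing cycles into
quantitative curves:

* **inter-frame displacement** — mean motion of the tracked points between
  adjacent frames, split into horizontal and vertical components (pixels);
* **cumulative displacement** — motion of the current frame relative to
  frame 0 (the running sum of the inter-frame values);
* **global strain** — with the tracked band reduced to k = 15 ordered group
  centroids and L(t) the chained Euclidean distance through them,

      GS(t) = (L(t) − L(0)) / L(0) × 100 %

  so a shortening (contracting) diaphragm has negative GS;
* **respiratory period** — from adjacent peaks/troughs of the smoothed
  displacement curve, T = 2·|pk − th| aggregated over all adjacent pairs;
* **drift-corrected curves and per-cycle peak-to-peak values** — sequential
  tracking accumulates error, so cumulative curves are corrected with
  S_corr(t) = S(t) − (S(T)/T)·t, anchored on the first cycle, after which
  the curves return to zero at every cycle boundary.

## Pipeline

1. 3×3 mean filtering of every frame.
2. Frame 0: automatic (Otsu) threshold segmentation — the band is much
   brighter than the surrounding tissue — with optional manual override;
   the largest 8-connected white region is taken as the diaphragm.
3. 300 tracking points seeded uniformly at random on the band; DBSCAN
   density clustering discards seeds on bright clutter (largest cluster
   kept).
4. Pyramidal Lucas-Kanade tracking of each point through the sequence,
   solving the m×m-window brightness-constancy normal equations per frame
   pair with sub-pixel (bilinear) sampling.
5. Points sorted along the band and split into 15 equal groups; group
   centroids define the band length for GS.
6. Size-5 convolutional smoothing, cycle detection, drift correction,
   per-cycle peak-to-peak summaries; results written as CSV + JSON.

Because no clinical recordings are distributed, the package ships a
synthetic speckle-phantom generator (`diaflow.phantom`) that renders a
bright curved band over a darker speckled background with programmable
translation, along-band stretch, drift and noise — with exact per-frame
ground truth, so every stage is testable end to end.

## Worked example

```
python examples/run_phantom_pipeline.py
```

prints (exact numbers depend on the seed):

```
frames tracked            : 200 (8.0 s at 25 fps)
points seeded / kept      : 300 / 300
respiratory period T      : 2.000 s   (truth 2.0 s)
cumulative vertical p2p   : 5.95 +/- 0.00 px (truth 6.0 px)
global strain p2p         : 10.42 +/- 0.00 %  (truth 10.0 %)
```

i.e. on a 4-cycle phantom breathing with a 2 s period, 3 px vertical
translation amplitude and 10 % strain amplitude, the pipeline recovers the
period exactly, the vertical peak-to-peak excursion within ~1 % and the
strain peak-to-peak within half a strain point, despite an injected
0.05 px/frame tracking drift. The other example scripts demonstrate
seed-point selection and drift correction in isolation.

## Command line

```
diaflow phantom render --spec spec.yaml --out fixture/
diaflow run --input fixture/ --frame-interval 0.04 --out results/
diaflow run --input loop.dcm --out results/ --threshold 120
```

`run` accepts a multi-frame DICOM file or a directory of numbered
grayscale images and writes `curves.csv` (time, inter-frame and cumulative
displacements, GS) plus a JSON sidecar and run report with the detected
period, extrema, per-stage point counts and every parameter used.

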