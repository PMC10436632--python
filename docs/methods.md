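# Methods

## Model and assumptions

The tracker estimates the apparent motion of material points on the
diaphragm band under the three classical optical-flow assumptions:
brightness constancy (a speckle patch keeps its intensity as it moves),
small inter-frame motion, and spatial coherence (neighbouring points on the
band move alike). For a point with spatial gradients Ix, Iy and temporal
difference It over an m×m window (n = m² pixels), the Lucas-Kanade normal
equations

    [ ΣIx²  ΣIxIy ] [u]   [ −ΣIxIt ]
    [ ΣIxIy ΣIy²  ] [v] = [ −ΣIyIt ]

are solved for the velocity (u, v) in pixels/frame, u along the column
(horizontal) axis and v along the row (vertical) axis. Coordinates are
0-based (row, col) with rows increasing downward, matching the on-screen
orientation; this convention is used everywhere in the package.

Ultrasound speckle is temporally coherent under small tissue motion, which
is what makes the band trackable; it decorrelates under large deformation
or out-of-plane motion, which is the main way the brightness-constancy
assumption fails on real data.

## Tunable parameters

| key | default | meaning |
|---|---|---|
| `lk.window` | 15 px | LK window side m; larger windows average more speckle but blur motion boundaries. 15 px is a typical speckle-tracking scale for 3–5 MHz convex-probe imagery. |
| `lk.pyramid_levels` | 3 | coarse-to-fine depth; level 1 is the plain single-scale solve. Extends the trackable motion range to several pixels/frame. |
| `lk.iterations` | 5 | Gauss-Newton refinements per level, early exit when the update falls below 0.01 px. With `pyramid_levels=1, iterations=1` the tracker reduces to the plain normal-equation solve. |
| `lk.min_eig_floor` | 1e-4·m² | smaller-eigenvalue floor of the structure matrix; below it a window is considered textureless and the point is invalidated. |
| `lk.max_condition` | 1e6 | condition-number cap (aperture-problem guard). |
| `seed_points.n` | 300 | random seeds drawn without replacement at integer pixel centres of the segmented band. |
| `dbscan.eps`, `dbscan.min_pts` | 15 px, 10 | density filter for the seeds; must scale with seed density inside the band's bounding box (300 points over a typical band give ~10+ neighbours within 15 px). Only the largest cluster is kept (`dbscan.keep_all_clusters` switches this off). |
| `groups.k` | 15 | along-band groups whose centroids define the band length L(t). |
| `smooth.kernel` | 5 | uniform smoothing kernel applied to all output curves. |
| `cycles.curve` | `cumulative_v` | detection curve for the respiratory period; vertical excursion carries the largest respiratory signal in diaphragm imaging. |
| `cycles.min_prominence` | 10 % of range | extremum prominence floor; cycle extraction presumes unambiguous extrema. |

Segmentation runs on the mean-filtered frame 0 only (the band is not
re-segmented later); "adaptive thresholding" is realized as Otsu's
between-class-variance criterion with a manual override
(`threshold.mode=manual`). Connectivity for the largest connected region
is 8-neighbour. A run is a pure function of (input, configuration, global
seed): stage seeds derive deterministically from `seed`.

## Numerical choices

* **Gradients** — central differences (one-sided at borders) on the
  mean-filtered frames; It is the plain frame difference.
* **Sub-pixel positions** — bilinear sampling (`map_coordinates`,
  order 1); windows that overlap the frame border sample replicated edge
  pixels, equivalent in effect to clipping the window to the frame. A point
  is invalidated when its centre leaves the frame or its structure matrix
  degenerates; invalidation is permanent and invalid points are excluded
  from all subsequent means.
* **Grouping** — points sorted by frame-0 column (ties by row), split into
  k contiguous groups of size ⌊N/k⌋ or ⌈N/k⌉; the group "centre" is the
  centroid of its valid members. Column-contiguous groups make the summed
  centroid-to-centroid distances approximate the band length.
* **Smoothing ends** — edge replication by default. Cumulative-type curves
  (cumulative displacement, GS) are instead extended anti-symmetrically
  (odd reflection) before convolution: edge replication biases the t = 0
  sample of a rising curve away from its defining zero, and after drift
  correction that offset grows linearly with cycle number (~0.5 px by the
  third boundary at default conditions).
* **Cycle detection** — a least-squares line is removed before locating
  extrema (a baseline tilt shifts peaks and troughs in opposite
  directions); extrema are found with the prominence floor above. Each
  adjacent peak-trough pair gives a half-period; since single spacings are
  still biased by any residual tilt, T is the median of sums of
  consecutive half-periods (each spanning one full cycle). A record with a
  single pair falls back to T = 2·|pk − th|.
* **Drift correction** — S(T) is read at the sample nearest t = T (no
  interpolation); the corrected series is exactly zero there, which makes
  the correction idempotent. It is applied to cumulative displacement and
  GS curves only — inter-frame curves cannot accumulate drift.
* **Ties** — largest connected component ties break on the smallest
  (row_min, col_min) bounding-box corner; DBSCAN cluster-size ties break
  on the cluster containing the smallest-index point.
* **Degenerate inputs** — constant frames reject automatic thresholding;
  an all-black threshold result, an all-noise DBSCAN labelling, loss of
  every tracked point, and a period longer than the record each raise a
  stage-specific error with a remedy hint.

## The phantom: what it emulates, and what it does not

`diaflow.phantom` renders a bright curved band (parabolic centreline, dome
sagitta `band_curvature`, soft 1 px edges, lateral taper `band_col_margin`
so the band clears the image sides) over a darker background. Both carry
multiplicative speckle-like texture — a Gaussian-smoothed random field
frozen in the band's material frame and advected with the motion, so it is
temporally coherent and trackable, with noise amplitude proportional to
local brightness as in real log-compressed speckle.

Motion per frame: sinusoidal translation (amplitudes `translation_amplitude_h/v`,
period `breath_period`, optional asymmetric inhale/exhale profile), a
linear `drift_rate` added to the vertical translation, and an along-band
stretch realized as an isotropic similarity scaling s(t) about the band
centre. Scaling both axes makes every length scale exactly by s(t), so the
true strain is GS(t) = (s(t) − 1)·100 with no discretization ambiguity.
The strain profile −(A/2)(1 − cos 2πt/T) starts at 0, dips to −A at
mid-cycle (inspiratory contraction, negative strain) and returns to 0, so
the programmed GS peak-to-peak equals `strain_amplitude`.

Default conditions (used by the test suite and the acceptance script):
160×224 px frames, 200 frames at 25 fps = 4 cycles of a 2 s period, 3 px
vertical and 5 px horizontal amplitude, 10 % strain amplitude,
0.05 px/frame drift, band ~200 vs background ~60 gray levels, speckle
σ = 10 gray levels. Unit tests use a smaller 96×144, 100-frame phantom.

The phantom does **not** emulate: out-of-plane motion and speckle
decorrelation, attenuation/shadowing (ribs, lung gas), probe motion,
log-compression dynamics, or anatomical structures other than one band.
Passing tests therefore demonstrate correctness of the algorithmic chain
under coherent speckle, not clinical accuracy; on real loops the dominant
error sources are exactly the decorrelation effects the phantom excludes.

## Design choices where the design was open

* Both DICOM and plain image-directory input are supported, with the frame
  interval overridable: vendor cine metadata varies, and frame time is not
  always present.
* Displacements are reported in pixels; millimetre columns are appended
  only when a pixel spacing is available in the metadata.
* DBSCAN is implemented from its published definition (core points,
  density-reachable expansion, border/noise labelling) rather than wrapped
  from a library, and is cross-checked against a reference implementation
  in the tests.
* Whether the density filter should keep only the largest cluster or all
  non-noise clusters is ambiguous; largest-cluster is the default with
  `dbscan.keep_all_clusters` as the escape hatch.
* Peak-to-peak cycle windows run between consecutive same-type extrema
  (peaks when at least two exist, else troughs); summaries are per-cycle
  mean ± SD.

## Known limitations

* Single-frame segmentation: a band that brightens or moves far from its
  frame-0 position is not re-segmented.
* No re-acquisition of lost points; long loops with aggressive motion can
  thin the point set and eventually starve a group (raised as an error).
* The drift model is a single linear ramp anchored on the first cycle;
  slowly varying (non-linear) drift is only partially removed.
* GS uses the 15 group centroids, not all points; segmental (per-group)
  strain is out of scope.
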