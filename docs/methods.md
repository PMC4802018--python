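# Methods

`atriareg` registers a preoperative 3D model of the left atrium (LA) to a
pair of synchronized X-ray sequences showing a contrast-agent (CA)
injection, acquired by a biplane C-arm whose two views are described by
calibrated 3×4 projection matrices `P_A`, `P_B`. The estimated pose is a
3-DOF translation `t` (mm). This note documents the model assumptions, the
tunable parameters, what the synthetic phantom does and does not emulate,
and the numerical choices.

## Registration model

**Contrast extraction.** The contrasted region in each plane is isolated by
digital subtraction angiography with best-reference selection: among all
frames annotated uncontrasted, the reference `Îu` minimizing the L1 norm of
`Iu − Ic` is subtracted from the contrasted frame `Ic`, so catheters and the
diaphragm cancel as far as possible. Negative DSA pixels are clamped, a
large square median filter suppresses residual thin artifacts, and the
binary contrast mask `I_thr` thresholds the filtered image `I_f` strictly
above `μ_f + σ_f` (mean and standard deviation over all pixels; the strict
inequality makes a constant image yield an empty mask). For edge features,
`I_f` is passed through a sigmoid with midpoint `t = μ_f − σ_f` — flattening
intensity variation inside the contrasted area while preserving the drop-off
at its boundary — and a gradient-of-Gaussian magnitude at a large scale
yields the smooth edge image `I_DOG`.

**Similarity measures.** All objectives are products over the two planes of
normalized cross-correlations (NCC, Pearson form: normalized by pixel count,
values in [−1, 1]; a zero-variance image contributes 0, treated as "no
information"):

- `shad_dsa`, `shad_thr`: NCC of the signed DSA image (or the binary mask)
  with the projected shadow `S_T` of the translated model;
- `edge`: NCC of `I_DOG` with an apparent-edge rendering `E_T` of the
  surface mesh — each triangle rasterized with opacity `o = 1 − |d·n|`
  (`d` the per-triangle unit viewing direction from the X-ray source to the
  centroid, `n` the outward normal), composited order-independently as
  `1 − Π(1 − o_k)` and Gaussian-smoothed at the `I_DOG` scale;
- `cade`: consistency of the contrast-agent distribution estimate. A chamber
  voxel is estimated contrasted iff it projects onto contrasted pixels in
  *both* planes and lies inside the chamber (`C3D = I_thr^A·I_thr^B·χ`,
  nearest-pixel lookup). `C3D` is forward-projected (splatted) into both
  planes and correlated with the masks. Consistency, not contrasted-voxel
  *count*, is scored: count maximization is biased toward placing the
  reconstructed contrast in the chamber's largest structure, which a
  regression test demonstrates.
- `<base>+edge`: base measure plus `α·ρ_edge`, default `α = 1`.

**Optimization.** The initial translation places the model at the
triangulation of the two image centers (closest approach of the two
back-projected rays), which can sit beyond 30 mm from the correct pose —
outside the capture range of gradient methods. A coarse-to-fine lattice
search therefore maximizes the objective: a cubic lattice of half-width
40 mm at 16 mm spacing, then repeated refinement by a factor 2 around the 8
best cells seen so far, down to a 1 mm step (≈1000 objective evaluations).
Ties break toward the lexicographically smaller (z, y, x) candidate, making
the search deterministic; non-finite objective values discard the cell. No
gradient polish follows — the 1 mm final step is well below the ~3 mm
interuser variability of manual registration that constitutes the practical
accuracy floor.

**Best-frame selection.** For a whole sequence, either the frame whose own
objective is maximal is reported, or cross-selection is used: poses are
estimated per frame with one measure (e.g. `cade+edge`) while frames are
*ranked* by a second measure (e.g. `shad_thr+edge`) evaluated at those
poses. The shadow measure rewards global opacification, so cross-selection
favors well-filled frames even when the pose estimator is the consistency
measure.

**Temporal filtering.** Per-frame estimates `T_i'` with objective values
`ρ_i` are smoothed as a first-order Markov chain: state terms
`(T_i − T_i')ᵀ Σ_i⁻¹ (T_i − T_i')` plus transition terms
`r²(T_i − T_{i−1})ᵀ Σ_v⁻¹ (T_i − T_{i−1})` (`r` the frame rate), minimized
over all frames jointly. `Σ_i = e(ρ_i)²·I` where `e(ρ)` is a linear
regression of observed error on objective value, trained on annotated data
and clamped to a floor of 0.1 mm; the chain therefore trusts
high-confidence frames and averages low-confidence ones toward their
neighbors. `Σ_v` is the second moment of frame-to-frame velocities of
annotated trajectories (zero mean imposed: over whole breathing cycles the
LA moves about a mean position). The quadratic is minimized by BFGS started
at the unfiltered series.

## Synthetic phantom

The phantom generator provides ground truth for every stage. The chamber is
an ellipsoid body (semi-axes 30×25×22 mm) with four tubular pulmonary veins
(radius 4.5–5 mm, length 18–20 mm) and two ellipsoidal lobes; the lobes and
the vein tubes give the surface internal apparent contours, as any real LA
mesh has — without them the edge rendering degenerates to a bare silhouette
ring and edge-based similarity loses its meaning. The model lives on a 2 mm
isotropic voxel grid (60³) with a marching-cubes surface.

Imaging uses an idealized orthogonal biplane geometry (source–iso-center
750 mm, source–detector 1050 mm, 256×256 detector at 1.6 mm pitch ≈ a
quarter-scale clinical detector; all pixel-unit parameters scale linearly
with image width). Attenuation is the splatted line integral of the binary
contrasted-voxel mask at fixed contrast density, subtracted from a smooth
vignetted background and quantized to 12 bits — sufficient because the
method consumes DSA differences, never absolute intensities. With zero
noise and full fill, the thresholded DSA footprint equals the projected
shadow at the true pose pixel for pixel, which anchors the whole geometry.

Contrast fill: voxels opacify in order of a wall-weighted geodesic distance
from the injection site — geodesic dilation inside the chamber (a vein
injection fills the vein first, then floods through the ostium) with
interior depth penalized at weight 4 per voxel of depth. The penalty makes
the spreading contrast pool along the chamber wall, reflecting that injected
CA, denser than blood, streams along walls and roof on the seconds-scale of
an injection rather than ballooning freely into the blood pool; the visible
contrast boundary then largely coincides with anatomy, which is the premise
of edge-based registration. Scenario presets: a center injection filling the
chamber completely before ejection into the ventricle (the well-contrasted
case), and a vein injection peaking at 30% fill (the sparse-contrast case).
Breathing translates the chamber along the cranio-caudal axis by
`A·sin(2πi/period)` (default 3 mm amplitude), giving a zero-mean
ground-truth trajectory over whole cycles. Optional artifacts reproduce the
classic DSA failure modes: a dark catheter-like curve whose position
changes frame to frame, a diaphragm ramp moving with breathing, global
brightness drift, and Gaussian detector noise. All randomness derives from
a single seed; identical seeds give bit-identical sequences.

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: non-rigid cardiac deformation, realistic
polychromatic attenuation and scatter, anatomical variability beyond the
parametric shape, automatic contrasted-frame detection (annotations are an
input), rotational misalignment, and the error magnitudes of patient
studies. Phantom error statistics validate *orderings and mechanisms*
(e.g. that consistency+edge beats shadow matching under partial fill, that
filtering reduces error), not clinical accuracy numbers.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| median kernel | 30 at 1024-px width | px | scaled by width/1024, rounded up to odd (31 at 1024, 9 at 256) |
| DOG sigma | 24 at 1024-px width | px | scaled by width/1024 |
| sigmoid slope `s` | 0.1 at 12-bit range | 1/intensity | scales inversely with dynamic range |
| sigmoid midpoint `t` | `μ_f − σ_f` | intensity | one σ below the mean of `I_f` |
| combination weight `α` | 1 | – | equal weighting of base and edge terms |
| search range | ±40 | mm | covers >30 mm initializations |
| level-0 step / refine / top-k / min step | 16 / 2 / 8 / 1 | mm,–,–,mm | ≈10³ coarse evaluations |
| confidence floor | 0.1 | mm | keeps `Σ_i` positive-definite |
| `Σ_v` ridge | 1e−6 | (mm/s)² | added when training motion is degenerate (logged) |
| wall affinity | 4 | cost per voxel depth | fill model, see above |

## Numerical choices

- **Coordinates.** 0-based pixel indices, pixel centers at integers,
  `(u, v) = (column, row)`, world units mm, row-major matrices. Projection
  matrices are normalized so the third row of the left 3×3 block is a unit
  vector with positive depth in front of the source.
- **Splatting.** Voxels project to their nearest pixel and deposit over a
  square footprint covering the voxel's projected extent (computed from the
  closest depth of the cloud, minimum 1 px), so coarse voxels leave no
  pinholes. The same splat path is used by the shadow renderer, the CADE
  projections and the phantom's attenuation, which makes the
  footprint-equals-shadow identity exact.
- **CADE lookup.** Nearest-pixel sampling of the binary masks (the images
  are binary; interpolation would manufacture fractional contrast).
- **Degenerate inputs.** Zero-variance NCC inputs score 0 (logged once per
  process); degenerate (zero-area) triangles are skipped and counted;
  non-finite objective cells are discarded; a rank-deficient velocity
  covariance is ridge-regularized.
- **BFGS exactness.** The chain quadratic can be extremely ill-conditioned
  (a near-singular `Σ_v` acts as a hard equality constraint), and near the
  optimum the remaining decrease drowns in float noise of the large
  objective value, stalling the line search around 1e−7 parameter accuracy.
  The solver therefore refines by minimizing the *increment*
  `J(x+δ) − J(x) = g(x)·δ + δ·(g(x+δ) − g(x))/2` — exact for a quadratic
  and free of the large constant — recovering agreement with the direct
  block-tridiagonal solve to better than 1e−8 (verified on random problems).
- **Mesh voxelization.** Center-inside voxelization of watertight meshes by
  vertical-column parity counting (sample columns offset by an irrational
  sub-voxel epsilon so they never hit edges exactly). A surface-inclusive
  voxelization would bias enclosed volume by ~20% at 2 mm pitch on this
  chamber.
- **Phantom mesh resolution.** Marching cubes at step 2 on the 2 mm grid
  (~4 mm facets): at the default detector scale a voxel projects to ~2 px,
  so finer facets add cost to every edge rendering without changing the
  rasterized contours.

## Problem sizes

Tests and the acceptance script run at 256×256 detector resolution with the
60³/2 mm phantom grid: translation recovery on single frames, measure
comparisons over 10 seeded phantoms, temporal filtering over 10 sequences
with leave-one-sequence-out training, and oracle equivalence checks on toy
grids (16³) and small random problems. These sizes keep a full run in
minutes on one core while leaving every algorithmic path identical to a
full-resolution run (all pixel-unit parameters scale with image width).

## Known limitations

- Translation-only: rotations are out of scope by design (patient
  positioning rules out large rotations; small ones are not reliably
  observable in sparse contrast).
- The CADE objective has a plateau when the contrast hull fits inside the
  chamber at many poses; discrimination comes from the chamber boundary and
  improves with body fill. For very small fills (<~5% of chamber volume)
  the consistency margin over the biased pose becomes thin.
- The edge measure alone has many local optima and a global optimum that
  need not be at the true pose; it is useful only in combination, mirroring
  its role in the similarity family.
- A single stationary `Σ_v` is used; breathing-phase-dependent transition
  statistics are not implemented.
- Online (causal) filtering is out of scope; the smoother uses the whole
  sequence.
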