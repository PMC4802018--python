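# atriareg

Contrast-agent-based 3D/2D rigid registration of the left atrium from
biplane X-ray.

## The problem

During X-ray-guided catheter ablation of atrial fibrillation, the left
atrium (LA) is invisible under fluoroscopy unless contrast agent (CA) is
injected — and physicians keep injections small. A preoperative 3D model of
the patient's LA (from CT or MRI) can be overlaid on the live images for
guidance, but first it must be registered to the X-ray coordinate frame.
`atriareg` performs that registration automatically from a pair of
synchronized X-ray sequences showing a CA injection, acquired by a biplane
C-arm with known projection matrices `P_A`, `P_B`, estimating a 3-DOF
translation `t` of the model. It is aimed at researchers in interventional
image guidance who need a reference implementation of contrast-based LA
registration, complete with a synthetic ground-truth phantom for
validation.

## The method

1. **Contrast extraction.** Digital subtraction angiography with
   best-reference selection: the uncontrasted frame `Îu` minimizing
   `‖Iu − Ic‖₁` is subtracted from the contrasted frame so catheter and
   diaphragm artifacts cancel. Clamping, a large median filter and a
   threshold at `μ_f + σ_f` give the binary contrast mask `I_thr`; a
   sigmoid (midpoint `μ_f − σ_f`) followed by a gradient-of-Gaussian
   magnitude gives the edge image `I_DOG`.
2. **Similarity measures** (each a product over the two planes of
   normalized cross-correlations `ρ_n`):
   - shadow: `ρ_shad = ρ_n(I_DSA, S_T)·…` or with `I_thr` — matches the
     projected shadow `S_T` of the translated model to the contrasted area;
   - apparent edges: `ρ_edge = ρ_n(I_DOG, E_T)·…` — the mesh rendered with
     per-triangle opacity `o = 1 − |d·n|`, responding exactly at apparent
     contours;
   - CADE consistency: `ρ_CADE = ρ_n(I_thr, C_T)·…` — a binary 3D
     contrast-agent distribution estimate `C_T³ᴰ(v) = I_thr^A(P_A T v) ·
     I_thr^B(P_B T v) · χ(v)` is reconstructed inside the chamber
     indicator `χ` and forward-projected; the pose making the estimate
     most consistent with both views wins. Combinations
     `ρ_base + α·ρ_edge` (default `α = 1`) are supported.
3. **Optimization.** Initialization at the triangulation of the two image
   centers (often >30 mm off), then a deterministic octree-like
   coarse-to-fine lattice search (±40 mm, 16 mm → 1 mm steps).
4. **Best-frame selection**, including cross-selection: estimate poses with
   one measure, rank frames for reporting with another.
5. **Markov temporal filtering.** Per-frame estimates are smoothed by
   maximizing a chain posterior with state covariances `Σᵢ = e(ρᵢ)²·I`
   from a confidence regression `e(ρ)` (error vs objective value) and a
   velocity covariance `Σ_v` learned from annotated trajectories; the
   convex quadratic is solved by BFGS.

A synthetic biplane phantom (ellipsoid-plus-veins chamber, wall-pooling
contrast fill, breathing motion, catheter/diaphragm artifacts, known
ground truth) exercises every stage; see `docs/methods.md` for the model
details and parameter table.

## Worked example

Register two frames of the bundled synthetic phantom (12-bit 256² biplane
sequence with noise, catheter and diaphragm artifacts) with the combined
CADE+edge measure:

```python
import json
from atriareg.interface import RunConfig, run_pipeline

cfg = RunConfig(phantom=True, measure="cade+edge", frames=[4, 5],
                noise_sd=8.0, seed=7)
report = run_pipeline(cfg)
print(json.dumps(report, indent=2, sort_keys=True))
```

prints (abridged):

```json
{
  "config_hash": "eb84168781f51587",
  "frames": [
    {"frame_index": 4, "rho": 1.0559, "t_hat_mm": [-1.0, -0.0, -2.0],
     "error_mm": 2.236},
    {"frame_index": 5, "rho": 0.8846, "t_hat_mm": [-1.0, -2.0, -1.0],
     "error_mm": 1.419}
  ],
  "mean_error_mm": 1.828,
  "measure": "cade+edge",
  "seed": 7
}
```

`t_hat_mm` is the estimated model translation per frame, `rho` the
objective value at the optimum, and `error_mm` the Euclidean distance to
the phantom's ground-truth pose — here ~1–2 mm, on the order of the 1 mm
final search step and well below the ~3 mm interuser variability of manual
registration. The same run is available from the shell
(`atriareg phantom`, `atriareg register`, `atriareg filter`,
`atriareg train-temporal`, `atriareg evaluate`).

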