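"""Per-frame translation optimization and best-frame selection.

The initialization places the model at the 3D point corresponding to the
centers of both 2D images (closest approach of the two back-projected
rays).  That can be more than 30 mm from the correct pose — beyond the
capture range of gradient-based optimizers — so the optimizer is an
octree-like coarse-to-fine lattice search: evaluate a coarse cubic lattice
of candidate translations, keep the best cells, and refine around each at
an increasingly finer spacing until the lattice step falls below a minimum.
No gradient polish follows: the final 1 mm step is well below the ~3 mm
interuser variability of manual registration.

Best-frame selection picks the frame whose own objective value is highest;
the cross-selection operator additionally allows estimating each frame's
pose with one measure (e.g. CADE) while ranking frames for selection with
another (e.g. the thresholded-shadow measure).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._util import warn_once
from .preproc import preprocess_frame
from .projection import (
    AtriumModel,
    ProjectionGeometry,
    RigidTransform,
    back_project_ray,
)
from .similarity import SimilarityConfig, rho_combined

__all__ = [
    "FrameRegistration",
    "SearchConfig",
    "coarse_to_fine_search",
    "initialize",
    "register_frame",
    "register_sequence",
    "select_best_frame",
]


@dataclass
class SearchConfig:
    """Coarse-to-fine lattice search parameters (mm).

    The level-0 lattice spans ``[init - range_mm, init + range_mm]^3`` at
    spacing ``level0_step_mm``; each refinement divides the spacing by
    ``refine_factor`` around the ``keep_top_k`` best cells seen so far,
    until the spacing would drop below ``min_step_mm``.  Defaults cover a
    40 mm capture range with about a thousand objective evaluations.
    """

    init_mode: str = "image-center"
    explicit_init: tuple[float, float, float] | None = None
    range_mm: float = 40.0
    level0_step_mm: float = 16.0
    refine_factor: float = 2.0
    keep_top_k: int = 8
    min_step_mm: float = 1.0

    def __post_init__(self):
        if not (self.range_mm >= self.level0_step_mm > self.min_step_mm > 0):
            raise ValueError("require range_mm >= level0_step_mm > min_step_mm > 0")
        if self.keep_top_k < 1:
            raise ValueError("keep_top_k must be >= 1")
        if self.refine_factor <= 1:
            raise ValueError("refine_factor must exceed 1")
        if self.init_mode not in ("image-center", "explicit"):
            raise ValueError("init_mode must be 'image-center' or 'explicit'")


@dataclass
class FrameRegistration:
    """Result of optimizing one frame: pose, objective value, measure name."""

    frame_index: int
    T_prime: RigidTransform
    rho_value: float
    measure_name: str


def initialize(geometry: ProjectionGeometry) -> RigidTransform:
    """Initial translation from image-center triangulation.

    Back-projects the center pixel of each detector and returns the midpoint
    of the closest-approach segment of the two rays.  Parallel rays (a
    degenerate biplane geometry) raise an error.
    """
    rows, cols = geometry.image_shape
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    o1, d1 = back_project_ray(geometry.P_A, center)
    o2, d2 = back_project_ray(geometry.P_B, center)
    b = float(d1 @ d2)
    denom = 1.0 - b * b  # d1, d2 are unit vectors
    if denom < 1e-12:
        raise ValueError("principal rays are parallel; cannot triangulate image centers")
    w0 = o1 - o2
    d = float(d1 @ w0)
    e = float(d2 @ w0)
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    p1 = o1 + s * d1
    p2 = o2 + t * d2
    return RigidTransform((p1 + p2) / 2.0)


def _zyx_key(point: np.ndarray) -> tuple[float, float, float]:
    return (round(point[2], 9), round(point[1], 9), round(point[0], 9))


def coarse_to_fine_search(objective, init: RigidTransform, config: SearchConfig):
    """Octree-like lattice maximization of ``objective`` over translations.

    Deterministic: candidate points are visited in lexicographic (z, y, x)
    order and equal objective values are broken toward the smaller (z, y, x)
    tuple.  Objective values that are non-finite discard the cell (logged
    once).  Returns ``(RigidTransform, best_value)``.
    """
    init_t = np.asarray(init.t, dtype=float)
    evaluated: dict[tuple, float] = {}
    entries: list[tuple[float, tuple, np.ndarray]] = []

    def evaluate(points):
        order = sorted(range(len(points)), key=lambda i: _zyx_key(points[i]))
        for i in order:
            p = points[i]
            key = _zyx_key(p)
            if key in evaluated:
                continue
            val = float(objective(RigidTransform(p)))
            if not np.isfinite(val):
                warn_once(
                    "search-nonfinite",
                    "coarse-to-fine search: discarded cell with non-finite objective",
                )
                val = -np.inf
            evaluated[key] = val
            entries.append((val, key, p))

    h = float(config.level0_step_mm)
    n0 = int(np.floor(config.range_mm / h))
    offsets = [k * h for k in range(-n0, n0 + 1)]
    level_points = [
        init_t + np.array(o) for o in itertools.product(offsets, offsets, offsets)
    ]
    evaluate(level_points)

    h /= config.refine_factor
    while h >= config.min_step_mm - 1e-12:
        best = sorted(entries, key=lambda e: (-e[0], e[1]))[: config.keep_top_k]
        pts = []
        for _, _, center in best:
            for o in itertools.product((-h, 0.0, h), repeat=3):
                pts.append(center + np.array(o))
        evaluate(pts)
        h /= config.refine_factor

    best_val, _, best_pt = min(entries, key=lambda e: (-e[0], e[1]))
    return RigidTransform(best_pt), float(best_val)


def register_frame(
    sequence,
    frame_index: int,
    model: AtriumModel,
    config: SearchConfig | None = None,
    measure: str | SimilarityConfig = "cade+edge",
) -> FrameRegistration:
    """Optimize the translation for one contrasted frame.

    Preprocessing (DSA, threshold, edge images) is computed once for the
    frame; only the renderers depend on the candidate transform inside the
    search loop.  A frame annotated uncontrasted raises an error.
    """
    config = config or SearchConfig()
    sim = measure if isinstance(measure, SimilarityConfig) else SimilarityConfig(measure)
    prepA, prepB = preprocess_frame(sequence, frame_index)
    geometry = sequence.geometry

    def objective(T: RigidTransform) -> float:
        return rho_combined(prepA, prepB, model, geometry, T, sim)

    if config.init_mode == "explicit":
        if config.explicit_init is None:
            raise ValueError("explicit init_mode requires explicit_init")
        init = RigidTransform(config.explicit_init)
    else:
        init = initialize(geometry)
    T_hat, rho = coarse_to_fine_search(objective, init, config)
    return FrameRegistration(
        frame_index=frame_index, T_prime=T_hat, rho_value=rho, measure_name=sim.measure
    )


def register_sequence(
    sequence,
    model: AtriumModel,
    config: SearchConfig | None = None,
    measure: str | SimilarityConfig = "cade+edge",
    frame_indices=None,
) -> list[FrameRegistration]:
    """Register every contrasted frame (or an explicit subset) of a sequence."""
    if frame_indices is None:
        frame_indices = [i for i in range(sequence.n_frames) if sequence.contrasted[i]]
    return [
        register_frame(sequence, i, model, config=config, measure=measure)
        for i in frame_indices
    ]


def select_best_frame(
    registrations: list[FrameRegistration],
    selector_measure: str | None = None,
    sequence=None,
    model: AtriumModel | None = None,
    alpha: float = 1.0,
) -> int:
    """Pick the frame used for the final sequence registration.

    Without ``selector_measure``: the frame whose own objective value is
    highest.  With it (cross-selection): each frame keeps the pose found by
    its primary measure, but frames are ranked by ``selector_measure``
    evaluated at that pose — e.g. estimate poses with the CADE measure, then
    select the frame where the thresholded-shadow measure is maximal.  Ties
    go to the lowest frame index.  Returns the winning ``frame_index``.
    """
    if not registrations:
        raise ValueError("no registrations to select from")
    if selector_measure is None:
        scores = [r.rho_value for r in registrations]
    else:
        if sequence is None or model is None:
            raise ValueError("cross-selection needs the sequence and the model")
        sim = SimilarityConfig(selector_measure, alpha)
        scores = []
        for r in registrations:
            prepA, prepB = preprocess_frame(sequence, r.frame_index)
            scores.append(
                rho_combined(prepA, prepB, model, sequence.geometry, r.T_prime, sim)
            )
    order = sorted(
        range(len(registrations)), key=lambda i: (-scores[i], registrations[i].frame_index)
    )
    return registrations[order[0]].frame_index
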