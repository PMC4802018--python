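"""Scalar registration objectives.

All measures are products over the two planes of normalized
cross-correlations (NCC) between a derived fluoroscopic image and a
rendering of the transformed 3D model:

* ``shad_dsa`` / ``shad_thr`` — NCC of the signed DSA image (or its binary
  threshold) with the projected shadow ``S_T``,
* ``edge`` — NCC of the DOG edge image with the apparent-edge rendering
  ``E_T``,
* ``cade`` — NCC of the thresholded contrast with the forward-projected
  contrast-agent distribution estimate ``C_T`` (consistency of the binary
  reconstruction with what both views saw),
* ``<base>+edge`` — base measure plus ``alpha`` times the edge measure.

Maximizing contrasted-voxel *count* is deliberately not an objective: it
biases the registration toward placing reconstructed contrast in the
largest structure of the chamber; consistency scoring avoids that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import warn_once
from .projection import (
    AtriumModel,
    ProjectionGeometry,
    RigidTransform,
    compute_cade,
    render_apparent_edges,
    render_shadow,
)

__all__ = [
    "MEASURES",
    "SimilarityConfig",
    "evaluate_measure",
    "ncc",
    "rho_cade",
    "rho_combined",
    "rho_edge",
    "rho_shadow",
]

MEASURES = (
    "shad_dsa",
    "shad_thr",
    "edge",
    "cade",
    "shad_dsa+edge",
    "shad_thr+edge",
    "cade+edge",
)


@dataclass
class SimilarityConfig:
    """Choice of objective and combination weight ``alpha`` (default 1)."""

    measure: str = "cade+edge"
    alpha: float = 1.0

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; choose from {MEASURES}")
        # alpha = 0 degenerates a combined measure to its base term
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def base(self) -> str:
        return self.measure.split("+")[0]

    @property
    def combined(self) -> bool:
        return self.measure.endswith("+edge") or self.measure == "edge"


def ncc(I1: np.ndarray, I2: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped images, in [-1, 1].

    Pearson correlation over all pixels with population statistics.  A
    constant image carries no information, so a zero standard deviation on
    either side returns 0 (logged once per process).
    """
    I1 = np.asarray(I1, dtype=np.float64)
    I2 = np.asarray(I2, dtype=np.float64)
    if I1.shape != I2.shape:
        raise ValueError(f"shape mismatch: {I1.shape} vs {I2.shape}")
    d1 = I1 - I1.mean()
    d2 = I2 - I2.mean()
    s1 = np.sqrt(np.mean(d1 * d1))
    s2 = np.sqrt(np.mean(d2 * d2))
    if s1 == 0.0 or s2 == 0.0:
        warn_once("ncc-zero-sigma", "NCC of a constant image: returning 0 (no information)")
        return 0.0
    return float(np.clip(np.mean(d1 * d2) / (s1 * s2), -1.0, 1.0))


def rho_shadow(
    prepA,
    prepB,
    model: AtriumModel,
    geometry: ProjectionGeometry,
    T: RigidTransform,
    variant: str = "thr",
) -> float:
    """Shadow-matching objective: product over planes of NCC(I, S_T).

    ``variant='dsa'`` correlates the signed DSA image with the shadow,
    ``variant='thr'`` the binary contrast mask.
    """
    if variant not in ("dsa", "thr"):
        raise ValueError("variant must be 'dsa' or 'thr'")
    shape = geometry.image_shape
    S_A = render_shadow(model, geometry.P_A, T, shape)
    S_B = render_shadow(model, geometry.P_B, T, shape)
    if variant == "dsa":
        return ncc(prepA.I_DSA, S_A) * ncc(prepB.I_DSA, S_B)
    return ncc(prepA.I_thr, S_A) * ncc(prepB.I_thr, S_B)


def rho_edge(
    prepA,
    prepB,
    mesh,
    geometry: ProjectionGeometry,
    T: RigidTransform,
) -> float:
    """Edge objective: product over planes of NCC(I_DOG, E_T).

    The apparent-edge rendering is smoothed at the same scale as the DOG
    edge image so both live at a comparable resolution.
    """
    shape = geometry.image_shape
    sigma = float(prepA.params.get("dog_sigma", 0.0))
    E_A = render_apparent_edges(mesh, geometry.P_A, T, shape, smooth_sigma=sigma)
    E_B = render_apparent_edges(mesh, geometry.P_B, T, shape, smooth_sigma=sigma)
    return ncc(prepA.I_DOG, E_A) * ncc(prepB.I_DOG, E_B)


def rho_cade(
    prepA,
    prepB,
    model: AtriumModel,
    geometry: ProjectionGeometry,
    T: RigidTransform,
) -> float:
    """CADE consistency objective: product over planes of NCC(I_thr, C_T)."""
    res = compute_cade(model, prepA.I_thr, prepB.I_thr, geometry, T)
    return ncc(prepA.I_thr, res.C_A) * ncc(prepB.I_thr, res.C_B)


def rho_combined(
    prepA,
    prepB,
    model: AtriumModel,
    geometry: ProjectionGeometry,
    T: RigidTransform,
    config: SimilarityConfig,
) -> float:
    """Dispatch the configured measure; ``<base>+edge`` adds alpha * rho_edge."""
    base = config.base
    if base == "edge":
        return rho_edge(prepA, prepB, model.mesh, geometry, T)
    if base in ("shad_dsa", "shad_thr"):
        value = rho_shadow(prepA, prepB, model, geometry, T, variant=base.split("_")[1])
    elif base == "cade":
        value = rho_cade(prepA, prepB, model, geometry, T)
    else:  # pragma: no cover - guarded by SimilarityConfig
        raise ValueError(base)
    if config.measure.endswith("+edge"):
        value += config.alpha * rho_edge(prepA, prepB, model.mesh, geometry, T)
    return value


def evaluate_measure(
    measure: str,
    prepA,
    prepB,
    model: AtriumModel,
    geometry: ProjectionGeometry,
    T: RigidTransform,
    alpha: float = 1.0,
) -> float:
    """Convenience wrapper: evaluate a named measure at one transform."""
    return rho_combined(prepA, prepB, model, geometry, T, SimilarityConfig(measure, alpha))
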