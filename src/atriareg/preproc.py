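"""Contrast extraction from raw biplane frames.

Turns one plane of a raw sequence into the derived images the similarity
measures consume:

* ``I_DSA`` — best-reference digital subtraction angiography.  Among all
  uncontrasted frames the reference ``Iu_hat`` minimizing the L1 norm of
  ``I_u - I_c`` is chosen, so catheters and the diaphragm cancel as much as
  possible; ``I_DSA = Iu_hat - I_c`` (contrast darkens the image, so
  injected contrast appears positive).
* ``I_f`` — ``I_DSA`` with negatives clamped to 0 and a large-kernel median
  filter applied; small residual motion artifacts do not pass the filter.
* ``I_thr`` — binary contrast mask, thresholded at ``mu_f + sigma_f``
  (mean and standard deviation of ``I_f`` over all pixels).
* ``I_sig`` — sigmoid-homogenized ``I_f`` (midpoint at ``mu_f - sigma_f``),
  flattening intensity variation inside the contrasted area while keeping
  the drop-off at its boundary.
* ``I_DOG`` — gradient-of-Gaussian edge magnitude of ``I_sig`` at a large
  scale, giving a smooth edge response at the contrast boundary.

Pixel-unit defaults (median kernel 30 px, DOG sigma 24 px) refer to a
1024-wide detector and scale linearly with image width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessedPlane",
    "default_params",
    "dog_edges",
    "extract_contrast",
    "preprocess_plane",
    "scaled_median_kernel",
    "select_reference",
    "sigmoid_homogenize",
]

#: parameter reference values at 1024-px image width, 12-bit intensity range
MEDIAN_KERNEL_AT_1024 = 30
DOG_SIGMA_AT_1024 = 24.0
SIGMOID_S_AT_12BIT = 0.1
REFERENCE_RANGE = 4096


@dataclass
class PreprocessedPlane:
    """All derived images of one plane for one contrasted frame."""

    I_DSA: np.ndarray
    reference_index: int
    I_f: np.ndarray
    mu_f: float
    sigma_f: float
    I_thr: np.ndarray
    I_sig: np.ndarray
    I_DOG: np.ndarray
    params: dict


def scaled_median_kernel(image_width: int) -> int:
    """Median kernel width scaled from the 1024-px reference, rounded up to odd."""
    k = max(1, round(MEDIAN_KERNEL_AT_1024 * image_width / 1024))
    return k if k % 2 == 1 else k + 1


def scaled_dog_sigma(image_width: int) -> float:
    return DOG_SIGMA_AT_1024 * image_width / 1024.0


def sigmoid_slope(intensity_range: float) -> float:
    """Sigmoid steepness for a detector with the given dynamic range.

    The reference value 0.1 applies to 12-bit input; the slope scales
    inversely with dynamic range so the transition width stays a fixed
    fraction of it.
    """
    return SIGMOID_S_AT_12BIT * REFERENCE_RANGE / float(intensity_range)


def default_params(image_width: int, intensity_range: float = REFERENCE_RANGE) -> dict:
    return {
        "median_kernel": scaled_median_kernel(image_width),
        "sigmoid_s": sigmoid_slope(intensity_range),
        "dog_sigma": scaled_dog_sigma(image_width),
    }


def select_reference(uncontrasted_frames, I_c: np.ndarray) -> tuple[int, np.ndarray]:
    """Best-reference selection: minimize the L1 norm of the DSA image.

    Returns the index (into ``uncontrasted_frames``) of the frame
    ``Iu_hat = argmin_u sum |I_u - I_c|`` and the corresponding
    ``I_DSA = Iu_hat - I_c``.  Ties are broken by the lowest index.
    """
    if len(uncontrasted_frames) == 0:
        raise ValueError("at least one uncontrasted candidate frame is required")
    I_c = np.asarray(I_c, dtype=np.float64)
    costs = np.empty(len(uncontrasted_frames), dtype=np.float64)
    for i, I_u in enumerate(uncontrasted_frames):
        I_u = np.asarray(I_u, dtype=np.float64)
        if I_u.shape != I_c.shape:
            raise ValueError(f"candidate {i} shape {I_u.shape} != contrasted frame {I_c.shape}")
        costs[i] = np.abs(I_u - I_c).sum()
    idx = int(np.argmin(costs))  # argmin takes the first minimum: lowest index
    I_DSA = np.asarray(uncontrasted_frames[idx], dtype=np.float64) - I_c
    return idx, I_DSA


def extract_contrast(
    I_DSA: np.ndarray, median_kernel: int
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Clamp, median-filter and threshold the DSA image.

    Negative pixels (no contrast) are set to 0, a square median window of
    width ``median_kernel`` is applied (reflect padding), and the binary
    mask ``I_thr`` marks pixels strictly above ``mu_f + sigma_f``.  The
    strict comparison makes a constant image yield an empty mask.
    """
    if median_kernel % 2 != 1 or median_kernel < 1:
        raise ValueError("median_kernel must be a positive odd width")
    clamped = np.maximum(np.asarray(I_DSA, dtype=np.float64), 0.0)
    if median_kernel == 1:
        I_f = clamped
    else:
        I_f = ndimage.median_filter(clamped, size=median_kernel, mode="reflect")
    mu_f = float(I_f.mean())
    sigma_f = float(I_f.std())
    I_thr = I_f > mu_f + sigma_f
    return I_f, mu_f, sigma_f, I_thr


def sigmoid_homogenize(I_f: np.ndarray, mu_f: float, sigma_f: float, s: float) -> np.ndarray:
    """Sigmoid intensity homogenization with midpoint ``t = mu_f - sigma_f``.

    ``I_sig = 1 / (1 + exp(-(I_f - t) * s))``: strictly increasing in
    ``I_f``, ~0 for background, ~1 well inside the contrasted area, with
    the transition (and hence the retained edge information) located just
    below typical contrast intensity.
    """
    t = mu_f - sigma_f
    arg = np.clip(-(np.asarray(I_f, dtype=np.float64) - t) * s, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(arg))


def dog_edges(I_sig: np.ndarray, dog_sigma: float) -> np.ndarray:
    """Gradient-of-Gaussian edge magnitude at scale ``dog_sigma`` px.

    Euclidean magnitude of the two first-order Gaussian-derivative
    responses (reflect padding); the large default scale gives a smooth,
    wide similarity basin rather than thin edges.
    """
    I = np.asarray(I_sig, dtype=np.float64)
    gx = ndimage.gaussian_filter(I, dog_sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(I, dog_sigma, order=(1, 0), mode="reflect")
    return np.hypot(gx, gy)


def preprocess_plane(
    uncontrasted_frames,
    I_c: np.ndarray,
    intensity_range: float = REFERENCE_RANGE,
    median_kernel: int | None = None,
    dog_sigma: float | None = None,
    sigmoid_s: float | None = None,
) -> PreprocessedPlane:
    """Full per-plane pipeline: best-reference DSA through the DOG edge image."""
    I_c = np.asarray(I_c, dtype=np.float64)
    width = I_c.shape[1]
    if median_kernel is None:
        median_kernel = scaled_median_kernel(width)
    if dog_sigma is None:
        dog_sigma = scaled_dog_sigma(width)
    if sigmoid_s is None:
        sigmoid_s = sigmoid_slope(intensity_range)

    ref_idx, I_DSA = select_reference(uncontrasted_frames, I_c)
    I_f, mu_f, sigma_f, I_thr = extract_contrast(I_DSA, median_kernel)
    I_sig = sigmoid_homogenize(I_f, mu_f, sigma_f, sigmoid_s)
    I_DOG = dog_edges(I_sig, dog_sigma)
    return PreprocessedPlane(
        I_DSA=I_DSA,
        reference_index=ref_idx,
        I_f=I_f,
        mu_f=mu_f,
        sigma_f=sigma_f,
        I_thr=I_thr,
        I_sig=I_sig,
        I_DOG=I_DOG,
        params={
            "median_kernel": median_kernel,
            "sigmoid_s": sigmoid_s,
            "sigmoid_t": mu_f - sigma_f,
            "dog_sigma": dog_sigma,
        },
    )


def dump_debug(prep: PreprocessedPlane, directory, stem: str = "plane") -> list[str]:
    """Write every intermediate grid as a float32 TIFF for inspection."""
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("I_DSA", "I_f", "I_thr", "I_sig", "I_DOG"):
        path = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(path, getattr(prep, name).astype(np.float32))
        written.append(str(path))
    return written


def preprocess_frame(sequence, frame_index: int) -> tuple[PreprocessedPlane, PreprocessedPlane]:
    """Preprocess both planes of one contrasted frame of a sequence."""
    if not sequence.contrasted[frame_index]:
        raise ValueError(f"frame {frame_index} is annotated uncontrasted")
    unc = np.flatnonzero(~sequence.contrasted)
    if unc.size == 0:
        raise ValueError("sequence contains no uncontrasted frames for DSA")
    preps = []
    for plane in ("A", "B"):
        stack = sequence.frames(plane)
        candidates = [stack[i] for i in unc]
        preps.append(
            preprocess_plane(candidates, stack[frame_index], sequence.intensity_range)
        )
    return preps[0], preps[1]
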