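"""File I/O, run configuration and the end-to-end pipeline.

Formats: meshes as STL/PLY (trimesh), volumes as MHD/NIfTI (SimpleITK),
sequences as one multi-page TIFF per plane plus a JSON sidecar carrying the
contrast annotations, frame rate and (for phantoms) the ground truth;
projection geometry as JSON with two row-major 3x4 matrices.  Transforms
and reports are JSON, human-diffable, with a versioned schema.  Clinical
DICOM ingestion is deliberately out of scope; converters are expected
upstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import trimesh
from numba import njit

from . import __version__
from ._util import logger
from .phantom import (
    BiplaneSequence,
    GroundTruth,
    InjectionScenario,
    PhantomSpec,
    _mesh_from_volume,
    build_phantom,
    center_injection_scenario,
    simulate_sequence,
    vein_injection_scenario,
)
from .projection import AtriumModel, ProjectionGeometry, RigidTransform, make_biplane_geometry
from .registration import SearchConfig, register_sequence, select_best_frame
from .similarity import MEASURES
from .temporal import (
    ConfidenceModel,
    Trajectory,
    TransitionModel,
    evaluate_trajectory,
    fit_confidence,
    fit_transition,
    smooth,
)

__all__ = [
    "RunConfig",
    "read_geometry",
    "read_model",
    "read_sequence",
    "run_pipeline",
    "write_geometry",
    "write_model",
    "write_sequence",
]

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# geometry I/O
# ---------------------------------------------------------------------------


def write_geometry(geometry: ProjectionGeometry, path) -> None:
    Path(path).write_text(json.dumps(geometry.to_dict(), indent=2, sort_keys=True))


def read_geometry(path) -> ProjectionGeometry:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    return ProjectionGeometry.from_dict(json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------


@njit(cache=True)
def _parity_fill(tris, xs, ys, zs):  # pragma: no cover - numba
    """Center-inside voxelization of a closed surface by z-column parity.

    A voxel center is inside iff an odd number of surface crossings lie
    above it along its vertical column.
    """
    nx, ny, nz = xs.size, ys.size, zs.size
    out = np.zeros((nx, ny, nz), dtype=np.uint8)
    for t in range(tris.shape[0]):
        ax, ay, az = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
        bx, by, bz = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
        cx, cy, cz = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]
        det = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if det == 0.0:
            continue
        xlo = min(ax, min(bx, cx))
        xhi = max(ax, max(bx, cx))
        ylo = min(ay, min(by, cy))
        yhi = max(ay, max(by, cy))
        for ix in range(nx):
            x = xs[ix]
            if x < xlo or x > xhi:
                continue
            for iy in range(ny):
                y = ys[iy]
                if y < ylo or y > yhi:
                    continue
                w0 = ((by - cy) * (x - cx) + (cx - bx) * (y - cy)) / det
                w1 = ((cy - ay) * (x - cx) + (ax - cx) * (y - cy)) / det
                w2 = 1.0 - w0 - w1
                if w0 >= 0.0 and w1 >= 0.0 and w2 >= 0.0:
                    z = w0 * az + w1 * bz + w2 * cz
                    for iz in range(nz):
                        if zs[iz] < z:
                            out[ix, iy, iz] ^= 1
    return out


def voxelize_mesh(mesh: trimesh.Trimesh, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a watertight mesh: a voxel is set iff its center is inside.

    Returns ``(volume, origin)``.  Implemented by vertical-column parity
    counting; sample columns are offset by a tiny irrational fraction of the
    spacing so they never pass exactly through mesh edges or vertices.
    """
    lo, hi = mesh.bounds
    eps = spacing * 1e-4 * np.sqrt(2.0)
    origin = lo - spacing + eps
    counts = np.ceil((hi - origin) / spacing).astype(int) + 1
    xs, ys, zs = (origin[k] + spacing * np.arange(counts[k]) for k in range(3))
    tris = np.ascontiguousarray(mesh.triangles.astype(np.float64))
    vol = _parity_fill(tris, xs, ys, zs).astype(bool)
    return vol, origin


def read_model(path, spacing: float = 2.0) -> AtriumModel:
    """Load a chamber model; both representations are always populated.

    STL/PLY meshes are voxelized at ``spacing`` (refused, with a
    diagnostic, if the mesh is not watertight — an open surface has no
    well-defined interior indicator).  MHD/NIfTI volumes are binarized at
    0.5 and a surface mesh is extracted by marching cubes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".stl", ".ply"):
        mesh = trimesh.load(str(path), force="mesh")
        if not mesh.is_watertight:
            raise ValueError(
                f"mesh {path} is not watertight: voxelization of an open surface "
                "has no defined interior; repair the mesh upstream"
            )
        volume, origin = voxelize_mesh(mesh, spacing)
        return AtriumModel(volume=volume, spacing=spacing, origin=origin, mesh=mesh)
    if suffix in (".mhd", ".nii") or path.name.lower().endswith(".nii.gz"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        sp = img.GetSpacing()
        if max(sp) - min(sp) > 1e-6:
            raise ValueError(f"volume {path} has anisotropic spacing {sp}; resample upstream")
        # SimpleITK arrays are (z, y, x); store as (x, y, z)
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0) > 0.5
        origin = np.asarray(img.GetOrigin(), dtype=float)
        mesh = _mesh_from_volume(arr, float(sp[0]), origin)
        return AtriumModel(volume=arr, spacing=float(sp[0]), origin=origin, mesh=mesh)
    raise ValueError(f"unsupported model format: {path}")


def write_model(model: AtriumModel, directory, stem: str = "model") -> dict:
    """Write the model as MHD volume + STL mesh; returns the paths."""
    import SimpleITK as sitk

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(model.volume.transpose(2, 1, 0).astype(np.uint8))
    img.SetSpacing((model.spacing,) * 3)
    img.SetOrigin(tuple(model.origin))
    vol_path = directory / f"{stem}.mhd"
    sitk.WriteImage(img, str(vol_path))
    mesh_path = directory / f"{stem}.stl"
    model.mesh.export(str(mesh_path))
    return {"volume": str(vol_path), "mesh": str(mesh_path)}


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------


def write_sequence(
    sequence: BiplaneSequence,
    directory,
    truth: GroundTruth | None = None,
    stem: str = "seq",
) -> dict:
    """Write a biplane sequence: TIFF stack per plane + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path_a = directory / f"{stem}_A.tif"
    path_b = directory / f"{stem}_B.tif"
    tifffile.imwrite(path_a, sequence.frames_a, photometric="minisblack")
    tifffile.imwrite(path_b, sequence.frames_b, photometric="minisblack")
    sidecar = {
        "contrasted": sequence.contrasted.astype(int).tolist(),
        "frame_rate": sequence.frame_rate,
        "intensity_range": sequence.intensity_range,
    }
    if truth is not None:
        sidecar["ground_truth_translations"] = truth.translations.tolist()
    sidecar_path = directory / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    geom_path = directory / f"{stem}_geometry.json"
    write_geometry(sequence.geometry, geom_path)
    return {
        "plane_a": str(path_a),
        "plane_b": str(path_b),
        "sidecar": str(sidecar_path),
        "geometry": str(geom_path),
    }


def _read_stack(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sequence file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def read_sequence(path_a, path_b, sidecar, geometry_path=None) -> tuple:
    """Read a biplane sequence; returns ``(BiplaneSequence, truth or None)``.

    Validates equal frame counts across planes and full annotation
    coverage.  8- and 16-bit inputs are both accepted; the recorded
    intensity range drives the sigmoid slope downstream.
    """
    frames_a = _read_stack(path_a)
    frames_b = _read_stack(path_b)
    if frames_a.shape != frames_b.shape:
        raise ValueError(
            f"plane frame counts/shapes differ: {frames_a.shape} vs {frames_b.shape}"
        )
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    contrasted = meta.get("contrasted")
    if contrasted is None or len(contrasted) != frames_a.shape[0]:
        missing = (
            "all" if contrasted is None
            else list(range(len(contrasted), frames_a.shape[0]))
        )
        raise ValueError(f"annotation missing for frames: {missing}")
    if "intensity_range" in meta:
        intensity_range = int(meta["intensity_range"])
    else:
        intensity_range = 256 if frames_a.dtype == np.uint8 else 4096
    if geometry_path is None:
        geometry_path = sidecar.with_name(sidecar.stem + "_geometry.json")
    geometry = read_geometry(geometry_path)
    seq = BiplaneSequence(
        frames_a=frames_a,
        frames_b=frames_b,
        contrasted=np.asarray(contrasted, dtype=bool),
        frame_rate=float(meta.get("frame_rate", 10.0)),
        geometry=geometry,
        intensity_range=intensity_range,
    )
    truth = None
    if "ground_truth_translations" in meta:
        t = np.asarray(meta["ground_truth_translations"], dtype=float)
        truth = GroundTruth(translations=t, voxel_masks=[np.zeros(0, bool)] * t.shape[0])
    return seq, truth


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one registration run needs.

    Either file paths (``model_path``/``geometry_path``/``sequence_*``) or
    ``phantom=True`` (generate the default synthetic phantom internally,
    with ground truth).  ``frames`` is ``"all"``, ``"best"`` or an explicit
    list of frame indices.  ``temporal=True`` appends Markov filtering,
    using confidence/transition model files when given and otherwise
    training them on sequences generated from held-out phantom seeds.
    """

    measure: str = "cade+edge"
    frames: object = "all"
    search: SearchConfig = field(default_factory=SearchConfig)
    seed: int = 0
    phantom: bool = False
    phantom_scenario: str = "center"
    noise_sd: float = 8.0
    model_path: str | None = None
    geometry_path: str | None = None
    sequence_a: str | None = None
    sequence_b: str | None = None
    sidecar: str | None = None
    confidence_path: str | None = None
    transition_path: str | None = None
    output_dir: str | None = None
    verbosity: str = "INFO"

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    d = config.to_jsonable()
    # where the report is written (and how chatty the log is) does not
    # change the computation: identical science -> identical hash
    d.pop("output_dir", None)
    d.pop("verbosity", None)
    payload = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _default_phantom(config: RunConfig):
    spec = PhantomSpec(seed=config.seed)
    model = build_phantom(spec)
    geometry = make_biplane_geometry()
    if config.phantom_scenario == "vein":
        scenario = vein_injection_scenario(noise_sd=config.noise_sd)
    else:
        scenario = center_injection_scenario(noise_sd=config.noise_sd)
    seq, truth = simulate_sequence(
        model, scenario, geometry, seed=spec.seed, pv_specs=spec.pv_specs
    )
    return model, seq, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom/load -> register -> (filter) -> evaluate; return report.

    The JSON report records software version, config hash and seed for
    reproducibility; identical config and seed give a byte-identical
    report.  When ground truth is available, per-frame Euclidean errors
    against it are included.
    """
    if config.measure not in MEASURES:
        raise ValueError(f"unknown measure {config.measure!r}")
    if config.phantom:
        model, sequence, truth = _default_phantom(config)
    else:
        if not (config.model_path and config.sequence_a and config.sequence_b and config.sidecar):
            raise ValueError("non-phantom runs need model_path, sequence_a/b and sidecar")
        model = read_model(config.model_path)
        sequence, truth = read_sequence(
            config.sequence_a, config.sequence_b, config.sidecar, config.geometry_path
        )

    contrasted = [i for i in range(sequence.n_frames) if sequence.contrasted[i]]
    if config.frames == "all" or config.frames == "best":
        indices = contrasted
    else:
        indices = list(config.frames)
    logger.info("registering %d frame(s) with measure %s", len(indices), config.measure)
    regs = register_sequence(
        sequence, model, config=config.search, measure=config.measure, frame_indices=indices
    )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "measure": config.measure,
        "frames": [
            {
                "frame_index": r.frame_index,
                "t_hat_mm": r.T_prime.t.tolist(),
                "rho": r.rho_value,
            }
            for r in regs
        ],
    }

    if config.frames == "best":
        best = select_best_frame(regs)
        report["best_frame"] = best

    truth_map = None
    if truth is not None:
        truth_map = {i: truth.translations[i] for i in range(truth.n_frames)}
        for entry, r in zip(report["frames"], regs):
            err = float(np.linalg.norm(r.T_prime.t - truth_map[r.frame_index]))
            entry["error_mm"] = err
        errs = [e["error_mm"] for e in report["frames"]]
        report["mean_error_mm"] = float(np.mean(errs))

    if getattr(config, "temporal", False) or (config.confidence_path and config.transition_path):
        if config.confidence_path and config.transition_path:
            confidence = ConfidenceModel.from_dict(
                json.loads(Path(config.confidence_path).read_text())
            )
            transition = TransitionModel.from_dict(
                json.loads(Path(config.transition_path).read_text())
            )
        else:
            raise ValueError("temporal filtering requires confidence and transition model files")
        traj = Trajectory(frames=regs, frame_rate=sequence.frame_rate)
        filtered = smooth(traj, confidence, transition)
        report["filtered"] = [t.t.tolist() for t in filtered]
        if truth_map is not None:
            ft = [truth_map[r.frame_index] for r in regs]
            stats = evaluate_trajectory(filtered, ft)
            report["filtered_mean_error_mm"] = stats["mean"]

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def train_temporal(truth_series, training_pairs, out_confidence=None, out_transition=None):
    """Fit the confidence regression and velocity covariance; optionally save.

    ``truth_series`` is a list of ``(translations (n,3), frame_rate)``;
    ``training_pairs`` a list of ``(rho, observed_error_mm)``.
    """
    confidence = fit_confidence(training_pairs)
    transition = fit_transition(truth_series)
    if out_confidence:
        Path(out_confidence).write_text(json.dumps(confidence.to_dict(), indent=2, sort_keys=True))
    if out_transition:
        Path(out_transition).write_text(json.dumps(transition.to_dict(), indent=2, sort_keys=True))
    return confidence, transition
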