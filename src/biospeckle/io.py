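"""Reading and writing speckle frame stacks.

Two lossless on-disk layouts: multi-page grayscale TIFF (the canonical
format for scientific stacks) and raw uint8 binary with dimensions held
in the sidecar. Every stack carries a JSON sidecar (same stem, ``.json``)
with acquisition metadata; a missing sidecar degrades to defaults with a
warning (15 fps, the standard acquisition rate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, CorruptFileError
from .synthetic import CameraModel, OpticalGeometry, SpeckleSequence

__all__ = ["SequenceManifest", "read_sequence", "write_sequence", "DEFAULT_FPS"]

DEFAULT_FPS = 15.0
SIDECAR_SCHEMA_VERSION = 1
_FORMATS = ("tiff-stack", "raw-u8")


@dataclass
class SequenceManifest:
    """Where a stored sequence lives and how to interpret the payload."""

    path: Path
    format: str
    height: int
    width: int
    n_frames: int
    fps: float
    sidecar: dict

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.format not in _FORMATS:
            raise ConfigError(f"unknown format {self.format!r}; expected one of {_FORMATS}")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")


def _sidecar_path(path: Path) -> Path:
    # append rather than replace the suffix, so a.tif and a.raw coexist
    return path.with_name(path.name + ".json")


def _geometry_to_dict(g: OpticalGeometry | None) -> dict | None:
    return None if g is None else asdict(g)


def write_sequence(
    sequence: SpeckleSequence, path: str | Path, format: str = "tiff-stack"
) -> SequenceManifest:
    """Store a sequence losslessly and emit its JSON sidecar.

    Returns the manifest describing the written payload.
    """
    path = Path(path)
    frames = np.asarray(sequence.frames)
    cam = sequence.camera
    max_allowed = cam.max_gray if cam is not None else np.iinfo(frames.dtype).max
    if frames.min() < 0 or frames.max() > max_allowed:
        raise ConfigError(
            f"gray values outside [0, {max_allowed}] cannot be written losslessly"
        )
    if format == "tiff-stack":
        tifffile.imwrite(path, frames, photometric="minisblack")
    elif format == "raw-u8":
        if frames.dtype != np.uint8:
            raise ConfigError("raw-u8 format requires uint8 frames")
        path.write_bytes(frames.tobytes())
    else:
        raise ConfigError(f"unknown format {format!r}; expected one of {_FORMATS}")

    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "format": format,
        "shape": list(frames.shape),
        "dtype": str(frames.dtype),
        "fps": sequence.fps,
        "condition": sequence.condition,
        "plant_id": sequence.plant_id,
        "age_dap": sequence.age_dap,
        "cycle": sequence.cycle,
        "acquisition": sequence.acquisition,
        "seed": sequence.seed,
        "rho": sequence.rho,
        "geometry": _geometry_to_dict(sequence.geometry),
        "camera": None if cam is None else asdict(cam),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return SequenceManifest(
        path=path,
        format=format,
        height=frames.shape[1],
        width=frames.shape[2],
        n_frames=frames.shape[0],
        fps=sequence.fps,
        sidecar=sidecar,
    )


def _load_sidecar(path: Path) -> dict:
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        warnings.warn(
            f"no sidecar {sc_path.name}; assuming defaults (fps={DEFAULT_FPS})",
            stacklevel=3,
        )
        return {}
    return json.loads(sc_path.read_text())


def read_sequence(source: SequenceManifest | str | Path) -> SpeckleSequence:
    """Load a stored sequence back into memory, bit-identically.

    ``source`` is a manifest or a path to the payload; metadata is merged
    from the sidecar. Payloads inconsistent with their declared
    dimensions raise :class:`CorruptFileError`.
    """
    if isinstance(source, SequenceManifest):
        path = source.path
        sidecar = source.sidecar or _load_sidecar(path)
        fmt = source.format
    else:
        path = Path(source)
        if not path.exists():
            raise CorruptFileError(f"no such file: {path}")
        sidecar = _load_sidecar(path)
        fmt = sidecar.get("format") or (
            "tiff-stack" if path.suffix.lower() in (".tif", ".tiff") else "raw-u8"
        )

    if fmt == "tiff-stack":
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types on truncation
            raise CorruptFileError(f"cannot decode TIFF stack {path}: {exc}") from exc
        frames = np.atleast_3d(frames)
        if frames.ndim != 3:
            raise CorruptFileError(f"{path} is not a frame stack (ndim={frames.ndim})")
        if "shape" in sidecar and list(frames.shape) != list(sidecar["shape"]):
            raise CorruptFileError(
                f"{path}: payload shape {frames.shape} != sidecar {sidecar['shape']}"
            )
    elif fmt == "raw-u8":
        if "shape" not in sidecar:
            raise CorruptFileError(f"{path}: raw payload without shape in sidecar")
        shape = tuple(sidecar["shape"])
        payload = path.read_bytes()
        expected = int(np.prod(shape))
        if len(payload) != expected:
            raise CorruptFileError(
                f"{path}: payload is {len(payload)} bytes, expected {expected}"
            )
        frames = np.frombuffer(payload, dtype=np.uint8).reshape(shape)
    else:
        raise CorruptFileError(f"unknown stored format {fmt!r}")

    geometry = sidecar.get("geometry")
    camera = sidecar.get("camera")
    return SpeckleSequence(
        frames=frames,
        fps=float(sidecar.get("fps") or DEFAULT_FPS),
        geometry=OpticalGeometry(**geometry) if geometry else None,
        camera=CameraModel(**camera) if camera else None,
        condition=sidecar.get("condition", "unknown"),
        plant_id=int(sidecar.get("plant_id", 0)),
        age_dap=int(sidecar.get("age_dap", 30)),
        cycle=int(sidecar.get("cycle", 1)),
        acquisition=int(sidecar.get("acquisition", 1)),
        seed=sidecar.get("seed"),
        rho=sidecar.get("rho"),
    )
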