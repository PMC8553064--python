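"""Seeded simulation of dynamic laser speckle image sequences.

The generator stands in for raw leaf videos: fully developed speckle of a
prescribed spatial size, first-order autoregressive temporal decorrelation
of the complex field (the stand-in for intracellular motion), and a camera
model with readout noise and quantization.

The temporal model mixes the complex field with an independent fresh field,

    E_{k+1} = rho * E_k + sqrt(1 - rho^2) * E_fresh,

so the field correlation at lag k is rho**k and, by the Siegert relation
for circular Gaussian fields, the intensity correlation is rho**(2*k).
The biospeckle activity of a noise-free sequence therefore has the closed
form BA_k = 1 - rho**(2*k), which anchors the calibration tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import j1

from .errors import ConfigError, InvalidGeometryError, UndersamplingError

__all__ = [
    "OpticalGeometry",
    "CameraModel",
    "DecorrelationModel",
    "SpeckleSequence",
    "StudyConfig",
    "theoretical_speckle_size",
    "generate_base_field",
    "evolve_field",
    "render_camera",
    "render_dark_frames",
    "simulate_sequence",
    "simulate_study",
    "simulate_ba_matrix",
    "rho_for_plateau",
    "plateau_for_rho",
    "derive_seed",
    "default_rho_map",
    "DEFAULT_PLATEAUS",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class OpticalGeometry:
    """Off-axis speckle imaging geometry.

    Parameters
    ----------
    wavelength_nm
        Laser wavelength in nanometres.
    distance_mm
        Sample-to-detector distance D in millimetres.
    beam_width_mm
        Illuminated width a (beam size on the sample) in millimetres.
    pixel_pitch_um
        Detector pixel pitch in micrometres.
    """

    wavelength_nm: float = 635.0
    distance_mm: float = 167.0
    beam_width_mm: float = 2.45
    pixel_pitch_um: float = 5.2

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "distance_mm", "beam_width_mm", "pixel_pitch_um"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.beam_width_mm >= self.distance_mm:
            raise InvalidGeometryError("beam_width_mm must be smaller than distance_mm")

    @property
    def speckle_size_um(self) -> float:
        return theoretical_speckle_size(self)

    @property
    def speckle_size_px(self) -> float:
        return self.speckle_size_um / self.pixel_pitch_um


@dataclass(frozen=True)
class CameraModel:
    """CMOS camera noise model: readout noise, full-well gain and bit depth.

    ``full_well_scale`` is the conversion gain in electrons per gray level,
    so the readout noise expressed on the gray scale is
    ``readout_noise_e / full_well_scale``.
    """

    bit_depth: int = 8
    readout_noise_e: float = 25.0
    full_well_scale: float = 50.0

    def __post_init__(self) -> None:
        if self.bit_depth < 1:
            raise ConfigError("bit_depth must be >= 1")
        if self.readout_noise_e < 0:
            raise ConfigError("readout_noise_e must be >= 0")
        if self.full_well_scale <= 0:
            raise ConfigError("full_well_scale must be > 0")

    @property
    def max_gray(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def readout_sigma_gray(self) -> float:
        return self.readout_noise_e / self.full_well_scale


@dataclass(frozen=True)
class DecorrelationModel:
    """Per-frame complex-field correlation for one exposure condition."""

    rho: float
    label: str = "unnamed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must lie in [0, 1], got {self.rho}")
        if self.label == "phantom" and self.rho != 1.0:
            raise ConfigError("a phantom (inanimate) condition must have rho = 1")


@dataclass
class SpeckleSequence:
    """A time-ordered stack of gray-level frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width), unsigned integer
    fps: float
    geometry: OpticalGeometry | None = None
    camera: CameraModel | None = None
    condition: str = "unknown"
    plant_id: int = 0
    age_dap: int = 30
    cycle: int = 1
    acquisition: int = 1
    seed: int | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (n_frames, height, width) array")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Time of frame k, with frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.fps

    @property
    def meta(self) -> dict:
        return {
            "condition": self.condition,
            "plant_id": self.plant_id,
            "age_dap": self.age_dap,
            "cycle": self.cycle,
            "acquisition": self.acquisition,
            "fps": self.fps,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Speckle size


def theoretical_speckle_size(geometry: OpticalGeometry) -> float:
    """Objective speckle size lambda * D / a, in micrometres."""
    lam_um = geometry.wavelength_nm * 1e-3
    d_um = geometry.distance_mm * 1e3
    a_um = geometry.beam_width_mm * 1e3
    return lam_um * d_um / a_um


def _jinc(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


# First x with |2 J1(x)/x|^2 = 1/2: sets the pupil cutoff for a requested
# intensity-autocovariance FWHM.
_JINC2_HALF_X: float = float(brentq(lambda x: _jinc(np.array([x]))[0] - 2**-0.5, 1.0, 2.5))


def _pupil_cutoff_cycles(speckle_size_px: float) -> float:
    """Pupil radius (cycles/pixel) so the intensity autocovariance FWHM
    equals ``speckle_size_px``."""
    return _JINC2_HALF_X / (np.pi * speckle_size_px)


# ---------------------------------------------------------------------------
# Field generation and evolution


def _as_rng(seed: int | SeedSequence | Generator | None) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def generate_base_field(
    shape: tuple[int, ...],
    speckle_size_px: float,
    seed: int | SeedSequence | Generator | None,
) -> np.ndarray:
    """Fully developed speckle field: circular complex Gaussian noise
    low-pass filtered by a circular pupil.

    ``shape`` may carry leading batch dimensions; the pupil acts on the
    last two axes. The field is normalized to unit mean intensity per
    batch element, so ``|field|**2`` follows Exp(1) marginally.
    """
    if speckle_size_px < 2:
        raise UndersamplingError(
            f"speckle_size_px must be >= 2 pixels (Nyquist), got {speckle_size_px}"
        )
    if len(shape) < 2 or shape[-2] < 32 or shape[-1] < 32:
        raise ConfigError("frame shape must be at least 32x32")
    rng = _as_rng(seed)
    fy = np.fft.fftfreq(shape[-2])[:, None]
    fx = np.fft.fftfreq(shape[-1])[None, :]
    pupil = (fy**2 + fx**2) <= _pupil_cutoff_cycles(speckle_size_px) ** 2
    # iid circular Gaussian spectrum on the pupil support only: identical in
    # law to low-pass filtering white noise, but cheaper by the pupil's
    # area fraction (one inverse FFT, no forward FFT)
    n_sup = int(pupil.sum())
    coeff = np.zeros(shape, dtype=complex)
    draws = rng.standard_normal(shape[:-2] + (2, n_sup))
    coeff[..., pupil] = draws[..., 0, :] + 1j * draws[..., 1, :]
    fld = np.fft.ifft2(coeff)
    mean_int = np.mean(np.abs(fld) ** 2, axis=(-2, -1), keepdims=True)
    return fld / np.sqrt(mean_int)


def evolve_field(
    fld: np.ndarray,
    rho: float | np.ndarray,
    seed: int | SeedSequence | Generator | None,
    speckle_size_px: float,
) -> np.ndarray:
    """One autoregressive decorrelation step of the complex field.

    Returns ``rho * fld + sqrt(1 - rho**2) * fresh`` with ``fresh`` an
    independent field from the same pupil; marginal statistics are
    preserved. ``rho`` may be a scalar or broadcast over batch elements
    (shape ``batch + (1, 1)``).
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0) or np.any(rho_arr > 1):
        raise ConfigError(f"rho must lie in [0, 1], got {rho}")
    if rho_arr.ndim == 0 and rho_arr == 1.0:
        return fld.copy()
    fresh = generate_base_field(fld.shape, speckle_size_px, seed)
    return rho_arr * fld + np.sqrt(1.0 - rho_arr**2) * fresh


# ---------------------------------------------------------------------------
# Camera


def render_camera(
    intensity: np.ndarray,
    camera: CameraModel,
    seed: int | SeedSequence | Generator | None,
    target_mean_gray: float | None = None,
) -> np.ndarray:
    """Scale an intensity field to gray levels, add readout noise,
    clip to the ADC range and quantize.

    The mean intensity is mapped to ``target_mean_gray`` (default a
    quarter of full scale, leaving headroom for the long exponential
    tail of speckle intensity).
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ConfigError("intensity must be nonnegative")
    if target_mean_gray is None:
        target_mean_gray = (camera.max_gray + 1) / 4.0
    mean = intensity.mean()
    scaled = intensity * (target_mean_gray / mean) if mean > 0 else intensity
    rng = _as_rng(seed)
    if camera.readout_sigma_gray > 0:
        scaled = scaled + rng.normal(0.0, camera.readout_sigma_gray, size=scaled.shape)
    clipped = np.clip(np.rint(scaled), 0, camera.max_gray)
    dtype = np.uint8 if camera.bit_depth <= 8 else (np.uint16 if camera.bit_depth <= 16 else np.uint32)
    return clipped.astype(dtype)


def render_dark_frames(
    camera: CameraModel,
    shape: tuple[int, int],
    n_frames: int,
    seed: int | SeedSequence | Generator | None,
    offset_gray: float = 10.0,
) -> np.ndarray:
    """Dark frames (no light): a constant bias offset plus readout noise.

    The offset keeps the Gaussian noise clear of the zero clip so the
    dark frames carry an unbiased sample of the readout noise.
    """
    rng = _as_rng(seed)
    frames = offset_gray + rng.normal(
        0.0, camera.readout_sigma_gray, size=(n_frames,) + tuple(shape)
    )
    clipped = np.clip(np.rint(frames), 0, camera.max_gray)
    dtype = np.uint8 if camera.bit_depth <= 8 else np.uint16
    return clipped.astype(dtype)


# ---------------------------------------------------------------------------
# Sequences


def simulate_sequence(
    geometry: OpticalGeometry,
    camera: CameraModel,
    decorr: DecorrelationModel,
    fps: float = 15.0,
    duration_s: float = 20.0,
    seed: int | SeedSequence | None = 0,
    shape: tuple[int, int] = (256, 256),
    target_mean_gray: float | None = None,
    **meta,
) -> SpeckleSequence:
    """Simulate one acquisition: an autoregressive speckle movie rendered
    through the camera model.

    Frame 0 comes from :func:`generate_base_field`; frame k applies k
    decorrelation steps; every frame gets an independent readout-noise
    draw.
    """
    if fps <= 0 or duration_s <= 0:
        raise ConfigError("fps and duration_s must be positive")
    n_frames = int(round(fps * duration_s))
    speckle_px = geometry.speckle_size_px
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    ss_field, ss_noise = ss.spawn(2)
    field_children = ss_field.spawn(n_frames)
    noise_children = ss_noise.spawn(n_frames)

    frames = np.empty((n_frames,) + tuple(shape), dtype=np.uint8 if camera.bit_depth <= 8 else np.uint16)
    fld = generate_base_field(tuple(shape), speckle_px, field_children[0])
    frames[0] = render_camera(np.abs(fld) ** 2, camera, noise_children[0], target_mean_gray)
    for k in range(1, n_frames):
        fld = evolve_field(fld, decorr.rho, field_children[k], speckle_px)
        frames[k] = render_camera(np.abs(fld) ** 2, camera, noise_children[k], target_mean_gray)
    return SpeckleSequence(
        frames=frames,
        fps=fps,
        geometry=geometry,
        camera=camera,
        condition=decorr.label,
        seed=seed if isinstance(seed, int) else None,
        rho=decorr.rho,
        **meta,
    )


# ---------------------------------------------------------------------------
# Plateau <-> rho calibration

_DEFAULT_FPS = 15.0
_DEFAULT_DURATION_S = 20.0
_DEFAULT_PLATEAU_WINDOW_S = 5.0


def _plateau_lags(fps: float, duration_s: float, window_s: float) -> np.ndarray:
    n_frames = int(round(fps * duration_s))
    lags = np.arange(1, n_frames)
    times = lags / fps
    return lags[times > (n_frames - 1) / fps - window_s]


def plateau_for_rho(
    rho: float,
    fps: float = _DEFAULT_FPS,
    duration_s: float = _DEFAULT_DURATION_S,
    window_s: float = _DEFAULT_PLATEAU_WINDOW_S,
) -> float:
    """Expected late-window mean BA, mean over the final ``window_s`` of
    the closed form 1 - rho**(2k)."""
    lags = _plateau_lags(fps, duration_s, window_s)
    return float(np.mean(1.0 - rho ** (2.0 * lags)))


def rho_for_plateau(
    plateau: float,
    fps: float = _DEFAULT_FPS,
    duration_s: float = _DEFAULT_DURATION_S,
    window_s: float = _DEFAULT_PLATEAU_WINDOW_S,
) -> float:
    """Invert :func:`plateau_for_rho`: the per-frame field correlation
    whose noise-free BA curve plateaus at ``plateau``."""
    if not (0.0 < plateau < 1.0):
        raise ConfigError("plateau must lie strictly between 0 and 1")
    return float(
        brentq(
            lambda r: plateau_for_rho(r, fps, duration_s, window_s) - plateau,
            1e-9,
            1.0 - 1e-12,
            xtol=1e-14,
        )
    )


# ---------------------------------------------------------------------------
# Study-scale simulation

#: Late-window BA levels emulating the reported leaf measurements: the
#: control leaf decorrelates fastest (plateau ~0.9); music and
#: single-frequency stimuli slow the internal activity, most strongly at
#: 10 kHz in the older (30 dap) plants, while 14 dap plants respond weakly.
DEFAULT_PLATEAUS: Mapping[tuple[str, int], float] = {
    ("control", 14): 0.90,
    ("control", 30): 0.90,
    ("100Hz", 14): 0.88,
    ("100Hz", 30): 0.80,
    ("1kHz", 14): 0.85,
    ("1kHz", 30): 0.65,
    ("10kHz", 14): 0.82,
    ("10kHz", 30): 0.45,
    ("classic", 14): 0.70,
    ("classic", 30): 0.70,
    ("rock", 14): 0.50,
    ("rock", 30): 0.50,
}


def default_rho_map(
    conditions: Iterable[str],
    ages: Iterable[int],
    fps: float = _DEFAULT_FPS,
    duration_s: float = _DEFAULT_DURATION_S,
) -> dict[tuple[str, int], float]:
    """Condition x age -> rho, from the default plateau calibration.

    The phantom (inanimate paper) condition is static: rho = 1.
    """
    out: dict[tuple[str, int], float] = {}
    for cond in conditions:
        for age in ages:
            if cond == "phantom":
                out[(cond, age)] = 1.0
            elif (cond, age) in DEFAULT_PLATEAUS:
                out[(cond, age)] = rho_for_plateau(
                    DEFAULT_PLATEAUS[(cond, age)], fps, duration_s
                )
            else:
                raise ConfigError(f"no default decorrelation for condition {cond!r} at {age} dap")
    return out


@dataclass
class StudyConfig:
    """Everything needed to simulate one exposure study.

    ``rho_map`` maps (condition, age_dap) to the central per-frame field
    correlation. ``between_plant_plateau_sd`` adds seeded plant-to-plant
    variability on the plateau-BA scale (biological replicate variance);
    the phantom is exempt.
    """

    conditions: tuple[str, ...] = ("control", "100Hz", "1kHz", "10kHz")
    ages: tuple[int, ...] = (30,)
    n_plants: int = 6
    acquisitions_per_cycle: int = 5
    cycles: int = 3
    fps: float = _DEFAULT_FPS
    duration_s: float = _DEFAULT_DURATION_S
    shape: tuple[int, int] = (64, 64)
    geometry: OpticalGeometry = field(default_factory=OpticalGeometry)
    camera: CameraModel = field(default_factory=CameraModel)
    rho_map: Mapping[tuple[str, int], float] | None = None
    between_plant_plateau_sd: float = 0.05
    target_mean_gray: float | None = None

    def resolved_rho_map(self) -> Mapping[tuple[str, int], float]:
        if self.rho_map is not None:
            missing = [
                (c, a)
                for c in self.conditions
                for a in self.ages
                if (c, a) not in self.rho_map
            ]
            if missing:
                raise ConfigError(f"rho_map missing conditions: {missing}")
            return self.rho_map
        return default_rho_map(self.conditions, self.ages, self.fps, self.duration_s)


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from a master seed and a key tuple (SHA-256 based,
    independent of Python hash randomization), in [0, 2**31)."""
    key = "|".join([str(int(master_seed))] + [repr(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _plant_rho(
    cfg: StudyConfig, rho_map: Mapping[tuple[str, int], float],
    condition: str, age: int, plant: int, master_seed: int,
) -> float:
    rho = rho_map[(condition, age)]
    if cfg.between_plant_plateau_sd <= 0 or rho == 1.0:
        return rho
    plateau = plateau_for_rho(rho, cfg.fps, cfg.duration_s)
    rng = default_rng(derive_seed(master_seed, "plant-plateau", condition, age, plant))
    jittered = float(
        np.clip(rng.normal(plateau, cfg.between_plant_plateau_sd), 0.02, 0.98)
    )
    return rho_for_plateau(jittered, cfg.fps, cfg.duration_s)


def simulate_study(config: StudyConfig, master_seed: int):
    """Generate every acquisition of the exposure protocol.

    Yields one :class:`SpeckleSequence` per (age, condition, plant,
    cycle, acquisition); with the default 5 acquisitions x 3 cycles this
    is 15 sequences per plant per condition. Per-sequence seeds are a
    stable hash of the identity tuple, so two runs with the same master
    seed produce identical datasets.
    """
    rho_map = config.resolved_rho_map()
    for age in config.ages:
        for condition in config.conditions:
            for plant in range(1, config.n_plants + 1):
                rho = _plant_rho(config, rho_map, condition, age, plant, master_seed)
                label = condition if condition != "phantom" else "phantom"
                for cycle in range(1, config.cycles + 1):
                    for acq in range(1, config.acquisitions_per_cycle + 1):
                        seed = derive_seed(master_seed, age, condition, plant, cycle, acq)
                        yield simulate_sequence(
                            config.geometry,
                            config.camera,
                            DecorrelationModel(rho=rho, label=label),
                            fps=config.fps,
                            duration_s=config.duration_s,
                            seed=seed,
                            shape=config.shape,
                            target_mean_gray=config.target_mean_gray,
                            plant_id=plant,
                            age_dap=age,
                            cycle=cycle,
                            acquisition=acq,
                        )


# ---------------------------------------------------------------------------
# Fast noise-free path for calibration studies


def simulate_ba_matrix(
    n_sequences: int,
    rho: float | np.ndarray,
    n_frames: int,
    shape: tuple[int, int] = (48, 48),
    speckle_size_px: float = 3.0,
    seed: int | SeedSequence | None = 0,
    max_batch_pixels: int = 40_000_000,
) -> np.ndarray:
    """Noise-free BA curves for many independent sequences at once.

    Batched counterpart of :func:`simulate_sequence` +
    :func:`biospeckle.ba.ba_curve`, skipping the camera: BA is computed
    on the raw intensity ``|E|**2``. Used for statistical calibration
    studies (type-I error, power) where thousands of replicates are
    needed. ``rho`` may be per-sequence (length ``n_sequences``).

    Returns an ``(n_sequences, n_frames - 1)`` array of BA values.
    """
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (n_sequences,))
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    per_frame_px = shape[0] * shape[1]
    chunk = max(1, min(n_sequences, max_batch_pixels // per_frame_px))
    out = np.empty((n_sequences, n_frames - 1))
    chunk_seeds = ss.spawn(int(np.ceil(n_sequences / chunk)))
    for ci, start in enumerate(range(0, n_sequences, chunk)):
        stop = min(start + chunk, n_sequences)
        b = stop - start
        rho_b = rho_arr[start:stop][:, None, None]
        children = chunk_seeds[ci].spawn(n_frames)
        fld = generate_base_field((b,) + tuple(shape), speckle_size_px, children[0])
        ref = np.abs(fld) ** 2
        ref_c = ref - ref.mean(axis=(-2, -1), keepdims=True)
        ref_ss = np.sqrt((ref_c**2).sum(axis=(-2, -1)))
        for k in range(1, n_frames):
            fld = evolve_field(fld, rho_b, children[k], speckle_size_px)
            cur = np.abs(fld) ** 2
            cur_c = cur - cur.mean(axis=(-2, -1), keepdims=True)
            r = (ref_c * cur_c).sum(axis=(-2, -1)) / (
                ref_ss * np.sqrt((cur_c**2).sum(axis=(-2, -1)))
            )
            out[start:stop, k - 1] = 1.0 - r
    return out
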