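"""Statistical calibration of the protocol-layer significance test.

Monte-Carlo studies of :func:`biospeckle.protocol.compare_to_control`
under the speckle generator's own study conditions: the type-I error
when both plant groups share the same decorrelation kinetics, and the
power at the condition-vs-control effect sizes the generator is
calibrated to.

The per-plant statistic is the early-window (<= 5 s) mean BA of one
noise-free acquisition. To keep thousands of replicates tractable the
acquisition is simulated at a 3 fps temporal subsampling of the 15 fps
protocol — exact for the autoregressive field model, since skipping
four of five frames is the same process with per-frame correlation
rho**5 — on a 48x48 grid with 3-pixel speckles.
"""

from __future__ import annotations

import numpy as np
from numpy.random import default_rng

from .protocol import compare_to_control
from .synthetic import derive_seed, rho_for_plateau, simulate_ba_matrix

__all__ = ["early_mean_ba_samples", "type_i_error", "power"]

_PROTOCOL_FPS = 15.0


def early_mean_ba_samples(
    n_rep: int,
    n_plants: int,
    plateau: float,
    seed: int,
    plateau_sd: float = 0.05,
    window_s: float = 5.0,
    sub_fps: float = 3.0,
    shape: tuple[int, int] = (48, 48),
    speckle_size_px: float = 3.0,
) -> np.ndarray:
    """(n_rep, n_plants) early-window mean BA values.

    Each plant draws its own plateau from N(plateau, plateau_sd)
    (clipped to [0.02, 0.98]) — the generator's between-plant
    variability — and contributes one noise-free acquisition.
    """
    step = _PROTOCOL_FPS / sub_fps
    if abs(step - round(step)) > 1e-9:
        raise ValueError("sub_fps must divide the 15 fps protocol rate")
    total = n_rep * n_plants
    rng = default_rng(derive_seed(seed, "plateaus"))
    plateaus = np.clip(rng.normal(plateau, plateau_sd, size=total), 0.02, 0.98)
    rho_sub = np.array([rho_for_plateau(p) ** step for p in plateaus])
    n_frames = int(round(window_s * sub_fps)) + 1
    mat = simulate_ba_matrix(
        total, rho_sub, n_frames, shape=shape,
        speckle_size_px=speckle_size_px, seed=derive_seed(seed, "fields"),
    )
    return mat.mean(axis=1).reshape(n_rep, n_plants)


def type_i_error(
    n_rep: int = 2000,
    n_plants: int = 6,
    plateau: float = 0.9,
    seed: int = 0,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Null rejection rate of the condition-vs-control t-test when both
    groups come from the same decorrelation kinetics."""
    a = early_mean_ba_samples(n_rep, n_plants, plateau, derive_seed(seed, "null-a"), **kwargs)
    b = early_mean_ba_samples(n_rep, n_plants, plateau, derive_seed(seed, "null-b"), **kwargs)
    rejections = sum(
        compare_to_control(a[i], b[i], alpha=alpha).significant for i in range(n_rep)
    )
    return rejections / n_rep


def power(
    n_rep: int = 200,
    n_plants: int = 6,
    plateau_condition: float = 0.5,
    plateau_control: float = 0.9,
    seed: int = 0,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Detection rate at a given plateau-BA effect size (default: the
    rock-music-versus-control contrast, 0.5 vs 0.9)."""
    a = early_mean_ba_samples(
        n_rep, n_plants, plateau_condition, derive_seed(seed, "effect-a"), **kwargs
    )
    b = early_mean_ba_samples(
        n_rep, n_plants, plateau_control, derive_seed(seed, "effect-b"), **kwargs
    )
    detections = sum(
        compare_to_control(a[i], b[i], alpha=alpha).significant for i in range(n_rep)
    )
    return detections / n_rep
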