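"""Stereological sphere cross-section simulation.

Random 2D sections of a sphere under-represent its true size: a section at
offset X from the equator of a sphere of radius R is a circle of radius
Y = sqrt(R^2 - X^2), hence area pi (R^2 - X^2). Drawing the offset X
uniformly on [0, R] (equivalent by symmetry to sampling over the full
axis), the expected section area is (2/3) pi R^2. This module builds the
diameter -> mean-section-area calibration curve by Monte-Carlo sampling
(or its closed form) and inverts it to estimate the true particle diameter
from an observed mean cross-sectional area, the procedure used to correct
synaptosome sizes measured on single EM sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

__all__ = [
    "CalibrationCurve",
    "sample_cross_sections",
    "analytic_mean_area",
    "build_calibration",
    "estimate_diameter",
]

DEFAULT_N_SECTIONS = 30
DEFAULT_N_REPEATS = 4


@dataclass
class CalibrationCurve:
    """Diameter grid and mean cross-sectional area per diameter.

    Units: diameters in whatever unit the grid is given (declared by the
    caller), areas in that unit squared. Mean areas are strictly
    increasing after isotonic adjustment, guaranteeing invertibility.
    """

    diameters: np.ndarray
    mean_areas: np.ndarray
    sd_areas: np.ndarray
    n_sections: int
    n_repeats: int
    seed: int | None
    analytic: bool = False
    n_monotonized: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diameter": self.diameters,
                "mean_area": self.mean_areas,
                "sd_area": self.sd_areas,
            }
        )


def sample_cross_sections(radius: float, n: int, seed: int | None = None) -> np.ndarray:
    """Areas of ``n`` random plane sections of a sphere of radius ``radius``.

    The plane offset X is drawn uniformly from [0, R]; the section is the
    circle solving X^2 + Y^2 = R^2, so its area is pi (R^2 - X^2).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, radius, n)
    return np.pi * (radius**2 - x**2)


def analytic_mean_area(diameter: np.ndarray | float) -> np.ndarray | float:
    """Expected section area: E[pi (R^2 - X^2)] = (2/3) pi (d/2)^2."""
    d = np.asarray(diameter, dtype=float)
    out = (2.0 / 3.0) * np.pi * (d / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def build_calibration(
    diameters: np.ndarray,
    n_sections: int = DEFAULT_N_SECTIONS,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int | None = 0,
    analytic: bool = False,
) -> CalibrationCurve:
    """Calibration curve of mean section area over a diameter grid.

    Per diameter, ``n_repeats`` independent means of ``n_sections`` section
    areas are averaged (the sampled, experiment-faithful mode); with
    ``analytic=True`` the closed-form expectation (2/3) pi (d/2)^2 is used
    instead. Sampling noise can invert adjacent grid points; the curve is
    monotonized by isotonic regression before use (adjustment count
    recorded) so inversion is well defined.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size < 2:
        raise ValueError("diameter grid needs at least 2 points")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("diameter grid must be positive and strictly increasing")
    if analytic:
        means = analytic_mean_area(d)
        sds = np.zeros_like(means)
        n_mono = 0
    else:
        rng = np.random.default_rng(seed)
        means = np.empty_like(d)
        sds = np.empty_like(d)
        for i, di in enumerate(d):
            reps = [
                sample_cross_sections(
                    di / 2.0, n_sections, rng.integers(0, 2**31 - 1)
                ).mean()
                for _ in range(n_repeats)
            ]
            means[i] = np.mean(reps)
            sds[i] = np.std(reps, ddof=1) if n_repeats > 1 else 0.0
        iso = isotonic_regression(means).x
        n_mono = int((iso != means).sum())
        means = iso
    return CalibrationCurve(
        diameters=d, mean_areas=means, sd_areas=sds,
        n_sections=n_sections, n_repeats=n_repeats, seed=seed,
        analytic=analytic, n_monotonized=n_mono,
    )


def estimate_diameter(observed_mean_area: float, curve: CalibrationCurve) -> float:
    """Invert the calibration curve by monotone linear interpolation.

    The observed mean cross-sectional area must lie within the calibrated
    range; no extrapolation is performed.
    """
    areas, diams = curve.mean_areas, curve.diameters
    if observed_mean_area < areas[0] or observed_mean_area > areas[-1]:
        raise ValueError(
            f"observed area {observed_mean_area:g} outside calibrated range "
            f"[{areas[0]:g}, {areas[-1]:g}]"
        )
    return float(np.interp(observed_mean_area, areas, diams))
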