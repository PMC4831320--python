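"""Photoreceptor adaptation: the Naka-Rushton-style cone polarization model.

A cone adapted to intensity I_a responds to intensity I_b with a
normalized polarization

    V = I_b / (I_b + I_a),

where I_a is also the half-saturating intensity, so V(I_a) = 1/2 is the
baseline.  Re-expressed in temporal Weber contrast w = 100 (I_b - I_a)/I_a
the depolarization to dark contrasts (|V - 1/2| for w < 0) is accelerating
while the hyperpolarization to bright contrasts is compressive — the same
dark/bright asymmetry the spatial normalization model produces, and
exactly invariant to the adaptation level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASELINE_POLARIZATION = 0.5  # V at I_b = I_a


def cone_polarization(intensity, adapt_intensity: float):
    """Normalized polarization V = I_b / (I_b + I_a); V(I_a) = 1/2, V(0) = 0."""
    if adapt_intensity <= 0:
        raise ValueError("adaptation intensity I_a must be positive")
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("stimulus intensity I_b must be non-negative")
    v = intensity / (intensity + adapt_intensity)
    return float(v) if v.ndim == 0 else v


def temporal_weber(intensity, adapt_intensity: float):
    """Temporal Weber contrast, percent: 100 (I_b - I_a) / I_a."""
    if adapt_intensity <= 0:
        raise ValueError("adaptation intensity I_a must be positive")
    w = 100.0 * (np.asarray(intensity, dtype=float) - adapt_intensity) / adapt_intensity
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class ConeAdaptationCurve:
    """V as a function of absolute stimulus intensity for one adaptation level."""

    adapt_intensity: float
    intensities: np.ndarray
    polarizations: np.ndarray
    baseline: float = BASELINE_POLARIZATION


def cone_response_curve(adapt_intensity: float, intensities) -> ConeAdaptationCurve:
    """Sample the intensity-response curve of a cone adapted to ``adapt_intensity``."""
    intensities = np.asarray(intensities, dtype=float)
    return ConeAdaptationCurve(
        adapt_intensity=adapt_intensity,
        intensities=intensities,
        polarizations=np.atleast_1d(cone_polarization(intensities, adapt_intensity)),
    )


@dataclass(frozen=True)
class PolarizationContrastCurves:
    """Paired response-magnitude branches versus temporal Weber contrast magnitude.

    ``depolarization`` is |V - 1/2| for intensity decrements (the dark
    branch feeding OFF bipolar cells); ``hyperpolarization`` the same for
    increments (the bright branch feeding ON bipolars).
    """

    weber_magnitudes: np.ndarray  # percent, 0..100
    depolarization: np.ndarray
    hyperpolarization: np.ndarray
    adapt_intensity: float


def polarization_vs_contrast(
    adapt_intensity: float = 100.0,
    weber_grid=None,
    step_pct: float = 1.0,
) -> PolarizationContrastCurves:
    """Dark and bright response branches in the temporal-contrast domain.

    The curves are computed with intensities expressed in units of I_a
    (V = (1 + w~)/(2 + w~)), so the output is exactly independent of the
    adaptation level — the contrast-constancy-within-polarity property.
    ``weber_grid``, if given, must be symmetric about 0; its non-negative
    half indexes the output.
    """
    if adapt_intensity <= 0:
        raise ValueError("adaptation intensity I_a must be positive")
    if weber_grid is None:
        n_steps = 100.0 / step_pct
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("step_pct must divide 100")
        mags = np.linspace(0.0, 100.0, int(round(n_steps)) + 1)
    else:
        weber_grid = np.asarray(weber_grid, dtype=float)
        if not np.allclose(np.sort(weber_grid), np.sort(-weber_grid)):
            raise ValueError("weber_grid must be symmetric about 0")
        if np.any(np.abs(weber_grid) > 100):
            raise ValueError("temporal Weber contrast cannot exceed 100% in magnitude")
        mags = np.unique(np.abs(weber_grid))
    frac = mags / 100.0
    dark = BASELINE_POLARIZATION - cone_polarization(1.0 - frac, 1.0)
    bright = cone_polarization(1.0 + frac, 1.0) - BASELINE_POLARIZATION
    return PolarizationContrastCurves(
        weber_magnitudes=mags,
        depolarization=np.atleast_1d(dark),
        hyperpolarization=np.atleast_1d(bright),
        adapt_intensity=adapt_intensity,
    )
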