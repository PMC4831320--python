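"""The contrast encoder: a divisively normalized difference of Gaussians.

A model unit is defined by three Gaussian standard deviations: a center
(sigma_c, the fixed reference scale), an antagonistic surround (sigma_s),
and a normalization pool (sigma_n).  Its scalar response to a luminance
image f is

    r = [f * (g_c - g_s)] / [f * g_n]

where * is convolution evaluated at the single center point (image and
filter share one lattice), g_sigma is a unit-mass 2D Gaussian, and the
denominator is the local average luminance.  Half-wave rectification of r
yields the ON (r > 0) and OFF (r < 0) pathway responses; no further
nonlinearity is applied, so any ON/OFF asymmetry is created by the
normalization alone.

For uniform disks and squares on uniform backgrounds the response has a
closed form in the continuum limit (Gaussian mass inside a disk or square),
which serves as an independent oracle for the rasterized pipeline.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .stimuli import (
    STIMULUS_HALF_EXTENT,
    GridSpec,
    LuminanceImage,
    squared_radius,
)

#: Canonical surround/center scale factors (6 values).
SURROUND_RATIOS = (1.25, 1.5, 2.0, 3.0, 4.0, 6.0)
#: Canonical normalization/center scale factors (7 values).
NORMALIZATION_RATIOS = (1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0)


class DegenerateStimulusError(ValueError):
    """The normalization denominator vanished (e.g. an all-black image)."""


@dataclass(frozen=True)
class ModelUnit:
    """One encoder, defined by its three Gaussian scales.

    ``sigma_c`` is the reference scale (1.0 in internal units); ``sigma_s``
    and ``sigma_n`` are usually given as multiples of it.
    """

    sigma_s: float
    sigma_n: float
    sigma_c: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.sigma_s <= self.sigma_c:
            raise ValueError("surround must be broader than the center (sigma_s > sigma_c)")
        if self.sigma_n < self.sigma_c:
            raise ValueError("normalization pool must be at least center-sized (sigma_n >= sigma_c)")

    @property
    def surround_ratio(self) -> float:
        return self.sigma_s / self.sigma_c

    @property
    def norm_ratio(self) -> float:
        return self.sigma_n / self.sigma_c

    @property
    def max_sigma(self) -> float:
        return max(self.sigma_c, self.sigma_s, self.sigma_n)


def canonical_units(
    surround_ratios: Sequence[float] = SURROUND_RATIOS,
    norm_ratios: Sequence[float] = NORMALIZATION_RATIOS,
) -> list[ModelUnit]:
    """The canonical encoder family: the full surround x normalization grid.

    With the default 6 x 7 grid of scale factors this yields 42 units.
    """
    return [
        ModelUnit(sigma_s=ss, sigma_n=sn)
        for ss in surround_ratios
        for sn in norm_ratios
    ]


def default_grid(
    unit: ModelUnit, pixels_per_sigma_c: int = 16, padding: float = 5.0
) -> GridSpec:
    """A lattice wide enough that every kernel's truncated mass is < 1e-5."""
    half_width = max(2.0, padding * unit.max_sigma / unit.sigma_c)
    return GridSpec(pixels_per_sigma_c=pixels_per_sigma_c, half_width=half_width)


def shared_grid(
    units: Iterable[ModelUnit], pixels_per_sigma_c: int = 16, padding: float = 5.0
) -> GridSpec:
    """One lattice accommodating every unit in a family (used by sweeps)."""
    units = list(units)
    if not units:
        return GridSpec(pixels_per_sigma_c=pixels_per_sigma_c, half_width=2.0)
    half_width = max(2.0, padding * max(u.max_sigma / u.sigma_c for u in units))
    return GridSpec(pixels_per_sigma_c=pixels_per_sigma_c, half_width=half_width)


@dataclass(frozen=True)
class FilterKernel:
    """A sampled filter on the shared lattice; single Gaussians sum to exactly 1."""

    weights: np.ndarray
    kind: str  # center | surround | normalization
    sigma: float


def make_gaussian_kernel(sigma: float, grid: GridSpec, kind: str = "center") -> FilterKernel:
    """Sample a 2D Gaussian at pixel centers and renormalize to unit sum.

    The analytic prefactor 1/(2 pi sigma^2) is absorbed by the discrete
    renormalization, which makes uniform images map to exactly zero
    antagonistic output on the lattice.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = np.exp(-squared_radius(grid) / (2.0 * sigma * sigma))
    w /= w.sum()
    return FilterKernel(weights=w, kind=kind, sigma=sigma)


@functools.lru_cache(maxsize=4)
def _unit_kernels(unit: ModelUnit, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gc = make_gaussian_kernel(unit.sigma_c, grid, "center").weights
    gs = make_gaussian_kernel(unit.sigma_s, grid, "surround").weights
    gn = make_gaussian_kernel(unit.sigma_n, grid, "normalization").weights
    return gc, gs, gn


def antagonistic_response(image: LuminanceImage, unit: ModelUnit) -> float:
    """The linear center-surround (DoG) stage alone, without normalization.

    Odd in contrast and homogeneous of degree 1 in overall luminance:
    doubling the illumination doubles this response.
    """
    gc, gs, _ = _unit_kernels(unit, image.grid)
    return float(np.sum(image.values * (gc - gs)))


def model_response(
    image: LuminanceImage, unit: ModelUnit, *, eps: float = 1e-12
) -> float:
    """Full normalized response r of one unit to one image (signed scalar).

    Raises
    ------
    DegenerateStimulusError
        If the normalization output is <= ``eps * background`` (an
        essentially black image leaves the divisive stage undefined).
    """
    gc, gs, gn = _unit_kernels(unit, image.grid)
    numerator = float(np.sum(image.values * (gc - gs)))
    denominator = float(np.sum(image.values * gn))
    if denominator <= eps * max(image.background, 1.0):
        raise DegenerateStimulusError(
            "normalization denominator is not positive; the local luminance "
            "average vanished (all-black stimulus?)"
        )
    return numerator / denominator


@dataclass(frozen=True)
class RectifiedResponse:
    """Half-wave rectified ON/OFF pair: on = max(r, 0), off = max(-r, 0)."""

    on: float
    off: float


def rectify(r: float) -> RectifiedResponse:
    """Split a signed response into the ON and OFF pathway outputs."""
    return RectifiedResponse(on=max(r, 0.0), off=max(-r, 0.0))


# --- closed-form continuum oracle -----------------------------------------

def gaussian_disk_mass(sigma: float, radius: float = STIMULUS_HALF_EXTENT) -> float:
    """Mass of a unit 2D Gaussian inside a centered disk: 1 - exp(-R^2/2 sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 - float(np.exp(-(radius**2) / (2.0 * sigma**2)))


def gaussian_square_mass(sigma: float, half_width: float = STIMULUS_HALF_EXTENT) -> float:
    """Mass of a unit 2D Gaussian inside a centered square: erf(h/sigma sqrt2)^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(special.erf(half_width / (sigma * np.sqrt(2.0))) ** 2)


def analytic_disk_response(unit: ModelUnit, contrast_pct: float) -> float:
    """Continuum-limit response to a disk of Weber contrast c on any background.

    With c~ = c/100, A = M_c - M_s and L = M_n (Gaussian masses inside the
    disk), r = c~ A / (1 + c~ L); the background cancels.
    """
    if abs(contrast_pct) > 100:
        raise ValueError("Weber contrast must lie in [-100, 100]%")
    ct = contrast_pct / 100.0
    a = gaussian_disk_mass(unit.sigma_c) - gaussian_disk_mass(unit.sigma_s)
    lum = gaussian_disk_mass(unit.sigma_n)
    denominator = 1.0 + ct * lum
    if denominator <= 0:
        raise DegenerateStimulusError("normalization denominator vanished in the oracle")
    return ct * a / denominator


def analytic_square_response(unit: ModelUnit, background: float, target: float) -> float:
    """Continuum-limit response to a square of luminance ``target`` on ``background``."""
    if background <= 0:
        raise ValueError("background luminance must be positive")
    if target < 0:
        raise ValueError("square luminance must be non-negative")
    a = gaussian_square_mass(unit.sigma_c) - gaussian_square_mass(unit.sigma_s)
    lum = gaussian_square_mass(unit.sigma_n)
    denominator = background + (target - background) * lum
    if denominator <= 0:
        raise DegenerateStimulusError("normalization denominator vanished in the oracle")
    return (target - background) * a / denominator


# --- exact fast path for uniform-figure stimuli ---------------------------

def footprint_masses(unit: ModelUnit, grid: GridSpec, mask: np.ndarray) -> tuple[float, float]:
    """Discrete DoG and normalization kernel mass inside a stimulus footprint.

    An image ``b + delta * mask`` is affine in ``delta``, so its response is
    exactly ``delta * a_dog / (b + delta * a_norm)`` with the two masses
    returned here — identical (to float rounding) to rendering the image and
    calling :func:`model_response`, at a fraction of the cost.  This is the
    rasterized pipeline, not the continuum oracle: the masses are lattice
    sums, not closed forms.
    """
    gc, gs, gn = _unit_kernels(unit, grid)
    a_dog = float(np.sum((gc - gs) * mask))
    a_norm = float(np.sum(gn * mask))
    return a_dog, a_norm


def response_from_masses(
    a_dog: float,
    a_norm: float,
    background: float,
    delta: float | np.ndarray,
    *,
    eps: float = 1e-12,
):
    """Signed response(s) for figure-minus-background luminance ``delta``."""
    delta = np.asarray(delta, dtype=float)
    denominator = background + delta * a_norm
    bad = denominator <= eps * max(background, 1.0)
    if np.any(bad):
        if delta.ndim == 0:
            raise DegenerateStimulusError("normalization denominator vanished")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(bad, np.nan, delta * a_dog / denominator)
        return r
    r = delta * a_dog / denominator
    return float(r) if r.ndim == 0 else r
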