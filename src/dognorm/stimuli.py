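"""Rasterized luminance stimuli: uniform disks and squares on uniform backgrounds.

Contrast response functions are probed with disks whose diameter is four
times the standard deviation of the model's center Gaussian (sigma_c), at
Weber contrasts between -100% and +100%.  Luminance response functions are
probed with squares of the same width whose absolute luminance is varied on
one of three fixed backgrounds (2, 61 or 120 cd/m^2).  Everything is
rendered on a square pixel lattice with a center pixel at the origin, in
units of sigma_c.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

#: Disk radius and square half-width, in units of sigma_c.  The stimulus
#: diameter / side length is 4 sigma_c.
STIMULUS_HALF_EXTENT = 2.0

#: Fixed square-stimulus backgrounds (cd/m^2) used for luminance responses.
LUMINANCE_BACKGROUNDS = (2.0, 61.0, 120.0)


@dataclass(frozen=True)
class GridSpec:
    """Square pixel lattice, in sigma_c units, with a pixel at the origin.

    Parameters
    ----------
    pixels_per_sigma_c
        Lattice resolution.  The rasterization is exact in the limit of
        infinite resolution; 16 px per sigma_c keeps discretization error
        below the two-significant-figure level of the derived statistics.
    half_width
        Half the image side, in sigma_c units.  The lattice spans
        ``[-half_width, +half_width]`` on both axes and has an odd side
        length so that a pixel center sits exactly at (0, 0).
    """

    pixels_per_sigma_c: int = 16
    half_width: float = 10.0

    def __post_init__(self) -> None:
        if int(self.pixels_per_sigma_c) != self.pixels_per_sigma_c or self.pixels_per_sigma_c < 1:
            raise ValueError("pixels_per_sigma_c must be a positive integer")
        if self.half_width < 2.0:
            raise ValueError(
                "half_width must be >= 2 sigma_c so the image contains the "
                "full stimulus (diameter 4 sigma_c)"
            )

    @property
    def n_half(self) -> int:
        """Number of pixels on each side of the center pixel, per axis."""
        return int(round(self.half_width * self.pixels_per_sigma_c))

    @property
    def side(self) -> int:
        """Side length of the (odd-sized) square lattice, in pixels."""
        return 2 * self.n_half + 1

    def coords(self) -> np.ndarray:
        """Pixel-center coordinates along one axis, in sigma_c units."""
        return np.arange(-self.n_half, self.n_half + 1) / self.pixels_per_sigma_c


@functools.lru_cache(maxsize=8)
def _squared_radius(grid: GridSpec) -> np.ndarray:
    x = grid.coords()
    return x[:, None] ** 2 + x[None, :] ** 2


def squared_radius(grid: GridSpec) -> np.ndarray:
    """x^2 + y^2 at every pixel center (cached per grid)."""
    return _squared_radius(grid)


def _membership_1d(x: np.ndarray, half_extent: float) -> np.ndarray:
    # Pixel-center test with a symmetric tie rule: a pixel whose center
    # lies exactly on the boundary is half inside.  The stimulus half-extent
    # (2 sigma_c) lands exactly on pixel centers at power-of-two
    # resolutions, where a strict test would bias the footprint by half a
    # pixel per side.
    w = np.where(np.abs(x) < half_extent, 1.0, 0.0)
    w[np.isclose(np.abs(x), half_extent, rtol=1e-12, atol=1e-9)] = 0.5
    return w


def disk_mask(grid: GridSpec, radius: float = STIMULUS_HALF_EXTENT) -> np.ndarray:
    """Footprint weights of a centered disk: 1 inside, 0 outside, 1/2 on ties."""
    r2 = squared_radius(grid)
    m = np.where(r2 < radius**2, 1.0, 0.0)
    m[np.isclose(r2, radius**2, rtol=1e-12, atol=1e-9)] = 0.5
    return m


def square_mask(grid: GridSpec, half_width: float = STIMULUS_HALF_EXTENT) -> np.ndarray:
    """Footprint weights of a centered axis-aligned square (corner ties 1/4)."""
    w = _membership_1d(grid.coords(), half_width)
    return np.outer(w, w)


@dataclass(frozen=True)
class LuminanceImage:
    """A non-negative luminance image f(x, y) on a shared lattice.

    Luminance units are opaque (arbitrary units or cd/m^2); the encoder is
    invariant to overall scale, so no unit conversion exists anywhere.
    """

    values: np.ndarray
    grid: GridSpec
    background: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.side, self.grid.side):
            raise ValueError(
                f"values shape {v.shape} does not match grid {self.grid.side}x{self.grid.side}"
            )
        if np.any(v < 0):
            raise ValueError("luminance values must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class DiskStimulus:
    """A uniform disk of Weber contrast ``contrast_pct`` on background ``background``.

    The disk luminance is ``background * (1 + contrast_pct / 100)``; Weber
    contrast is 100 (d - b) / b.
    """

    background: float
    contrast_pct: float
    radius: float = STIMULUS_HALF_EXTENT

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background luminance must be positive")
        if self.contrast_pct < -100:
            raise ValueError(
                f"Weber contrast {self.contrast_pct}% would give a negative disk "
                "luminance; the darkest physical disk is -100% (luminance 0)"
            )
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")

    @property
    def target_luminance(self) -> float:
        return self.background * (1.0 + self.contrast_pct / 100.0)


@dataclass(frozen=True)
class SquareStimulus:
    """A uniform square of absolute luminance ``target_luminance`` on ``background``."""

    background: float
    target_luminance: float
    half_width: float = STIMULUS_HALF_EXTENT

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background luminance must be positive")
        if self.target_luminance < 0:
            raise ValueError("square luminance must be non-negative")
        if self.half_width <= 0:
            raise ValueError("square half-width must be positive")


StimulusSpec = Union[DiskStimulus, SquareStimulus]


def render_disk(spec: DiskStimulus, grid: GridSpec) -> LuminanceImage:
    """Rasterize a disk stimulus; pixels outside the footprint equal background."""
    if grid.half_width < spec.radius:
        raise ValueError("grid does not contain the disk")
    delta = spec.target_luminance - spec.background
    values = spec.background + delta * disk_mask(grid, spec.radius)
    return LuminanceImage(values=values, grid=grid, background=spec.background)


def render_square(spec: SquareStimulus, grid: GridSpec) -> LuminanceImage:
    """Rasterize a square stimulus; pixels outside the footprint equal background."""
    if grid.half_width < spec.half_width:
        raise ValueError("grid does not contain the square")
    delta = spec.target_luminance - spec.background
    values = spec.background + delta * square_mask(grid, spec.half_width)
    return LuminanceImage(values=values, grid=grid, background=spec.background)


def render(spec: StimulusSpec, grid: GridSpec) -> LuminanceImage:
    if isinstance(spec, DiskStimulus):
        return render_disk(spec, grid)
    if isinstance(spec, SquareStimulus):
        return render_square(spec, grid)
    raise TypeError(f"unknown stimulus spec {type(spec).__name__}")


# --- flat key/value (de)serialization -------------------------------------

def stimulus_to_dict(spec: StimulusSpec) -> dict:
    """Flat key/value form: shape + background + contrast_pct | target_luminance."""
    if isinstance(spec, DiskStimulus):
        return {
            "shape": "disk",
            "background": float(spec.background),
            "contrast_pct": float(spec.contrast_pct),
        }
    if isinstance(spec, SquareStimulus):
        return {
            "shape": "square",
            "background": float(spec.background),
            "target_luminance": float(spec.target_luminance),
        }
    raise TypeError(f"unknown stimulus spec {type(spec).__name__}")


def stimulus_from_dict(d: dict) -> StimulusSpec:
    shape = d.get("shape")
    if shape == "disk":
        return DiskStimulus(background=float(d["background"]),
                            contrast_pct=float(d["contrast_pct"]))
    if shape == "square":
        return SquareStimulus(background=float(d["background"]),
                              target_luminance=float(d["target_luminance"]))
    raise ValueError(f"stimulus config must have shape 'disk' or 'square', got {shape!r}")


def dump_stimulus(spec: StimulusSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(stimulus_to_dict(spec), sort_keys=True))


def load_stimulus(path: str | Path) -> StimulusSpec:
    return stimulus_from_dict(yaml.safe_load(Path(path).read_text()))


def write_pgm(image: LuminanceImage, path: str | Path) -> None:
    """Export an image as plain 16-bit PGM (P2) for visual inspection.

    Luminance is stored directly as integer counts (maxval 65535), so
    images with luminances up to 65535 round-trip without clipping.
    """
    v = np.rint(image.values).astype(int)
    if v.max() > 65535:
        raise ValueError("luminance exceeds the 16-bit PGM range")
    lines = [f"P2", f"{image.grid.side} {image.grid.side}", "65535"]
    lines += [" ".join(str(int(x)) for x in row) for row in v]
    Path(path).write_text("\n".join(lines) + "\n")
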