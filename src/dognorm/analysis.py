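"""Contrast and luminance response sweeps and their derived statistics.

For each encoder the package measures:

* a contrast response function (CRF) from disks at Weber contrasts
  0..100% (ON from increments, OFF from decrements);
* a nonlinearity index — log10 of the CRF slope at a high contrast
  (default 50%) over the slope at a low contrast (default 5%), slopes by
  central finite differences; positive means accelerating;
* the OFF/ON response ratio at 100% contrast;
* luminance response functions from squares of absolute luminance on the
  fixed backgrounds 2, 61 and 120, summarized by Rmax (response at the
  largest luminance contrast presented) and L50 (luminance of
  half-maximal response, expressed as a proportion of the sampled range);
* population aggregates of the background-dependence ratios of L50 and
  Rmax across the canonical 42-unit family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .encoder import (
    ModelUnit,
    canonical_units,
    footprint_masses,
    response_from_masses,
    shared_grid,
)
from .stimuli import GridSpec, LUMINANCE_BACKGROUNDS, disk_mask, square_mask

logger = logging.getLogger(__name__)

#: Extreme target luminance per polarity: ON curves run up to the brightest
#: target (120), OFF curves down to the darkest (2).
LUMINANCE_EXTREMES = {"on": 120.0, "off": 2.0}

POPULATION_COLUMNS = [
    "sigma_s_ratio", "sigma_n_ratio",
    "nli_on", "nli_off", "offon_ratio_100",
    "l50_on_dark", "l50_on_gray", "l50_off_light", "l50_off_gray",
    "rmax_on_dark", "rmax_on_gray", "rmax_off_light", "rmax_off_gray",
    "note",
]


@dataclass(frozen=True)
class ContrastResponseFunction:
    """Sampled rectified ON/OFF responses versus Weber contrast magnitude."""

    contrasts: np.ndarray  # percent, 0..100, equal steps
    on: np.ndarray         # rectified response at +c
    off: np.ndarray        # rectified response at -c
    unit: ModelUnit
    background: float

    @property
    def degenerate(self) -> np.ndarray:
        """Per-point flags for contrasts where the denominator vanished."""
        return np.isnan(self.on) | np.isnan(self.off)


def compute_crf(
    unit: ModelUnit,
    background: float = 50.0,
    step_pct: float = 1.0,
    grid: GridSpec | None = None,
    pixels_per_sigma_c: int = 16,
) -> ContrastResponseFunction:
    """Sweep disk stimuli over Weber contrast and rectify the responses.

    ON is sampled at +c, OFF at -c, for c = 0, step, ..., 100.  Degenerate
    points (vanishing denominator) are flagged as NaN rather than dropped.
    """
    n_steps = 100.0 / step_pct
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step_pct must divide 100")
    if grid is None:
        grid = shared_grid([unit], pixels_per_sigma_c)
    contrasts = np.linspace(0.0, 100.0, int(round(n_steps)) + 1)
    a_dog, a_norm = footprint_masses(unit, grid, disk_mask(grid))
    ct = contrasts / 100.0
    r_on = response_from_masses(a_dog, a_norm, background, background * ct)
    r_off = response_from_masses(a_dog, a_norm, background, -background * ct)
    return ContrastResponseFunction(
        contrasts=contrasts,
        on=np.maximum(np.atleast_1d(r_on), 0.0),
        off=np.maximum(-np.atleast_1d(r_off), 0.0),
        unit=unit,
        background=background,
    )


@dataclass(frozen=True)
class NonlinearityIndex:
    """log10(slope at c_high / slope at c_low); NaN when a slope is not positive."""

    value: float
    c_low: float
    c_high: float
    polarity: str


def _central_slope(contrasts: np.ndarray, y: np.ndarray, c: float) -> float:
    idx = np.flatnonzero(np.isclose(contrasts, c))
    if idx.size != 1:
        raise ValueError(f"contrast {c}% is not a sampled point of this curve")
    i = int(idx[0])
    if i == 0 or i == len(contrasts) - 1:
        raise ValueError(f"contrast {c}% must be interior to the sampled range")
    return float((y[i + 1] - y[i - 1]) / (contrasts[i + 1] - contrasts[i - 1]))


def nonlinearity_index(
    crf: ContrastResponseFunction,
    polarity: str = "off",
    c_low: float = 5.0,
    c_high: float = 50.0,
) -> NonlinearityIndex:
    """Log slope ratio of one polarity's CRF between a high and a low contrast."""
    if polarity not in ("on", "off"):
        raise ValueError("polarity must be 'on' or 'off'")
    y = crf.on if polarity == "on" else crf.off
    s_low = _central_slope(crf.contrasts, y, c_low)
    s_high = _central_slope(crf.contrasts, y, c_high)
    if not (s_low > 0 and s_high > 0) or not np.isfinite(s_low * s_high):
        value = float("nan")
    else:
        value = float(np.log10(s_high / s_low))
    return NonlinearityIndex(value=value, c_low=c_low, c_high=c_high, polarity=polarity)


def offon_ratio_at_max(
    unit: ModelUnit,
    background: float = 50.0,
    grid: GridSpec | None = None,
    pixels_per_sigma_c: int = 16,
) -> float:
    """OFF response at -100% over ON response at +100% Weber contrast.

    Greater than 1 for every unit: a full decrement lowers the
    normalization pool while a full increment raises it.  Depends only on
    the normalization scale sigma_n, not on the surround.
    """
    if grid is None:
        grid = shared_grid([unit], pixels_per_sigma_c)
    a_dog, a_norm = footprint_masses(unit, grid, disk_mask(grid))
    on = response_from_masses(a_dog, a_norm, background, background)
    off = -response_from_masses(a_dog, a_norm, background, -background)
    if not on > 0:
        raise ValueError("ON response at +100% contrast is not positive")
    return off / on


@dataclass(frozen=True)
class LuminanceResponseFunction:
    """Rectified responses of one polarity to squares of absolute luminance."""

    background: float
    targets: np.ndarray
    responses: np.ndarray
    polarity: str  # "on" | "off"
    unit: ModelUnit


def compute_luminance_response(
    unit: ModelUnit,
    background: float,
    polarity: str,
    targets: Sequence[float] | None = None,
    n_targets: int = 60,
    grid: GridSpec | None = None,
    pixels_per_sigma_c: int = 16,
) -> LuminanceResponseFunction:
    """Sweep square stimuli from the background to the extreme luminance.

    By default 60 evenly spaced targets span [background, extreme], where
    the extreme is 120 (brightest) for ON and 2 (darkest) for OFF,
    matching the fixed background set (2, 61, 120).
    """
    if polarity not in LUMINANCE_EXTREMES:
        raise ValueError("polarity must be 'on' or 'off'")
    extreme = LUMINANCE_EXTREMES[polarity]
    if targets is None:
        if background == extreme:
            raise ValueError(
                f"background {background} equals the {polarity.upper()} extreme; "
                "no luminance contrast range to sweep"
            )
        targets = np.linspace(background, extreme, n_targets)
    targets = np.asarray(targets, dtype=float)
    if grid is None:
        grid = shared_grid([unit], pixels_per_sigma_c)
    a_dog, a_norm = footprint_masses(unit, grid, square_mask(grid))
    r = response_from_masses(a_dog, a_norm, background, targets - background)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    responses = np.maximum(r, 0.0) if polarity == "on" else np.maximum(-r, 0.0)
    return LuminanceResponseFunction(
        background=background, targets=targets, responses=responses,
        polarity=polarity, unit=unit,
    )


@dataclass(frozen=True)
class SaturationSummary:
    """Rmax (response at the largest luminance contrast) and the L50 proportion."""

    l50: float
    rmax: float


def saturation_summary(lrf: LuminanceResponseFunction) -> SaturationSummary:
    """Half-saturation point of a monotone luminance response curve.

    Rmax is the response at the largest presented luminance contrast (the
    last target).  L50 is the target luminance at which the response first
    reaches Rmax/2, located by linear interpolation between samples and
    expressed as a proportion of the sampled luminance-contrast range.
    """
    if lrf.targets.size < 10:
        raise ValueError("need at least 10 sampled luminances to summarize saturation")
    x = np.abs(lrf.targets - lrf.background)
    order = np.argsort(x)
    x, resp = x[order], lrf.responses[order]
    if np.any(np.diff(resp) < -1e-12 * max(resp.max(), 1.0)):
        raise ValueError("luminance response curve is not monotone in |target - background|")
    rmax = float(resp[-1])
    if rmax <= 0:
        raise ValueError("Rmax is not positive; cannot define L50")
    l50 = float(np.interp(rmax / 2.0, resp, x) / x[-1])
    return SaturationSummary(l50=l50, rmax=rmax)


def population_sweep(
    units: Sequence[ModelUnit] | None = None,
    pixels_per_sigma_c: int = 16,
    step_pct: float = 1.0,
    n_targets: int = 60,
    crf_background: float = 50.0,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """All derived statistics for a family of units, one row per unit.

    Every unit is evaluated on one shared lattice so that statistics that
    depend only on sigma_n are exactly constant across sigma_s.  Per-unit
    failures are recorded in the ``note`` column and never abort the sweep.
    """
    if units is None:
        units = canonical_units()
    if grid is None:
        grid = shared_grid(units, pixels_per_sigma_c)
    rows = []
    for unit in units:
        row: dict = {
            "sigma_s_ratio": unit.surround_ratio,
            "sigma_n_ratio": unit.norm_ratio,
            "note": "",
        }
        try:
            crf = compute_crf(unit, background=crf_background, step_pct=step_pct, grid=grid)
            row["nli_on"] = nonlinearity_index(crf, "on").value
            row["nli_off"] = nonlinearity_index(crf, "off").value
            row["offon_ratio_100"] = offon_ratio_at_max(unit, crf_background, grid=grid)
            for key, (bkg, pol) in {
                "on_dark": (2.0, "on"), "on_gray": (61.0, "on"),
                "off_light": (120.0, "off"), "off_gray": (61.0, "off"),
            }.items():
                lrf = compute_luminance_response(
                    unit, bkg, pol, n_targets=n_targets, grid=grid
                )
                summ = saturation_summary(lrf)
                row[f"l50_{key}"] = summ.l50
                row[f"rmax_{key}"] = summ.rmax
            if np.isclose(unit.norm_ratio, 1.0):
                # The -100% contrast point leaves only the far Gaussian tail
                # in the normalization pool; included, but resolution-sensitive.
                row["note"] = "near-degenerate dark endpoint (sigma_n = sigma_c)"
        except Exception as exc:  # record, keep sweeping
            logger.warning("unit %s failed: %s", unit, exc)
            row["note"] = f"failed: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows, columns=POPULATION_COLUMNS)
    return table


_AGGREGATORS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),
}


def summarize_background_ratios(
    table: pd.DataFrame, aggregator: str = "mean"
) -> dict[str, float]:
    """Population background-dependence ratios of L50 and Rmax.

    Per unit, forms OFF light/gray and ON dark/gray ratios of L50 and of
    Rmax, then aggregates across units (arithmetic mean by default).
    Units with missing entries are excluded with a logged count.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregator]
    pairs = {
        "off_l50_light_gray": ("l50_off_light", "l50_off_gray"),
        "on_l50_dark_gray": ("l50_on_dark", "l50_on_gray"),
        "off_rmax_light_gray": ("rmax_off_light", "rmax_off_gray"),
        "on_rmax_dark_gray": ("rmax_on_dark", "rmax_on_gray"),
    }
    out: dict[str, float] = {}
    for name, (num, den) in pairs.items():
        ratio = table[num] / table[den]
        ok = ratio.dropna()
        if len(ok) < len(ratio):
            logger.warning(
                "%s: excluded %d unit(s) with missing entries", name, len(ratio) - len(ok)
            )
        out[name] = agg(ok.to_numpy()) if len(ok) else float("nan")
    return out
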