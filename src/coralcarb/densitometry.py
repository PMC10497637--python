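"""Wedge-calibrated optical densitometry of coral slab radiographs.

The stepped aragonite wedge (known density, 2.83 g cm^-3, and per-step
thickness) imaged next to each slab maps gray level to areal density
(g cm^-2).  The calibration is a monotone piecewise-linear interpolant through
the wedge reference points with the air background appended as a zero-areal-
density anchor: assumption-free and exact on any monotone detector response.
Slab gray divided through the slab thickness gives bulk skeletal density
(g cm^-3); annual density and extension series follow from the positions of
density minima along the growth-axis track, one value per pair of bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .radiograph import Radiograph

__all__ = [
    "CalibrationCurve",
    "DensityProfile",
    "AnnualBandSeries",
    "CalibrationError",
    "NoCompleteBandError",
    "build_calibration",
    "gray_to_density",
    "extract_density_profile",
    "detect_annual_bands",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the wedge reference points cannot form a monotone curve."""


class NoCompleteBandError(ValueError):
    """Raised when fewer than two density minima bound no complete band."""


@dataclass
class CalibrationCurve:
    """Monotone gray -> areal density (g cm^-2) interpolant from the wedge.

    ``grays``/``areals`` are the reference points sorted by gray, including the
    air anchor at areal density zero.  Conversion beyond the reference range is
    clamped (with a logged warning at call time).
    """

    grays: np.ndarray
    areals: np.ndarray
    wedge_density: float
    slab_thickness_cm: float

    def areal_density(self, gray) -> np.ndarray:
        g = np.asarray(gray, dtype=float)
        if (g < self.grays[0]).any() or (g > self.grays[-1]).any():
            log.warning("gray values outside the calibrated wedge range; clamping")
        return np.interp(g, self.grays, self.areals)


def build_calibration(rad: Radiograph) -> CalibrationCurve:
    """Build the calibration curve from the annotated wedge and background.

    Reference points are (mean step gray, wedge_density x step thickness) for
    every wedge step, plus (mean background gray, 0).  Mean grays must be
    strictly monotone in areal density; direction (polarity) is arbitrary.
    """
    if len(rad.wedge_steps) < 3:
        raise CalibrationError("need >=3 annotated wedge steps")
    if max(s.thickness_cm for s in rad.wedge_steps) < rad.slab_thickness_cm:
        raise CalibrationError("wedge must include a step at or above the slab thickness")
    if not rad.background_mask.any():
        raise CalibrationError("missing background (air) region")
    img = rad.image.astype(float)
    steps = sorted(rad.wedge_steps, key=lambda s: s.thickness_cm)
    grays = [img[rad.background_mask].mean()] + [img[s.mask].mean() for s in steps]
    areals = [0.0] + [rad.wedge_density * s.thickness_cm for s in steps]
    grays = np.asarray(grays)
    areals = np.asarray(areals)
    diffs = np.diff(grays)
    if (diffs > 0).all():
        pass
    elif (diffs < 0).all():
        grays, areals = grays[::-1], areals[::-1]
    else:
        thick = [0.0] + [s.thickness_cm for s in steps]
        bad = [f"{thick[i]:.2f}->{thick[i + 1]:.2f} cm" for i in np.flatnonzero(diffs <= 0)]
        raise CalibrationError(
            "wedge mean grays are not strictly monotone in areal density at steps: "
            + ", ".join(bad)
        )
    return CalibrationCurve(
        grays=grays,
        areals=areals,
        wedge_density=rad.wedge_density,
        slab_thickness_cm=rad.slab_thickness_cm,
    )


def gray_to_density(gray, curve: CalibrationCurve) -> np.ndarray:
    """Convert gray level(s) to bulk skeletal density (g cm^-3)."""
    return curve.areal_density(gray) / curve.slab_thickness_cm


@dataclass
class DensityProfile:
    """Calibrated density along the growth axis (positions in cm from 0)."""

    positions_cm: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions_cm) != len(self.density):
            raise ValueError("positions and densities must align")
        if len(self.positions_cm) and (
            self.positions_cm[0] != 0.0 or (np.diff(self.positions_cm) <= 0).any()
        ):
            raise ValueError("positions must strictly increase from 0")


@dataclass
class AnnualBandSeries:
    """Per band-year density and extension, indexed from the colony surface.

    ``table`` columns: band_index (1 = most recent), density_g_cm3,
    extension_cm, start_cm, end_cm.  Incomplete terminal intervals (before the
    first and after the last minimum) are discarded as partial years.
    """

    table: pd.DataFrame

    @property
    def densities(self) -> np.ndarray:
        return self.table["density_g_cm3"].to_numpy()

    @property
    def extensions(self) -> np.ndarray:
        return self.table["extension_cm"].to_numpy()

    @property
    def boundaries_cm(self) -> np.ndarray:
        t = self.table
        return np.concatenate((t["start_cm"].to_numpy(), [t["end_cm"].iloc[-1]]))


def extract_density_profile(
    rad: Radiograph, curve: CalibrationCurve, track_width: int = 5
) -> DensityProfile:
    """Calibrated density profile along the annotated growth-axis track.

    At each track point the gray is averaged over ``track_width`` pixels
    perpendicular to the local track direction before calibration; positions
    are the cumulative path length times the pixel size, starting at 0.
    """
    if rad.track is None:
        raise ValueError("radiograph has no growth-axis track annotation")
    if track_width < 1:
        raise ValueError("track_width must be >= 1")
    tr = np.asarray(rad.track, dtype=float)
    n = len(tr)
    # local tangent by central differences; perpendicular unit vector
    tang = np.gradient(tr, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    perp = np.column_stack((-tang[:, 1] / norm, tang[:, 0] / norm))
    offsets = np.arange(track_width) - (track_width - 1) / 2.0
    img = rad.image.astype(float)
    grays = np.empty(n)
    for i in range(n):
        pts = np.rint(tr[i] + offsets[:, None] * perp[i]).astype(int)
        pts[:, 0] = np.clip(pts[:, 0], 0, img.shape[0] - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, img.shape[1] - 1)
        if not rad.slab_mask[pts[:, 0], pts[:, 1]].all():
            raise ValueError(
                f"track (with width {track_width}) exits the slab mask at index {i}"
            )
        grays[i] = img[pts[:, 0], pts[:, 1]].mean()
    seglen = np.hypot(*np.diff(tr, axis=0).T)
    positions = np.concatenate(([0.0], np.cumsum(seglen))) * rad.pixel_size_cm
    return DensityProfile(positions_cm=positions, density=np.asarray(gray_to_density(grays, curve)))


def _moving_average(y: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return y.copy()
    pad = win // 2
    yp = np.pad(y, pad, mode="edge")
    sm = np.convolve(yp, np.ones(win) / win, mode="valid")
    return sm[: len(y)]


def _refine_minimum(sm: np.ndarray, m: int, half: int) -> int:
    """Re-localize a minimum by a least-squares parabola over +-half samples,
    rounded back to the nearest sample (keeps band arithmetic index-exact)."""
    lo, hi = max(0, m - half), min(len(sm), m + half + 1)
    t = np.arange(lo, hi) - m
    if len(t) < 3:
        return m
    a, b, _ = np.polyfit(t, sm[lo:hi], 2)
    if a <= 0:
        return m
    shift = -b / (2.0 * a)
    shift = float(np.clip(shift, -half, half))
    return int(np.clip(round(m + shift), 0, len(sm) - 1))


def detect_annual_bands(
    profile: DensityProfile,
    smooth_window_cm: float = 0.05,
    min_prominence: float = 0.05,
    min_separation_cm: float = 0.1,
) -> AnnualBandSeries:
    """Detect annual bands from density minima along the profile.

    The profile is smoothed by a centered moving average of ``smooth_window_cm``
    before minima detection; minima must have prominence of at least
    ``min_prominence`` times the smoothed profile's range, and minima closer
    than ``min_separation_cm`` (far below any annual extension) are treated as
    one noise-split boundary, keeping the most prominent.  Each minimum is then
    re-localized by a parabola fitted around it, which averages detector noise
    over the neighborhood instead of trusting a single-sample argmin.
    Extension is the distance between consecutive minima; annual density is the
    unweighted mean of the RAW calibrated densities over the half-open interval
    [m_i, m_{i+1}).  Band 1 is the interval nearest the colony surface
    (position 0).
    """
    pos = profile.positions_cm
    dens = profile.density
    if len(pos) < 3:
        raise NoCompleteBandError("profile too short")
    dx = np.median(np.diff(pos))
    if smooth_window_cm >= pos[-1] - pos[0]:
        raise ValueError("smooth_window_cm must be smaller than the profile length")
    win = max(1, int(round(smooth_window_cm / dx)))
    if win % 2 == 0:
        win += 1
    sm = _moving_average(dens, win)
    rng = sm.max() - sm.min()
    prominence = min_prominence * rng if rng > 0 else None
    if prominence is None:
        raise NoCompleteBandError("flat profile: no density minima")
    minima, _ = find_peaks(
        -sm, prominence=prominence, distance=max(1, int(round(min_separation_cm / dx)))
    )
    minima = np.unique([_refine_minimum(sm, int(m), max(3, win)) for m in minima])
    if len(minima) < 2:
        raise NoCompleteBandError(
            f"no complete band: found {len(minima)} density minima (need >= 2)"
        )
    rows = []
    for idx, (a, b) in enumerate(zip(minima[:-1], minima[1:]), start=1):
        rows.append(
            (
                idx,
                float(dens[a:b].mean()),
                float(pos[b] - pos[a]),
                float(pos[a]),
                float(pos[b]),
            )
        )
    table = pd.DataFrame(
        rows, columns=["band_index", "density_g_cm3", "extension_cm", "start_cm", "end_cm"]
    )
    return AnnualBandSeries(table=table)
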