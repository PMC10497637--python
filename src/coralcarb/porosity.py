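"""Gray-band porosity segmentation and particle counting.

Porous space in a slab radiograph is the set of slab pixels whose gray lies
strictly between two thresholds derived from the same image: S_max, the mean
gray of the aragonite-standard reference region (solid CaCO3 at slab
thickness), and S_min, the mean gray of the air background pooled with the
thinnest 0.05 cm of the wedge (the intermediate air/CaCO3 transition).  Pixels
at the reference gray are solid aragonite by construction; pixels at the air
level are background; everything between reads as partial-volume pore space.
Connected pore components are counted (8-connectivity by default) and the mean
slab gray, calibrated through the wedge curve, complements the porosity
percentage with a bulk slab density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .densitometry import CalibrationCurve, gray_to_density
from .radiograph import Radiograph

__all__ = [
    "PorosityThresholds",
    "PoreSegmentation",
    "PorosityResult",
    "compute_thresholds",
    "segment_pores",
    "porosity_summary",
]

#: wedge thickness (cm) up to which pixels count toward the air-side threshold
THIN_WEDGE_MAX_CM = 0.05


@dataclass(frozen=True)
class PorosityThresholds:
    """Polarity-normalized gray thresholds: s_min (air side) < s_max (solid)."""

    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if not self.s_min < self.s_max:
            raise ValueError("no dynamic range: S_min must be below S_max")


@dataclass
class PoreSegmentation:
    """Binary pore mask over the slab with labeled connected components."""

    mask: np.ndarray
    labels: np.ndarray
    areas_px: np.ndarray  # per-component pixel areas

    @property
    def count(self) -> int:
        return len(self.areas_px)


@dataclass(frozen=True)
class PorosityResult:
    """Slab-level porosity summary."""

    pore_count: int
    porosity_pct: float
    mean_slab_gray: float
    mean_density_g_cm3: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.porosity_pct <= 100.0:
            raise ValueError("porosity percent out of [0, 100]")
        if self.pore_count < 0:
            raise ValueError("pore count must be >= 0")


def compute_thresholds(
    rad: Radiograph, reference: str = "step_at_slab"
) -> PorosityThresholds:
    """Per-radiograph S_min/S_max from the annotated wedge and background.

    ``reference`` selects the aragonite-standard region for S_max:
    ``"step_at_slab"`` (default) uses the wedge step whose thickness is closest
    to the slab thickness, so a solid-aragonite slab pixel images at S_max;
    ``"whole_wedge"`` pools every wedge step.  Thresholds are normalized so
    s_min < s_max regardless of gray polarity.
    """
    if not rad.wedge_steps:
        raise ValueError("radiograph has no wedge annotation")
    if not rad.background_mask.any():
        raise ValueError("radiograph has no background annotation")
    img = rad.image.astype(float)
    if reference == "step_at_slab":
        step = min(rad.wedge_steps, key=lambda s: abs(s.thickness_cm - rad.slab_thickness_cm))
        ref_mask = step.mask
    elif reference == "whole_wedge":
        ref_mask = rad.wedge_mask()
    else:
        raise ValueError(f"unknown reference choice: {reference!r}")
    s_solid = img[ref_mask].mean()

    air_vals = [img[rad.background_mask]]
    for s in rad.wedge_steps:
        if s.thickness_cm <= THIN_WEDGE_MAX_CM:
            air_vals.append(img[s.mask])
    s_air = np.concatenate(air_vals).mean()
    lo, hi = sorted((s_air, s_solid))
    if lo == hi:
        raise ValueError("no dynamic range: air and reference grays coincide")
    return PorosityThresholds(s_min=lo, s_max=hi)


def segment_pores(
    rad: Radiograph,
    thresholds: PorosityThresholds,
    connectivity: int = 8,
    min_area: int = 1,
) -> PoreSegmentation:
    """Segment pore space: slab pixels strictly between S_min and S_max.

    Components are labeled at 4- or 8-connectivity; components smaller than
    ``min_area`` pixels are dropped from both the mask and the count."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    img = rad.image.astype(float)
    mask = rad.slab_mask & (img > thresholds.s_min) & (img < thresholds.s_max)
    lab = label(mask, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(lab.ravel())[1:]  # component areas, label order
    keep = np.flatnonzero(areas >= min_area) + 1
    if len(keep) < lab.max():
        mask = np.isin(lab, keep)
        lab = label(mask, connectivity=1 if connectivity == 4 else 2)
        areas = np.bincount(lab.ravel())[1:]
    return PoreSegmentation(mask=mask, labels=lab, areas_px=np.sort(areas)[::-1])


def porosity_summary(
    seg: PoreSegmentation, rad: Radiograph, curve: CalibrationCurve
) -> PorosityResult:
    """Porosity percent, pore count and calibrated mean slab density."""
    n_slab = int(rad.slab_mask.sum())
    if n_slab == 0:
        raise ValueError("empty slab mask")
    mean_gray = float(rad.image[rad.slab_mask].astype(float).mean())
    return PorosityResult(
        pore_count=seg.count,
        porosity_pct=100.0 * float(seg.mask.sum()) / n_slab,
        mean_slab_gray=mean_gray,
        mean_density_g_cm3=float(gray_to_density(mean_gray, curve)),
    )
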