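"""Annotated slab radiograph container and image/sidecar I/O.

A :class:`Radiograph` couples a gray-scale slab X-ray image with the region
annotations that the downstream densitometry and porosity stages require: the
stepped aragonite calibration wedge (with per-step thickness), the slab mask,
the air background, and the growth-axis track running from the colony surface
toward the base of the slab.

Images travel as plain 8/16-bit gray TIFF or PNG; annotations travel in a
JSON sidecar so that a radiograph round-trips losslessly through disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["WedgeStep", "Radiograph", "write_radiograph", "read_radiograph"]


@dataclass(frozen=True)
class WedgeStep:
    """One step of the aragonite calibration wedge.

    Parameters
    ----------
    thickness_cm
        Physical thickness of the step (cm). Areal density of the step is
        ``wedge_density * thickness_cm`` (g cm^-2).
    mask
        Boolean pixel mask of the step region.
    """

    thickness_cm: float
    mask: np.ndarray


@dataclass
class Radiograph:
    """Calibrated-gray slab radiograph with region annotations.

    Attributes
    ----------
    image
        2D integer gray image (uint8 or uint16).
    pixel_size_cm
        Physical size of one pixel (cm); 0.01 cm = 100 µm by default upstream.
    bit_depth
        8 or 16.
    slab_thickness_cm
        Thickness of the coral slab (cm), uniform per radiograph.
    wedge_density
        Density of the calibration standard (g cm^-3), aragonite = 2.83.
    wedge_steps
        Steps of the wedge, thin to thick.
    slab_mask, background_mask
        Boolean region masks; mutually disjoint.
    track
        (N, 2) integer array of (row, col) pixel coordinates ordered from the
        colony surface/apex toward the base; lies inside ``slab_mask``.
    gray_polarity
        +1 when denser material images brighter (default), -1 when inverted.
    """

    image: np.ndarray
    pixel_size_cm: float
    bit_depth: int
    slab_thickness_cm: float
    wedge_density: float
    wedge_steps: list[WedgeStep]
    slab_mask: np.ndarray
    background_mask: np.ndarray
    track: np.ndarray | None = None
    gray_polarity: int = 1
    sample_id: str = "sample"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_cm <= 0:
            raise ValueError("pixel_size_cm must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        masks = [self.slab_mask, self.background_mask] + [s.mask for s in self.wedge_steps]
        overlap = np.zeros(self.image.shape, dtype=int)
        for m in masks:
            if m.shape != self.image.shape:
                raise ValueError("region mask shape does not match image")
            overlap += m.astype(int)
        if (overlap > 1).any():
            raise ValueError("region annotations overlap")
        if self.track is not None:
            tr = np.asarray(self.track)
            if tr.ndim != 2 or tr.shape[1] != 2:
                raise ValueError("track must be an (N, 2) array of (row, col)")
            if not self.slab_mask[tr[:, 0], tr[:, 1]].all():
                raise ValueError("growth-axis track must lie inside the slab mask")

    @property
    def gray_max(self) -> int:
        return (1 << self.bit_depth) - 1

    def wedge_mask(self) -> np.ndarray:
        """Union of all wedge-step masks."""
        out = np.zeros(self.image.shape, dtype=bool)
        for s in self.wedge_steps:
            out |= s.mask
        return out


def _mask_to_rle(mask: np.ndarray) -> dict:
    """Flat run-length encoding of a boolean mask (compact JSON-able form)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    # run starts where value changes
    change = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    runs = [[int(s), int(l)] for s, l, v in zip(starts, lengths, flat[starts]) if v]
    return {"shape": list(mask.shape), "runs": runs}


def _rle_to_mask(obj: dict) -> np.ndarray:
    shape = tuple(obj["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, l in obj["runs"]:
        flat[s : s + l] = True
    return flat.reshape(shape)


def write_radiograph(rad: Radiograph, image_path: str | Path) -> Path:
    """Write image (TIFF/PNG by extension) plus a JSON annotation sidecar.

    Returns the sidecar path (``<image>.regions.json``).
    """
    image_path = Path(image_path)
    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(image_path, rad.image)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(image_path, rad.image)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    sidecar = image_path.with_suffix(image_path.suffix + ".regions.json")
    doc = {
        "pixel_size_cm": rad.pixel_size_cm,
        "bit_depth": rad.bit_depth,
        "slab_thickness_cm": rad.slab_thickness_cm,
        "wedge_density": rad.wedge_density,
        "gray_polarity": rad.gray_polarity,
        "sample_id": rad.sample_id,
        "metadata": rad.metadata,
        "slab_mask": _mask_to_rle(rad.slab_mask),
        "background_mask": _mask_to_rle(rad.background_mask),
        "wedge_steps": [
            {"thickness_cm": s.thickness_cm, "mask": _mask_to_rle(s.mask)} for s in rad.wedge_steps
        ],
        "track": None if rad.track is None else np.asarray(rad.track).tolist(),
    }
    sidecar.write_text(json.dumps(doc))
    return sidecar


def read_radiograph(image_path: str | Path) -> Radiograph:
    """Read an image and its ``.regions.json`` sidecar back into a Radiograph."""
    image_path = Path(image_path)
    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        image = tifffile.imread(image_path)
    elif suffix == ".png":
        import imageio.v3 as iio

        image = np.asarray(iio.imread(image_path))
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    sidecar = image_path.with_suffix(image_path.suffix + ".regions.json")
    doc = json.loads(sidecar.read_text())
    return Radiograph(
        image=image,
        pixel_size_cm=doc["pixel_size_cm"],
        bit_depth=doc["bit_depth"],
        slab_thickness_cm=doc["slab_thickness_cm"],
        wedge_density=doc["wedge_density"],
        wedge_steps=[
            WedgeStep(thickness_cm=s["thickness_cm"], mask=_rle_to_mask(s["mask"]))
            for s in doc["wedge_steps"]
        ],
        slab_mask=_rle_to_mask(doc["slab_mask"]),
        background_mask=_rle_to_mask(doc["background_mask"]),
        track=None if doc["track"] is None else np.asarray(doc["track"], dtype=int),
        gray_polarity=doc["gray_polarity"],
        sample_id=doc["sample_id"],
        metadata=doc["metadata"],
    )
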