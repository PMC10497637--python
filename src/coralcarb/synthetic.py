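"""Synthetic fixtures with exact ground truth.

Three generators mirror the three data streams of the analysis:

* :func:`generate_radiograph` — phantom slab X-radiographs with a stepped
  aragonite calibration wedge (2.83 g cm^-3), banded density along a growth
  axis, planted pore structures, and Gaussian detector noise.  The forward
  imaging model is gray linear in areal density (g cm^-2); the calibration
  stage never assumes this — it interpolates through the wedge — so linearity
  stays an internal generator choice that makes analytic inversion testable.
* :func:`generate_band_dataset` — annual-band density observations with a
  known colony-status effect, depth slope, and colony-level random intercepts,
  the observational structure entering the mixed models.
* :func:`generate_survey` — belt-transect colony tables over a set of reefs
  together with the TRUE carbonate budget obtained by direct summation, the
  oracle for the budget module.

Pores are rendered as partial-depth voids that remove a configurable fraction
of the local areal density (default half).  A hole through the full slab would
image exactly at the air gray level and is background, not porous space; the
porosity thresholds deliberately capture the intermediate air/CaCO3 grays, so
the phantom plants pores there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .budget import BudgetResult
from .radiograph import Radiograph, WedgeStep

__all__ = [
    "RadiographPhantomParams",
    "GroundTruth",
    "SpeciesSimSpec",
    "SurveySimParams",
    "sinusoidal_bands",
    "generate_radiograph",
    "generate_band_dataset",
    "generate_survey",
    "default_species",
    "default_reef_areas",
]

#: default wedge: 10 steps spanning the 0.9 cm slab thickness with margin
DEFAULT_WEDGE_STEPS = tuple(round(0.09 + 0.11 * i, 2) for i in range(10))


def sinusoidal_bands(
    mean: float = 1.4, amplitude: float = 0.4, period_cm: float = 0.8, phase: float = 0.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Banded density profile ``mean + amplitude*sin(2*pi*x/period + phase)``."""

    def profile(x: np.ndarray) -> np.ndarray:
        return mean + amplitude * np.sin(2.0 * np.pi * np.asarray(x) / period_cm + phase)

    return profile


@dataclass
class RadiographPhantomParams:
    """Ground-truth parameters of a phantom slab radiograph.

    Lengths in cm, densities in g cm^-3.  ``band_profile`` maps position along
    the growth axis (cm from the colony surface) to skeletal density and must
    stay within ``(0, wedge_density]``.
    """

    pixel_size_cm: float = 0.01  # 100 µm
    slab_thickness_cm: float = 0.9  # 9-mm slabs
    wedge_density: float = 2.83  # aragonite standard
    wedge_steps_cm: Sequence[float] = DEFAULT_WEDGE_STEPS
    band_profile: Callable[[np.ndarray], np.ndarray] = field(default_factory=sinusoidal_bands)
    track_length_cm: float = 4.0
    slab_height_cm: float = 0.6
    pore_fraction: float = 0.0
    pore_radius_range_cm: tuple[float, float] = (0.02, 0.05)
    pore_depth_fraction: float = 0.5
    noise_sd: float = 0.0
    bit_depth: int = 8
    gray_polarity: int = 1

    def __post_init__(self) -> None:
        steps = np.asarray(self.wedge_steps_cm, dtype=float)
        if len(steps) < 3 or not (np.diff(steps) > 0).all():
            raise ValueError("wedge_steps_cm must be >=3 strictly increasing thicknesses")
        if steps.max() < self.slab_thickness_cm:
            raise ValueError(
                "wedge thinner than slab: cannot calibrate the full density range "
                f"(max step {steps.max()} cm < slab {self.slab_thickness_cm} cm)"
            )
        if not 0.0 <= self.pore_fraction < 1.0:
            raise ValueError("pore_fraction must be in [0, 1)")
        if not 0.0 < self.pore_depth_fraction <= 1.0:
            raise ValueError("pore_depth_fraction must be in (0, 1]")
        if self.gray_polarity not in (1, -1):
            raise ValueError("gray_polarity must be +1 (denser=brighter) or -1")


@dataclass
class GroundTruth:
    """Exact truth accompanying a generated radiograph."""

    density_map: np.ndarray  # per-pixel true bulk density over the slab (g cm^-3)
    band_boundaries_cm: np.ndarray  # positions of density minima along the track
    band_densities: np.ndarray  # mean density between consecutive minima
    band_extensions_cm: np.ndarray  # distance between consecutive minima
    pore_mask: np.ndarray
    pore_count: int
    air_gray: float  # forward-model gray at zero areal density (pre-polarity)
    gray_per_areal: float  # forward-model slope (gray per g cm^-2)


def _forward_gray(
    areal: np.ndarray,
    g0: float,
    k: float,
    polarity: int,
    gray_max: int,
    noise_sd: float,
    rng: np.random.Generator,
    dtype,
) -> np.ndarray:
    base = g0 + k * areal
    if polarity < 0:
        base = gray_max - base
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return np.clip(np.rint(base), 0, gray_max).astype(dtype)


def _plant_pores(
    slab_rows: slice,
    slab_cols: slice,
    shape: tuple[int, int],
    pore_fraction: float,
    radius_range_px: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Rejection-sample non-overlapping discs until the area fraction is met."""
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = slab_rows.start, slab_cols.start
    h, w = slab_rows.stop - r0, slab_cols.stop - c0
    slab_area = h * w
    target = pore_fraction * slab_area
    if target <= 0:
        return mask, 0
    centers: list[tuple[float, float, float]] = []
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    count = 0
    attempts = 0
    mean_disc_area = np.pi * ((radius_range_px[0] + radius_range_px[1]) / 2.0) ** 2
    max_attempts = 2000 + int(200 * target / max(mean_disc_area, 1.0))
    while mask.sum() < target:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"pore_fraction {pore_fraction} unachievable without overlap "
                f"(placed {count} pores, reached {mask.sum() / slab_area:.3f})"
            )
        rad = rng.uniform(*radius_range_px)
        cy = rng.uniform(r0 + rad + 1, r0 + h - rad - 1)
        cx = rng.uniform(c0 + rad + 1, c0 + w - rad - 1)
        # non-overlap with >=1 px clearance keeps planted count a usable oracle
        if any((cy - y) ** 2 + (cx - x) ** 2 <= (rad + r + 2.0) ** 2 for y, x, r in centers):
            continue
        disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        if not disc.any():
            continue
        mask |= disc
        centers.append((cy, cx, rad))
        count += 1
    return mask, count


def generate_radiograph(
    params: RadiographPhantomParams, seed: int
) -> tuple[Radiograph, GroundTruth]:
    """Render a phantom radiograph and return it with its exact ground truth.

    Layout: the slab is a horizontal rectangle with the growth-axis track along
    its mid-line (surface at the left edge, position 0); the stepped wedge sits
    below it, thin to thick, left to right; everything else is air background.
    Gray = clip(quantize(g0 + k * areal_density + N(0, noise_sd))) with g0 and
    k fixed so the wedge spans >=80% of the dynamic range.
    """
    p = params
    rng = np.random.default_rng(seed)
    px = p.pixel_size_cm
    n_track = int(round(p.track_length_cm / px))
    slab_h = int(round(p.slab_height_cm / px))
    steps = np.asarray(p.wedge_steps_cm, dtype=float)
    margin = 10
    wedge_h = 36
    step_w = max(8, n_track // len(steps))
    width = margin + max(n_track, step_w * len(steps)) + margin
    height = margin + slab_h + margin + wedge_h + margin
    gray_max = (1 << p.bit_depth) - 1
    dtype = np.uint8 if p.bit_depth == 8 else np.uint16

    # forward model constants: air at 5% of range, wedge top at 95%
    areal_max = p.wedge_density * steps.max()
    g0 = 0.05 * gray_max
    k = 0.90 * gray_max / areal_max

    slab_rows = slice(margin, margin + slab_h)
    slab_cols = slice(margin, margin + n_track)
    slab_mask = np.zeros((height, width), dtype=bool)
    slab_mask[slab_rows, slab_cols] = True

    wedge_rows = slice(margin + slab_h + margin, margin + slab_h + margin + wedge_h)
    wedge_steps: list[WedgeStep] = []
    for i, t in enumerate(steps):
        m = np.zeros((height, width), dtype=bool)
        m[wedge_rows, margin + i * step_w : margin + (i + 1) * step_w] = True
        wedge_steps.append(WedgeStep(thickness_cm=float(t), mask=m))
    wedge_mask = np.zeros((height, width), dtype=bool)
    for s in wedge_steps:
        wedge_mask |= s.mask
    background_mask = ~(slab_mask | wedge_mask)

    # true bulk density along the growth axis, constant across the slab height
    x = np.arange(n_track) * px
    profile = np.asarray(p.band_profile(x), dtype=float)
    if (profile <= 0).any() or (profile > p.wedge_density + 1e-9).any():
        raise ValueError("band_profile values must lie in (0, wedge_density]")
    density_map = np.zeros((height, width), dtype=float)
    density_map[slab_rows, slab_cols] = profile[np.newaxis, :]

    pore_mask, pore_count = _plant_pores(
        slab_rows,
        slab_cols,
        (height, width),
        p.pore_fraction,
        (p.pore_radius_range_cm[0] / px, p.pore_radius_range_cm[1] / px),
        rng,
    )
    density_map[pore_mask] *= 1.0 - p.pore_depth_fraction

    areal = np.zeros((height, width), dtype=float)
    areal[slab_mask] = density_map[slab_mask] * p.slab_thickness_cm
    for s in wedge_steps:
        areal[s.mask] = p.wedge_density * s.thickness_cm

    image = _forward_gray(areal, g0, k, p.gray_polarity, gray_max, p.noise_sd, rng, dtype)

    track_row = (slab_rows.start + slab_rows.stop) // 2
    track = np.column_stack(
        (np.full(n_track, track_row, dtype=int), np.arange(slab_cols.start, slab_cols.stop))
    )

    minima, _ = find_peaks(-profile)
    boundaries = minima * px
    if len(minima) >= 2:
        band_densities = np.array(
            [profile[a:b].mean() for a, b in zip(minima[:-1], minima[1:])]
        )
        band_extensions = np.diff(boundaries)
    else:
        band_densities = np.empty(0)
        band_extensions = np.empty(0)

    rad = Radiograph(
        image=image,
        pixel_size_cm=px,
        bit_depth=p.bit_depth,
        slab_thickness_cm=p.slab_thickness_cm,
        wedge_density=p.wedge_density,
        wedge_steps=wedge_steps,
        slab_mask=slab_mask,
        background_mask=background_mask,
        track=track,
        gray_polarity=p.gray_polarity,
        metadata={"seed": seed, "kv": 55, "mAs": 6},  # acquisition settings are metadata only
    )
    truth = GroundTruth(
        density_map=density_map,
        band_boundaries_cm=boundaries,
        band_densities=band_densities,
        band_extensions_cm=band_extensions,
        pore_mask=pore_mask,
        pore_count=pore_count,
        air_gray=g0,
        gray_per_areal=k,
    )
    return rad, truth


# ---------------------------------------------------------------------------
# annual-band observation datasets for the mixed models
# ---------------------------------------------------------------------------


def generate_band_dataset(
    n_colonies: int,
    bands_per_colony: int,
    status_effect: float = -0.3,
    depth_slope: float = 0.0,
    sd_colony: float = 0.05,
    sd_resid: float = 0.10,
    seed: int = 0,
    mu: float = 1.4,
    status_effects: dict[str, float] | None = None,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Simulate annual-band density observations with known effects.

    density = mu + status_effect*I(dead) + depth_slope*band_age + b_colony + eps,
    b_colony ~ N(0, sd_colony^2), eps ~ N(0, sd_resid^2).  Each colony carries a
    single status and reef zone; colonies alternate across statuses and zones.
    ``status_effects`` generalises to >2 status levels (e.g. living / dead_1yr /
    dead_2yr) as a mapping of non-living level -> effect.

    The true parameters are recorded in ``df.attrs["true"]``.
    """
    if n_colonies < 2 or bands_per_colony < 2:
        raise ValueError("need n_colonies >= 2 and bands_per_colony >= 2")
    if sd_colony < 0 or sd_resid < 0:
        raise ValueError("variance components must be non-negative")
    if status_effects is None:
        status_effects = {"dead": status_effect}
    levels = ["living"] + list(status_effects)
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0.0, sd_colony, size=n_colonies)
    for c in range(n_colonies):
        status = levels[c % len(levels)]
        zone = "back" if (c // len(levels)) % 2 == 0 else "fore"
        eff = 0.0 if status == "living" else status_effects[status]
        ages = np.arange(1, bands_per_colony + 1)
        eps = rng.normal(0.0, sd_resid, size=bands_per_colony)
        ext = np.exp(rng.normal(np.log(0.8), 0.15, size=bands_per_colony))
        dens = mu + eff + depth_slope * ages + b[c] + eps
        for a, e, d in zip(ages, ext, dens):
            rows.append((f"colony_{c:03d}", species, status, zone, int(a), e, d))
    df = pd.DataFrame(
        rows,
        columns=["colony", "species", "status", "zone", "band_age", "extension_cm", "density"],
    )
    df.attrs["true"] = {
        "mu": mu,
        "status_effects": dict(status_effects),
        "depth_slope": depth_slope,
        "sd_colony": sd_colony,
        "sd_resid": sd_resid,
        "seed": seed,
    }
    return df


# ---------------------------------------------------------------------------
# benthic survey simulation with a direct-summation budget oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesSimSpec:
    """One species in the simulated community (synthetic default densities)."""

    name: str
    rel_abundance: float
    growth_form: str  # 'massive' | 'columnar' | 'branching'
    d_living: float  # g cm^-3
    d_dead: float  # g cm^-3, equal to d_living when no dissolution applies
    sctld_susceptible: bool


def default_species() -> list[SpeciesSimSpec]:
    """Synthetic stand-in community: four focal Caribbean reef-builders plus
    common non-susceptible space-holders.  Densities are plausible synthetic
    values, not measured ones; dissolution (d_dead < d_living) applies to
    D. cylindrus, P. strigosa and S. siderea only."""
    return [
        SpeciesSimSpec("Pseudodiploria strigosa", 0.20, "massive", 1.54, 1.23, True),
        SpeciesSimSpec("Siderastrea siderea", 0.20, "massive", 1.50, 1.35, True),
        SpeciesSimSpec("Dendrogyra cylindrus", 0.03, "columnar", 1.60, 1.12, True),
        SpeciesSimSpec("Orbicella faveolata", 0.12, "massive", 1.30, 1.30, True),
        SpeciesSimSpec("Porites astreoides", 0.25, "massive", 1.35, 1.35, False),
        SpeciesSimSpec("Acropora palmata", 0.10, "branching", 1.70, 1.70, False),
        SpeciesSimSpec("Agaricia tenuifolia", 0.10, "branching", 1.50, 1.50, False),
    ]


def default_reef_areas() -> dict[str, float]:
    """Synthetic reef-unit areas (m^2) for a six-reef system."""
    return {
        "Limones": 640_000.0,
        "Bonanza": 210_000.0,
        "La Catedral": 890_000.0,
        "Tanchacte": 520_000.0,
        "Jardines": 440_000.0,
        "La Pared": 460_000.0,
    }


@dataclass
class SurveySimParams:
    """Configuration of the synthetic belt-transect survey (10 x 1 m default)."""

    species: list[SpeciesSimSpec] = field(default_factory=default_species)
    reef_areas_m2: dict[str, float] = field(default_factory=default_reef_areas)
    transects_per_reef: int = 10
    transect_area_m2: float = 10.0
    colonies_per_transect_mean: float = 8.0
    diam_lognorm_median_m: float = 0.25
    diam_lognorm_sigma: float = 0.6
    height_aspect_median: float = 0.6
    height_aspect_sigma: float = 0.3
    affliction_prob: float = 0.5
    branching_correction: float = 0.11
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must not be empty")
        total = sum(s.rel_abundance for s in self.species)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"species relative abundances must sum to 1 (got {total})")
        if self.transect_area_m2 <= 0:
            raise ValueError("transect_area_m2 must be positive")
        if self.diam_lognorm_median_m <= 0 or self.height_aspect_median <= 0:
            raise ValueError("size-distribution medians must be positive")


def _true_volume_m3(form: str, dmax: float, dperp: float, h: float, corr: float) -> float:
    # inline scalar arithmetic: the oracle stays independent of carbonate_budget
    if form in ("massive", "columnar"):
        r = (dmax + dperp) / 4.0
        return (math.pi / 2.0) * h * r * r
    if form == "branching":
        return corr * dmax * dperp * h
    raise ValueError(f"unknown growth form: {form}")


def generate_survey(params: SurveySimParams) -> tuple[dict, BudgetResult]:
    """Simulate a multi-reef colony survey and its TRUE carbonate budget.

    Returns ``(tables, truth)`` where ``tables`` holds the colony survey table,
    the species density table and the reef-area table (all DataFrames ready to
    write as CSV), and ``truth`` is the budget computed by direct summation over
    the colony table — the oracle for the carbonate_budget module.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    probs = np.array([s.rel_abundance for s in p.species])
    spec_by_name = {s.name: s for s in p.species}

    rows = []
    for reef in p.reef_areas_m2:
        for t in range(p.transects_per_reef):
            tid = f"{reef}-T{t + 1:02d}"
            zone = "back" if t % 2 == 0 else "fore"
            n = rng.poisson(p.colonies_per_transect_mean)
            for _ in range(n):
                sp = p.species[rng.choice(len(p.species), p=probs)]
                dmax = p.diam_lognorm_median_m * np.exp(
                    rng.normal(0.0, p.diam_lognorm_sigma)
                )
                dperp = dmax * rng.uniform(0.6, 1.0)
                h = dmax * p.height_aspect_median * np.exp(
                    rng.normal(0.0, p.height_aspect_sigma)
                )
                afflicted = bool(sp.sctld_susceptible and rng.random() < p.affliction_prob)
                if afflicted:
                    if rng.random() < 0.3:
                        lesion, mort = 0.0, 100.0
                    else:
                        lesion, mort = float(rng.uniform(15.0, 95.0)), float(rng.uniform(0, 40))
                else:
                    lesion, mort = float(rng.uniform(0.0, 8.0)), float(rng.uniform(0.0, 5.0))
                rows.append(
                    (sp.name, round(dmax, 4), round(dperp, 4), round(h, 4), round(lesion, 2),
                     round(mort, 2), tid, reef, zone)
                )
    survey = pd.DataFrame(
        rows,
        columns=["species", "d_max_m", "d_perp_m", "height_m", "sctld_lesion_pct",
                 "recent_mortality_pct", "transect", "reef", "zone"],
    )
    densities = pd.DataFrame(
        [
            (s.name, s.growth_form, s.d_living, s.d_dead, s.sctld_susceptible)
            for s in p.species
        ],
        columns=["species", "growth_form", "d_living_g_cm3", "d_dead_g_cm3", "sctld_susceptible"],
    )
    areas = pd.DataFrame(
        sorted(p.reef_areas_m2.items()), columns=["reef", "area_m2"]
    )

    # ---- direct-summation oracle over the rounded table we just emitted ----
    transect_pre: dict[str, float] = {}
    transect_post: dict[str, float] = {}
    transect_reef: dict[str, str] = {}
    for reef in p.reef_areas_m2:
        for t in range(p.transects_per_reef):
            tid = f"{reef}-T{t + 1:02d}"
            transect_pre[tid] = 0.0
            transect_post[tid] = 0.0
            transect_reef[tid] = reef
    for row in survey.itertuples(index=False):
        sp = spec_by_name[row.species]
        vol = _true_volume_m3(
            sp.growth_form, row.d_max_m, row.d_perp_m, row.height_m, p.branching_correction
        )
        dead_post = sp.sctld_susceptible and (
            row.sctld_lesion_pct > 10.0 or row.recent_mortality_pct == 100.0
        )
        m_pre = vol * sp.d_living * 1000.0  # kg
        m_post = vol * (sp.d_dead if dead_post else sp.d_living) * 1000.0
        transect_pre[row.transect] += m_pre / p.transect_area_m2
        transect_post[row.transect] += m_post / p.transect_area_m2

    tr = pd.DataFrame(
        {
            "transect": list(transect_pre),
            "reef": [transect_reef[t] for t in transect_pre],
            "pre_kg_m2": [transect_pre[t] for t in transect_pre],
            "post_kg_m2": [transect_post[t] for t in transect_pre],
        }
    )
    tr["loss_kg_m2"] = tr["post_kg_m2"] - tr["pre_kg_m2"]
    tr = tr.sort_values("transect", ignore_index=True)

    reef_rows = []
    for reef, area in sorted(p.reef_areas_m2.items()):
        sub = tr[tr["reef"] == reef]
        pre = sub["pre_kg_m2"].mean()
        post = sub["post_kg_m2"].mean()
        loss = sub["loss_kg_m2"].mean()
        reef_rows.append((reef, area, pre, post, loss, loss * area / 1000.0))
    reefs = pd.DataFrame(
        reef_rows,
        columns=["reef", "area_m2", "pre_kg_m2", "post_kg_m2", "loss_kg_m2", "loss_t"],
    )
    total_area = reefs["area_m2"].sum()
    pre_t = float((reefs["pre_kg_m2"] * reefs["area_m2"]).sum() / 1000.0)
    loss_t = float(reefs["loss_t"].sum())
    system = {
        "loss_t": loss_t,
        "mean_loss_kg_m2": loss_t * 1000.0 / total_area,
        "pre_t": pre_t,
        "percent_lost": 0.0 if pre_t == 0 else 100.0 * (-loss_t) / pre_t,
    }
    truth = BudgetResult(transects=tr, reefs=reefs, system=system)
    layout = tr[["transect", "reef"]].copy()
    tables = {"survey": survey, "densities": densities, "reef_areas": areas, "transects": layout}
    return tables, truth
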