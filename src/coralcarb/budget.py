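"""Pre-/post-mortality carbonate budgets from benthic survey tables.

Colony volume follows the growth form: massive/columnar colonies use the
elliptical-paraboloid model C = (pi/2) * H * r^2 with r the mean of the two
measured diameters divided by two (a radius); branching/foliose colonies use a
rectangular prism scaled by an empirical correction factor (0.11) derived from
3D colony models.  CaCO3 mass is volume x species density (g cm^-3 -> kg m^-3).

Two scenarios are contrasted: "pre" assigns every colony its living skeletal
density; "post" assigns dead-skeleton density to colonies judged killed by
SCTLD (susceptible species with lesions over >10% of the surface, or 100%
recent mortality).  The pre/post difference per unit survey area, aggregated
over transects and scaled by reef areas, is the dissolution loss.  Losses are
reported as negative numbers everywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ColonyRecord",
    "SpeciesDensityTable",
    "VolumeModelParams",
    "BudgetResult",
    "colony_volume",
    "colony_mass",
    "classify_colony",
    "transect_budget",
    "reef_scale",
    "run_budget",
]

GROWTH_FORMS_PARABOLOID = ("massive", "columnar", "sub-massive")
GROWTH_FORMS_PRISM = ("branching", "foliose")


@dataclass(frozen=True)
class ColonyRecord:
    """One surveyed colony (lengths in metres, percents in [0, 100])."""

    species: str
    d_max_m: float
    d_perp_m: float
    height_m: float
    sctld_lesion_pct: float = 0.0
    recent_mortality_pct: float = 0.0
    transect: str = "T01"
    reef: str = "reef"
    zone: str = "back"

    def __post_init__(self) -> None:
        for name in ("d_max_m", "d_perp_m", "height_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sctld_lesion_pct", "recent_mortality_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")


@dataclass
class SpeciesDensityTable:
    """Per-species growth form, living/dead densities and SCTLD susceptibility.

    ``d_dead`` equals ``d_living`` for species where no dissolution applies; a
    dead colony of such a species then contributes zero loss by construction.
    """

    table: pd.DataFrame  # columns: species, growth_form, d_living_g_cm3, d_dead_g_cm3, sctld_susceptible

    def __post_init__(self) -> None:
        required = {"species", "growth_form", "d_living_g_cm3", "d_dead_g_cm3", "sctld_susceptible"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"species density table missing columns: {sorted(missing)}")
        t = self.table
        if (t["d_living_g_cm3"] <= 0).any():
            raise ValueError("d_living_g_cm3 must be positive")
        bad = (t["d_dead_g_cm3"] <= 0) | (t["d_dead_g_cm3"] > t["d_living_g_cm3"])
        if bad.any():
            raise ValueError(
                "d_dead_g_cm3 must satisfy 0 < d_dead <= d_living for: "
                + ", ".join(t.loc[bad, "species"])
            )
        self._by_species = t.set_index("species")

    def lookup(self, species: str) -> pd.Series:
        try:
            return self._by_species.loc[species]
        except KeyError:
            raise KeyError(f"species not in density table: {species!r}") from None


@dataclass(frozen=True)
class VolumeModelParams:
    """Volume-model settings; the branching correction factor (default 0.11,
    an empirical constant derived from 3D colony models) is applied as given,
    never re-derived here."""

    branching_correction: float = 0.11

    def __post_init__(self) -> None:
        if not 0.0 < self.branching_correction <= 1.0:
            raise ValueError("branching correction factor must be in (0, 1]")


@dataclass
class BudgetResult:
    """Budget aggregates at transect, reef and system level.

    transects: transect, reef, pre_kg_m2, post_kg_m2, loss_kg_m2 (<= 0)
    reefs:     reef, area_m2, pre_kg_m2, post_kg_m2, loss_kg_m2, loss_t
    system:    loss_t, mean_loss_kg_m2, pre_t, percent_lost (>= 0)
    """

    transects: pd.DataFrame
    reefs: pd.DataFrame
    system: dict = field(default_factory=dict)


def colony_volume(rec: ColonyRecord, growth_form: str, params: VolumeModelParams | None = None) -> float:
    """Colony volume in m^3 for the given growth-form class."""
    params = params or VolumeModelParams()
    if growth_form in GROWTH_FORMS_PARABOLOID:
        r = (rec.d_max_m + rec.d_perp_m) / 4.0  # mean diameter / 2
        return (math.pi / 2.0) * rec.height_m * r * r
    if growth_form in GROWTH_FORMS_PRISM:
        return params.branching_correction * rec.d_max_m * rec.d_perp_m * rec.height_m
    raise ValueError(f"unknown growth form: {growth_form!r}")


def colony_mass(volume_m3: float, density_g_cm3: float) -> float:
    """CaCO3 mass in kg: volume (m^3) x density (g cm^-3 = t m^-3) x 1000."""
    if volume_m3 < 0:
        raise ValueError("volume must be >= 0")
    if density_g_cm3 <= 0:
        raise ValueError("density must be > 0")
    return volume_m3 * density_g_cm3 * 1000.0


def classify_colony(rec: ColonyRecord, table: SpeciesDensityTable) -> str:
    """'dead_post' if the colony is treated as killed by SCTLD in the post
    scenario, else 'alive_both'.

    A susceptible colony dies in the post scenario when SCTLD lesions cover
    >10% of its surface or recent mortality is total; losses of non-susceptible
    species are not attributed to the disease."""
    row = table.lookup(rec.species)
    if bool(row["sctld_susceptible"]) and (
        rec.sctld_lesion_pct > 10.0 or rec.recent_mortality_pct == 100.0
    ):
        return "dead_post"
    return "alive_both"


def transect_budget(
    colonies: Iterable[ColonyRecord],
    table: SpeciesDensityTable,
    params: VolumeModelParams | None = None,
    transect_area_m2: float = 10.0,
) -> dict:
    """Pre/post/loss kg CaCO3 m^-2 for one transect.

    pre sums living-density mass over ALL colonies; post repeats the sum with
    dead-skeleton density for colonies classified dead_post."""
    if transect_area_m2 <= 0:
        raise ValueError("transect_area_m2 must be positive")
    params = params or VolumeModelParams()
    colonies = list(colonies)
    if not colonies:
        warnings.warn("empty transect: budget is zero", stacklevel=2)
        return {"pre_kg_m2": 0.0, "post_kg_m2": 0.0, "loss_kg_m2": 0.0}
    pre = 0.0
    post = 0.0
    for rec in colonies:
        row = table.lookup(rec.species)
        vol = colony_volume(rec, str(row["growth_form"]), params)
        m_l = colony_mass(vol, float(row["d_living_g_cm3"]))
        pre += m_l
        if classify_colony(rec, table) == "dead_post":
            post += colony_mass(vol, float(row["d_dead_g_cm3"]))
        else:
            post += m_l
    pre /= transect_area_m2
    post /= transect_area_m2
    return {"pre_kg_m2": pre, "post_kg_m2": post, "loss_kg_m2": post - pre}


def reef_scale(transect_results: pd.DataFrame, reef_areas: pd.DataFrame) -> BudgetResult:
    """Aggregate per-transect budgets to reef and system scale.

    ``transect_results`` needs columns transect, reef, pre_kg_m2, post_kg_m2,
    loss_kg_m2; ``reef_areas`` needs reef, area_m2.  Reef values are the mean
    over that reef's transects; tonnes = mean loss x reef area / 1000; the
    system percent lost is relative to the pre-event total fixed CaCO3."""
    required = {"transect", "reef", "pre_kg_m2", "post_kg_m2", "loss_kg_m2"}
    missing = required - set(transect_results.columns)
    if missing:
        raise ValueError(f"transect results missing columns: {sorted(missing)}")
    areas = reef_areas.set_index("reef")["area_m2"]
    if (areas <= 0).any():
        raise ValueError("every reef must have a positive area")
    reef_rows = []
    for reef, area in areas.sort_index().items():
        sub = transect_results[transect_results["reef"] == reef]
        if sub.empty:
            raise ValueError(f"reef {reef!r} has an area but no transects")
        pre = float(sub["pre_kg_m2"].mean())
        post = float(sub["post_kg_m2"].mean())
        loss = float(sub["loss_kg_m2"].mean())
        reef_rows.append((reef, float(area), pre, post, loss, loss * area / 1000.0))
    unknown = set(transect_results["reef"]) - set(areas.index)
    if unknown:
        raise ValueError(f"transects reference reefs without an area: {sorted(unknown)}")
    reefs = pd.DataFrame(
        reef_rows,
        columns=["reef", "area_m2", "pre_kg_m2", "post_kg_m2", "loss_kg_m2", "loss_t"],
    )
    total_area = float(reefs["area_m2"].sum())
    pre_t = float((reefs["pre_kg_m2"] * reefs["area_m2"]).sum() / 1000.0)
    loss_t = float(reefs["loss_t"].sum())
    system = {
        "loss_t": loss_t,
        "mean_loss_kg_m2": loss_t * 1000.0 / total_area,
        "pre_t": pre_t,
        "percent_lost": 0.0 if pre_t == 0 else 100.0 * (-loss_t) / pre_t,
    }
    out = transect_results.sort_values("transect", ignore_index=True)
    return BudgetResult(transects=out, reefs=reefs, system=system)


def run_budget(
    survey: pd.DataFrame,
    densities: pd.DataFrame,
    reef_areas: pd.DataFrame,
    params: VolumeModelParams | None = None,
    transect_area_m2: float = 10.0,
    transects: pd.DataFrame | None = None,
) -> BudgetResult:
    """End-to-end budget from tidy survey/density/area tables.

    ``transects`` optionally registers the full transect layout (columns
    transect, reef); surveyed transects holding no colonies then enter the reef
    means as zeros instead of silently dropping out."""
    params = params or VolumeModelParams()
    table = SpeciesDensityTable(densities)
    rows = []
    seen = set()
    for (reef, tid), grp in survey.groupby(["reef", "transect"], sort=True):
        recs = [
            ColonyRecord(
                species=r.species,
                d_max_m=r.d_max_m,
                d_perp_m=r.d_perp_m,
                height_m=r.height_m,
                sctld_lesion_pct=r.sctld_lesion_pct,
                recent_mortality_pct=r.recent_mortality_pct,
                transect=tid,
                reef=reef,
                zone=getattr(r, "zone", "back"),
            )
            for r in grp.itertuples(index=False)
        ]
        res = transect_budget(recs, table, params, transect_area_m2)
        rows.append((tid, reef, res["pre_kg_m2"], res["post_kg_m2"], res["loss_kg_m2"]))
        seen.add(tid)
    if transects is not None:
        for r in transects.itertuples(index=False):
            if r.transect not in seen:
                rows.append((r.transect, r.reef, 0.0, 0.0, 0.0))
    tr = pd.DataFrame(rows, columns=["transect", "reef", "pre_kg_m2", "post_kg_m2", "loss_kg_m2"])
    return reef_scale(tr, reef_areas)
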