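"""CSV/config readers and writers shared across pipeline stages.

Units convention, fixed globally and carried in column names: survey lengths
in metres, slab/image lengths in centimetres, densities in g cm^-3, masses in
kg, reef reports in tonnes.  All writers emit a deterministic column and row
order with plain C-locale number formatting; every output file starts with
comment lines recording the master seed and the configuration hash so a rerun
can be matched to its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .budget import ColonyRecord

__all__ = [
    "SURVEY_COLUMNS",
    "PipelineConfig",
    "read_survey",
    "write_survey",
    "read_table",
    "write_table",
    "load_config",
    "save_config",
]

SURVEY_COLUMNS = [
    "species",
    "d_max_m",
    "d_perp_m",
    "height_m",
    "sctld_lesion_pct",
    "recent_mortality_pct",
    "transect",
    "reef",
    "zone",
]


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_survey(path: str | Path) -> list[ColonyRecord]:
    """Read and validate a colony survey CSV into :class:`ColonyRecord` rows.

    Validation errors name the offending row (1-based, excluding the header).
    """
    df = _read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey file {path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                ColonyRecord(
                    species=str(row.species),
                    d_max_m=float(row.d_max_m),
                    d_perp_m=float(row.d_perp_m),
                    height_m=float(row.height_m),
                    sctld_lesion_pct=float(row.sctld_lesion_pct),
                    recent_mortality_pct=float(row.recent_mortality_pct),
                    transect=str(row.transect),
                    reef=str(row.reef),
                    zone=str(row.zone),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"survey file {path}, row {i}: {exc}") from exc
    return records


def write_survey(records: list[ColonyRecord], path: str | Path, header: dict | None = None) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=SURVEY_COLUMNS)
    write_table(df, path, header=header)


def write_table(df: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    """Write a DataFrame as CSV with optional ``# key=value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path)


@dataclass
class PipelineConfig:
    """Master configuration of an end-to-end run.

    Paths are interpreted relative to the config file's directory when loaded
    from disk.  The master seed fans out deterministically into per-stage child
    seeds; it is recorded (with the config hash) in every output header.
    """

    out_dir: str = "coralcarb_out"
    seed: int = 0
    # simulate stage (None disables a sub-simulation)
    simulate: bool = True
    phantoms_per_status: int = 3
    survey_transects_per_reef: int = 10
    # densitometry
    track_width_px: int = 5
    smooth_window_cm: float = 0.05
    min_prominence: float = 0.05
    # porosity
    porosity_reference: str = "step_at_slab"
    connectivity: int = 8
    min_pore_area_px: int = 1
    # mixed model
    include_interaction: bool = True
    include_extension: bool = True
    contrast_adjustment: str = "tukey"
    # budget
    transect_area_m2: float = 10.0
    branching_correction: float = 0.11
    # externally supplied inputs (used when simulate is False)
    survey_csv: str | None = None
    densities_csv: str | None = None
    reef_areas_csv: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # hash the scientific parameters only, not output location or verbosity
        doc = asdict(self)
        doc.pop("out_dir", None)
        doc.pop("log_level", None)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> dict:
        return {"seed": self.seed, "config_sha": self.config_hash()}


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
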