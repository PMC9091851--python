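"""Readers, writers and run configuration.

The single interchange format between measurement and statistics is the tidy
RPP table: one CSV row per specimen x element x sector x quadrant with
columns ``specimen_id, taxon, element, age_dph, dev_strategy, sector, q,
porosity`` (``q`` in a..d; porosity blank for missing, never zero).  A wide
per-element variant (columns ``P_a..P_d``) is offered for human inspection.
Label images travel as single-channel 8-bit TIFF/PNG with the pixel size in
a YAML sidecar; every pipeline artifact gets a manifest recording version,
seed and effective configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEV_STRATEGIES,
    ELEMENTS,
    InvalidInputError,
    RPPTrajectory,
    SectorProfile,
    SpecimenMetadata,
    mean_rpp,
)
from .distances import DEFAULT_EPS, DEFAULT_N_TRANSLATIONS, DistanceMatrix
from .geometry import LabelImage, SectorSpec

__all__ = [
    "RPP_COLUMNS",
    "RPPTableData",
    "RunConfig",
    "read_rpp_table",
    "trajectories_from_frame",
    "write_rpp_table",
    "write_wide_table",
    "read_label_image",
    "write_label_image",
    "write_sector_polygons",
    "write_distance_matrix",
    "write_manifest",
]

RPP_COLUMNS = (
    "specimen_id",
    "taxon",
    "element",
    "age_dph",
    "dev_strategy",
    "sector",
    "q",
    "porosity",
)

_QUADRANT_ORDER = {"a": 0, "b": 1, "c": 2, "d": 3}


@dataclass(frozen=True)
class RPPTableData:
    """Validated content of a tidy RPP table."""

    trajectories: list[RPPTrajectory]
    profiles: dict[str, list[SectorProfile]]
    rejected: pd.DataFrame

    @property
    def metadata_frame(self) -> pd.DataFrame:
        """One row of specimen metadata per element, indexed by element id."""
        rows = {
            t.element_id: {
                "specimen_id": t.metadata.specimen_id,
                "taxon": t.metadata.taxon,
                "element": t.metadata.element,
                "age_dph": t.metadata.age_dph,
                "dev_strategy": t.metadata.dev_strategy,
            }
            for t in self.trajectories
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = pd.Series("", index=df.index)
    poro = pd.to_numeric(df["porosity"], errors="coerce")
    bad_poro = poro.notna() & ((poro < 0) | (poro > 100))
    text_junk = df["porosity"].notna() & poro.isna() & (
        df["porosity"].astype(str).str.strip() != ""
    )
    reasons[bad_poro] = "porosity outside [0, 100]"
    reasons[text_junk] = "porosity not numeric"
    reasons[~df["element"].isin(ELEMENTS)] = "unknown element"
    reasons[~df["q"].astype(str).isin(_QUADRANT_ORDER)] = "quadrant not in a-d"
    sector = pd.to_numeric(df["sector"], errors="coerce")
    reasons[sector.isna() | (sector < 1)] = "invalid sector index"
    ok = reasons == ""
    good = df[ok].copy()
    good["porosity"] = poro[ok]
    good["sector"] = sector[ok].astype(int)
    rejected = df[~ok].copy()
    rejected["reason"] = reasons[~ok]
    return good, rejected


def trajectories_from_frame(df: pd.DataFrame) -> RPPTableData:
    """Build sector profiles and mean RPPs from a tidy in-memory table."""
    missing = [c for c in RPP_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"RPP table missing required columns: {missing}")
    good, rejected = _validate_rows(df.copy())
    trajectories: list[RPPTrajectory] = []
    profiles: dict[str, list[SectorProfile]] = {}
    for (spec, element), sub in good.groupby(["specimen_id", "element"], sort=True):
        first = sub.iloc[0]
        age = first["age_dph"]
        strategy = str(first["dev_strategy"])
        meta = SpecimenMetadata(
            specimen_id=str(spec),
            taxon=str(first["taxon"]),
            element=str(element),
            age_dph=None if pd.isna(age) else float(age),
            dev_strategy=strategy if strategy in DEV_STRATEGIES else "unknown",
        )
        elem_profiles = []
        for s, srows in sub.groupby("sector", sort=True):
            values = [np.nan] * 4
            for _, row in srows.iterrows():
                values[_QUADRANT_ORDER[str(row["q"])]] = (
                    np.nan if pd.isna(row["porosity"]) else float(row["porosity"])
                )
            elem_profiles.append(SectorProfile(sector_index=int(s), values=tuple(values)))
        traj = mean_rpp(elem_profiles, metadata=meta)
        trajectories.append(traj)
        profiles[traj.element_id] = elem_profiles
    return RPPTableData(
        trajectories=trajectories, profiles=profiles, rejected=rejected
    )


def read_rpp_table(path: str | Path) -> RPPTableData:
    """Read and validate a tidy RPP CSV; malformed rows land in ``rejected``."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "q": str})
    return trajectories_from_frame(df)


def write_rpp_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RPP_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"RPP table missing required columns: {missing}")
    df.to_csv(path, index=False)


def write_wide_table(trajectories: Sequence[RPPTrajectory], path: str | Path) -> None:
    """Wide per-element mean-RPP table (P_a..P_d columns)."""
    rows = []
    for t in trajectories:
        arr = t.as_array()
        rows.append(
            {
                "element_id": t.element_id,
                "specimen_id": t.metadata.specimen_id,
                "taxon": t.metadata.taxon,
                "element": t.metadata.element,
                "age_dph": t.metadata.age_dph,
                "dev_strategy": t.metadata.dev_strategy,
                "n_sectors": t.n_sectors,
                "centred": t.centred,
                **{f"P_{q}": arr[i] for i, q in enumerate("abcd")},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_label_image(image: LabelImage, path: str | Path) -> None:
    """Write a class raster as 8-bit TIFF/PNG with a pixel-size sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.raster)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.raster)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({"pixel_size": float(image.pixel_size)}))


def read_label_image(path: str | Path) -> LabelImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raster = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raster = iio.imread(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    pixel_size = 1.0
    if sidecar.exists():
        pixel_size = float(yaml.safe_load(sidecar.read_text())["pixel_size"])
    return LabelImage(raster=np.asarray(raster), pixel_size=pixel_size)


def write_sector_polygons(sectors: Sequence[SectorSpec], path: str | Path) -> None:
    """Audit dump of sector boundary polylines, one 'x y' vertex per line."""
    lines = []
    for s in sectors:
        lines.append(f"# sector {s.sector_index}")
        for name in ("inner_boundary", "outer_boundary", "radial_side_1", "radial_side_2"):
            lines.append(f"## {name}")
            for x, y in getattr(s, name):
                lines.append(f"{x:.4f} {y:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path)


def write_manifest(path: str | Path, seed: int | None, config: dict) -> None:
    """Record version, seed and a hash of the effective configuration."""
    from . import __version__

    payload = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Defaults follow the standard measurement design: three sectors, four
    quadrants, missing-quadrant threshold 0.5, K-means/GBTM with 100
    restarts, group numbers 3-5 tested, GBTM capped at five groups.
    """

    n_sectors: int = 3
    n_quadrants: int = 4
    missing_threshold: float = 0.5
    eps: float = DEFAULT_EPS
    n_translations: int = DEFAULT_N_TRANSLATIONS
    k_range: tuple[int, ...] = (3, 4, 5)
    n_restarts: int = 100
    k_max: int = 5
    degrees: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_quadrants < 2:
            raise InvalidInputError("quadrant count must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("k_range", "degrees"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)
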