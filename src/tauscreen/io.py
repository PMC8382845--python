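"""Data model and file I/O for field images, plate layouts, masks and metric tables.

Images travel as plain numpy grids inside :class:`FieldImage`; nothing here
rescales, clips or silently type-promotes intensities.  Label masks round-trip
through 16-bit single-plane TIFFs, metric tables through CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    ChannelGeometryError,
    DuplicateWellError,
    IncompleteFieldError,
    LabelOverflowError,
    NoNegativeControlError,
)

#: Channel roles every field must carry, in canonical plane order.
CHANNELS = ("dna", "tubulin", "total_tau", "p_tau")

#: Treatment kinds recognised in a plate layout.
TREATMENT_KINDS = ("dmso", "positive_control", "compound", "empty")

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


def validate_well_id(well_id: str) -> str:
    """Check a 96-well coordinate (A1..H12); returns it normalised (uppercase)."""
    w = str(well_id).strip().upper()
    if not _WELL_RE.match(w):
        raise ValueError(f"well {well_id!r} outside 96-well grid A1-H12")
    return w


@dataclass
class FieldImage:
    """One imaged field: four co-registered 2D intensity grids plus identity.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"B7"``.
    field_index : int
        Acquisition index within the well, 0..fields_per_well-1.
    channels : dict
        Mapping of channel role (:data:`CHANNELS`) to a 2D non-negative grid.
    pixel_size : float, optional
        Physical edge length of one pixel in micrometres.
    """

    well_id: str
    field_index: int
    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise IncompleteFieldError(
                f"incomplete field: missing channel(s) {missing}"
            )
        shapes = {c: np.asarray(g).shape for c, g in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ChannelGeometryError(f"channel geometry mismatch: {shapes}")
        for c in CHANNELS:
            g = np.asarray(self.channels[c])
            if g.ndim != 2:
                raise ChannelGeometryError(f"channel {c} is not a 2D grid")
            if not np.all(np.isfinite(g)) or (g < 0).any():
                raise ValueError(f"channel {c} holds non-finite or negative values")
        self.well_id = validate_well_id(self.well_id)

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.channels["dna"]).shape


@dataclass
class Treatment:
    kind: str
    compound_id: str | None = None
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in TREATMENT_KINDS:
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if self.kind == "compound":
            if self.compound_id is None:
                raise ValueError("compound well without compound_id")
            if self.dose is None:
                raise ValueError(f"compound well {self.compound_id} without dose")


@dataclass
class PlateLayout:
    """A 96-well plate map: treatment per well plus acquisition geometry."""

    plate_id: str
    wells: dict[str, Treatment]
    fields_per_well: int = 25

    def __post_init__(self) -> None:
        self.wells = {validate_well_id(w): t for w, t in self.wells.items()}
        if not any(t.kind == "dmso" for t in self.wells.values()):
            raise NoNegativeControlError("no negative control (DMSO) well in layout")

    def wells_of_kind(self, kind: str) -> list[str]:
        return sorted(w for w, t in self.wells.items() if t.kind == kind)


def read_field(path: str | Path, channel_map: Mapping[int, str]) -> FieldImage:
    """Read a multi-plane TIFF into a :class:`FieldImage`.

    ``channel_map`` maps plane index -> channel role and must cover all four
    roles; plane order is never inferred.  Pixel values pass through unchanged
    (8/16-bit integer and floating point all accepted).
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    missing = set(CHANNELS) - set(channel_map.values())
    if missing:
        raise IncompleteFieldError(f"incomplete field: channel_map lacks {sorted(missing)}")
    channels: dict[str, np.ndarray] = {}
    for plane, role in channel_map.items():
        if plane >= arr.shape[0]:
            raise IncompleteFieldError(
                f"incomplete field: plane {plane} absent in {path.name} "
                f"({arr.shape[0]} planes)"
            )
        channels[role] = np.asarray(arr[plane])
    well_id, field_index = _identity_from_name(path.stem)
    return FieldImage(well_id=well_id, field_index=field_index, channels=channels)


def read_field_channels(paths: Mapping[str, str | Path],
                        well_id: str = "A1", field_index: int = 0) -> FieldImage:
    """Read a per-channel TIFF set (role -> file path) into a FieldImage."""
    missing = set(CHANNELS) - set(paths)
    if missing:
        raise IncompleteFieldError(f"incomplete field: no file for {sorted(missing)}")
    channels = {role: tifffile.imread(Path(p)) for role, p in paths.items()}
    return FieldImage(well_id=well_id, field_index=field_index, channels=channels)


def write_field(field_img: FieldImage, path: str | Path) -> None:
    """Write a FieldImage as a multi-plane float32 TIFF in canonical order.

    The file name encodes well and field index so :func:`read_field` can
    recover identity.
    """
    path = Path(path)
    stack = np.stack([np.asarray(field_img.channels[c], dtype=np.float32)
                      for c in CHANNELS])
    tifffile.imwrite(path, stack, photometric="minisblack")


def field_file_name(well_id: str, field_index: int, suffix: str = ".tif") -> str:
    return f"{well_id}_f{field_index:02d}{suffix}"


def _identity_from_name(stem: str) -> tuple[str, int]:
    m = re.match(r"^([A-H](?:[1-9]|1[0-2]))_f(\d+)", stem)
    if m:
        return m.group(1), int(m.group(2))
    return "A1", 0


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read a plate map from CSV (well,kind,compound_id,dose) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rows = [dict(well=w, **rec) for w, rec in doc.get("wells", {}).items()]
        plate_id = str(doc.get("plate_id", path.stem))
        fields_per_well = int(doc.get("fields_per_well", 25))
    else:
        df = pd.read_csv(path, comment="#")
        rows = df.to_dict("records")
        plate_id = path.stem
        fields_per_well = 25
    wells: dict[str, Treatment] = {}
    for row in rows:
        w = validate_well_id(row["well"])
        if w in wells:
            raise DuplicateWellError(f"duplicate well {w}")
        kind = str(row["kind"]).strip().lower()
        comp = row.get("compound_id")
        if comp is not None and (isinstance(comp, float) and np.isnan(comp)):
            comp = None
        dose = row.get("dose")
        if dose is not None and not (isinstance(dose, str) and not dose):
            dose = None if (isinstance(dose, float) and np.isnan(dose)) else float(dose)
        wells[w] = Treatment(kind=kind, compound_id=comp, dose=dose)
    return PlateLayout(plate_id=plate_id, wells=wells, fields_per_well=fields_per_well)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    rows = [
        {"well": w, "kind": t.kind, "compound_id": t.compound_id, "dose": t.dose}
        for w, t in sorted(layout.wells.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# masks

#: Mask roles written by write_masks, in output order.
MASK_ROLES = (
    "nucleus_labels",
    "soma_labels",
    "neurite_mask_total",
    "neurite_mask_final",
    "clump_mask",
    "soma_quant_labels",
    "neurite_quant_mask",
)


def write_masks(masks, path: str | Path) -> dict[str, Path]:
    """Write segmentation masks as 16-bit single-plane TIFFs, one per role.

    ``path`` is a prefix; each role lands in ``<path>_<role>.tif``.  Background
    is 0 and labels are preserved exactly, so a read-back reproduces the grid.
    """
    path = Path(path)
    out: dict[str, Path] = {}
    for role in MASK_ROLES:
        grid = getattr(masks, role, None)
        if grid is None:
            continue
        grid = np.asarray(grid)
        if grid.dtype == bool:
            grid = grid.astype(np.uint16)
        if grid.max(initial=0) > np.iinfo(np.uint16).max:
            raise LabelOverflowError(
                f"label overflow in {role}: max label {int(grid.max())} > 65535"
            )
        fp = path.parent / f"{path.name}_{role}.tif"
        tifffile.imwrite(fp, grid.astype(np.uint16), photometric="minisblack")
        out[role] = fp
    return out


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


# ---------------------------------------------------------------------------
# metric tables


def write_metrics(table, path: str | Path) -> None:
    """Write a metrics collection to CSV at full float precision.

    Accepts a DataFrame or any iterable of dataclass-like records exposing
    ``to_row()`` or ``__dict__``.  The first line is a ``#`` header naming the
    column order so files are self-describing.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        rows = []
        for rec in table:
            if hasattr(rec, "to_row"):
                rows.append(rec.to_row())
            else:
                rows.append(dict(rec.__dict__))
        df = pd.DataFrame(rows)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns: " + ",".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
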