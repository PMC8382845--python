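"""Per-field and per-well compartment measures.

Mean intensities follow the total-over-area construction: the summed channel
intensity over a quantification mask divided by the mask's pixel count, with
soma pixels pooled across the field rather than averaged per cell.  The
phospho/total tau ratio is the ratio of those two means per field.  No
background subtraction is applied before summing (an optional local-background
flag exists for exploration and is off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import FieldImage, Treatment
from .segment import SegmentationMasks

#: Metric columns aggregated at well level.
METRIC_COLUMNS = (
    "neurite_area", "soma_area",
    "total_ptau_neurite", "total_ptau_soma",
    "total_ttau_neurite", "total_ttau_soma",
    "mean_ptau_neurite", "mean_ptau_soma",
    "mean_ttau_neurite", "mean_ttau_soma",
    "ratio_ptau_ttau_neurite", "ratio_ptau_ttau_soma",
    "n_neuronal_cells",
)


@dataclass
class FieldMetrics:
    well_id: str
    field_index: int
    neurite_area: float = 0.0
    soma_area: float = 0.0
    total_ptau_neurite: float = 0.0
    total_ptau_soma: float = 0.0
    total_ttau_neurite: float = 0.0
    total_ttau_soma: float = 0.0
    mean_ptau_neurite: float = math.nan
    mean_ptau_soma: float = math.nan
    mean_ttau_neurite: float = math.nan
    mean_ttau_soma: float = math.nan
    ratio_ptau_ttau_neurite: float = math.nan
    ratio_ptau_ttau_soma: float = math.nan
    n_neuronal_cells: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    def to_row(self) -> dict:
        return dict(self.__dict__)


def compartment_mean(channel: np.ndarray, mask: np.ndarray) -> float:
    """Summed intensity over the mask divided by the mask pixel count.

    Returns NaN (an undefined-value marker, never zero) for an empty mask so
    degenerate fields can be flagged rather than silently diluted.
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        return math.nan
    return float(np.asarray(channel, float)[mask].sum() / n)


def field_metrics(field_img: FieldImage, masks: SegmentationMasks) -> FieldMetrics:
    """Populate every per-field measure from the finalized quantification masks."""
    ptau = np.asarray(field_img.channels["p_tau"], float)
    ttau = np.asarray(field_img.channels["total_tau"], float)
    neur = np.asarray(masks.neurite_quant_mask, bool)
    soma = np.asarray(masks.soma_quant_labels) > 0

    m = FieldMetrics(well_id=field_img.well_id, field_index=field_img.field_index)
    m.neurite_area = float(neur.sum())
    m.soma_area = float(soma.sum())
    m.total_ptau_neurite = float(ptau[neur].sum())
    m.total_ptau_soma = float(ptau[soma].sum())
    m.total_ttau_neurite = float(ttau[neur].sum())
    m.total_ttau_soma = float(ttau[soma].sum())
    m.mean_ptau_neurite = compartment_mean(ptau, neur)
    m.mean_ptau_soma = compartment_mean(ptau, soma)
    m.mean_ttau_neurite = compartment_mean(ttau, neur)
    m.mean_ttau_soma = compartment_mean(ttau, soma)
    if m.mean_ttau_neurite and m.mean_ttau_neurite > 0:
        m.ratio_ptau_ttau_neurite = m.mean_ptau_neurite / m.mean_ttau_neurite
    if m.mean_ttau_soma and m.mean_ttau_soma > 0:
        m.ratio_ptau_ttau_soma = m.mean_ptau_soma / m.mean_ttau_soma
    m.n_neuronal_cells = sum(1 for r in masks.nuclei if r.klass == "neuronal_live")
    if m.neurite_area == 0 or m.soma_area == 0:
        m.excluded = True
        m.exclusion_reason = "degenerate"
    return m


@dataclass
class WellMetrics:
    well_id: str
    treatment: Treatment | None
    n_fields_used: int
    n_excluded: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    usable: bool = True

    def to_row(self) -> dict:
        row = {"well_id": self.well_id, "n_fields_used": self.n_fields_used,
               "n_excluded": self.n_excluded, "usable": self.usable}
        if self.treatment is not None:
            row.update(kind=self.treatment.kind,
                       compound_id=self.treatment.compound_id,
                       dose=self.treatment.dose)
        for k in METRIC_COLUMNS:
            row[f"{k}_mean"] = self.mean.get(k, math.nan)
            row[f"{k}_sd"] = self.sd.get(k, math.nan)
        return row


def aggregate_well(fields: Sequence[FieldMetrics],
                   treatment: Treatment | None = None) -> WellMetrics:
    """Mean/SD of every metric over a well's non-excluded fields.

    SD is left NaN (flagged, never fabricated) when fewer than two usable
    fields remain; a well with zero usable fields is flagged unusable.
    """
    if not fields:
        raise ValueError("aggregate_well needs at least one field")
    well_ids = {f.well_id for f in fields}
    if len(well_ids) != 1:
        raise ValueError(f"fields span multiple wells: {sorted(well_ids)}")
    used = [f for f in fields if not f.excluded]
    wm = WellMetrics(well_id=fields[0].well_id, treatment=treatment,
                     n_fields_used=len(used),
                     n_excluded=len(fields) - len(used),
                     usable=bool(used))
    for col in METRIC_COLUMNS:
        vals = np.array([getattr(f, col) for f in used], float)
        vals = vals[np.isfinite(vals)]
        wm.mean[col] = float(vals.mean()) if vals.size else math.nan
        wm.sd[col] = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return wm


def metrics_frame(fields: Iterable[FieldMetrics]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fields])
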