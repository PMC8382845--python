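"""Plate-level QC, normalization, z-factor, toxicity and hit calling.

QC checkpoints mirror the assay's three-rule scheme: (a) a plate is
"unresponsive" and excluded when the raw DMSO / positive-control phospho-tau
intensity ratio in neurites falls below 1.3; (b) fields whose neurite area
falls below the lower 95% confidence bound of their own well are excluded;
(c) fields below the lower bound of the plate's pooled DMSO wells are
excluded.  Rules (b) and (c) are evaluated on the original field set and the
union of exclusions is taken, so their order is immaterial.

Responses normalise to the plate-pooled DMSO mean (fold change), the
screening window is the Z'-factor 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|
computed on well-level means, a >20% decrease in neurite area flags
neurotoxicity, and a hit must fall below the positive-control fold change in
BOTH the cell-body and neurite compartments while non-toxic and QC-passing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientFieldsError,
    InvalidReferenceError,
    MissingControlError,
    ZeroDynamicRangeError,
)
from .io import PlateLayout


@dataclass
class QCThresholds:
    responsiveness_min_ratio: float = 1.3
    ci_level: float = 0.95
    toxicity_max_decrease: float = 0.20
    positive_control_dose: float = 11.0      # µM, reference GSK3 inhibitor
    ci_mode: str = "mean_ci"                 # or "percentile" (empirical lower tail)

    def __post_init__(self) -> None:
        if not self.responsiveness_min_ratio > 1:
            raise ValueError("responsiveness_min_ratio must exceed 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.toxicity_max_decrease < 1:
            raise ValueError("toxicity_max_decrease must be in (0, 1)")


@dataclass
class QCReport:
    plate_id: str
    plate_responsive: bool
    responsiveness_ratio: float
    exclusions: pd.DataFrame         # well_id, field_index, reason (one row per rule hit)
    n_excluded_by_rule: dict[str, int]

    def excluded_keys(self) -> set[tuple[str, int]]:
        return set(zip(self.exclusions["well_id"], self.exclusions["field_index"]))


def plate_responsiveness(dmso_values: Sequence[float],
                         pos_control_values: Sequence[float],
                         thresholds: QCThresholds) -> tuple[bool, float]:
    """Raw DMSO / positive-control ratio of field-level neurite phospho-tau means."""
    dmso = np.asarray(list(dmso_values), float)
    pos = np.asarray(list(pos_control_values), float)
    dmso = dmso[np.isfinite(dmso)]
    pos = pos[np.isfinite(pos)]
    if dmso.size == 0 or pos.size == 0:
        raise MissingControlError("missing control group for responsiveness check")
    ratio = float(dmso.mean() / pos.mean())
    return ratio >= thresholds.responsiveness_min_ratio, ratio


def ci_lower(values: Sequence[float], level: float = 0.95,
             mode: str = "mean_ci") -> float:
    """Lower bound of the t-based confidence interval of the mean.

    ``mode="percentile"`` instead returns the empirical (1-level)/2 quantile,
    an alternative reading of "lower 95% CI" exposed for comparison.
    """
    vals = np.asarray(list(values), float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise InsufficientFieldsError("insufficient fields for a confidence bound")
    if mode == "percentile":
        return float(np.quantile(vals, (1.0 - level) / 2.0))
    n = vals.size
    t = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return float(vals.mean() - t * vals.std(ddof=1) / math.sqrt(n))


def apply_field_qc(fields: pd.DataFrame, layout: PlateLayout,
                   thresholds: QCThresholds) -> QCReport:
    """Field-exclusion rules (b) within-well CI and (c) DMSO CI.

    ``fields`` is a field-metrics table (one row per field) with at least
    well_id, field_index, neurite_area, mean_ptau_neurite and excluded
    columns.  Both rules are evaluated against the original field set;
    exclusions are the union, each recorded under every rule it failed.
    """
    rows = []
    degenerate = fields[fields["excluded"].astype(bool)]
    for _, r in degenerate.iterrows():
        rows.append((r["well_id"], int(r["field_index"]), "degenerate"))

    # rule (b): within-well bound
    for well_id, grp in fields.groupby("well_id"):
        try:
            bound = ci_lower(grp["neurite_area"], thresholds.ci_level,
                             thresholds.ci_mode)
        except InsufficientFieldsError:
            continue
        bad = grp[grp["neurite_area"] < bound]
        rows.extend((well_id, int(r["field_index"]), "within_well_ci")
                    for _, r in bad.iterrows())

    # rule (c): plate-pooled DMSO bound
    dmso_wells = set(layout.wells_of_kind("dmso"))
    dmso_fields = fields[fields["well_id"].isin(dmso_wells)]
    if len(dmso_fields) >= 2:
        bound_c = ci_lower(dmso_fields["neurite_area"], thresholds.ci_level,
                           thresholds.ci_mode)
        bad = fields[fields["neurite_area"] < bound_c]
        rows.extend((r["well_id"], int(r["field_index"]), "dmso_ci")
                    for _, r in bad.iterrows())

    pos_wells = set(layout.wells_of_kind("positive_control"))
    pos_fields = fields[fields["well_id"].isin(pos_wells)]
    if len(dmso_fields) and len(pos_fields):
        responsive, ratio = plate_responsiveness(
            dmso_fields["mean_ptau_neurite"], pos_fields["mean_ptau_neurite"],
            thresholds)
    else:
        responsive, ratio = True, math.nan

    excl = pd.DataFrame(rows, columns=["well_id", "field_index", "reason"])
    counts = excl["reason"].value_counts().to_dict() if len(excl) else {}
    return QCReport(plate_id=layout.plate_id, plate_responsive=responsive,
                    responsiveness_ratio=ratio, exclusions=excl,
                    n_excluded_by_rule=counts)


def fold_change_vs_dmso(values: Sequence[float],
                        dmso_reference: Sequence[float]) -> np.ndarray:
    """Per-field fold change: each value over the pooled-DMSO reference mean."""
    ref = np.asarray(list(dmso_reference), float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0 or not np.isfinite(ref.mean()) or ref.mean() <= 0:
        raise InvalidReferenceError("invalid reference: DMSO mean undefined or <= 0")
    return np.asarray(list(values), float) / ref.mean()


def z_factor(positive: Sequence[float], negative: Sequence[float]) -> float:
    """Screening-window statistic 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|.

    Inputs are well-level means, one value per control well.
    """
    pos = np.asarray(list(positive), float)
    neg = np.asarray(list(negative), float)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientFieldsError("z-factor needs >= 2 wells per group")
    delta = abs(pos.mean() - neg.mean())
    if delta == 0:
        raise ZeroDynamicRangeError("zero dynamic range: control means equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / delta)


def flag_toxicity(neurite_area_fold: float, thresholds: QCThresholds) -> bool:
    """Neurotoxic iff the neurite-area fold change drops by more than the cap."""
    return bool(neurite_area_fold < 1.0 - thresholds.toxicity_max_decrease)


def call_hits(table: pd.DataFrame, control_fold_neurite: float,
              control_fold_soma: float) -> pd.DataFrame:
    """Hit and compartment-selectivity flags for a normalized screen table.

    A hit must beat the positive control in BOTH compartments, be non-toxic
    and QC-passing.  Compounds active only in neurites are reported as
    neurite-selective, not as hits.
    """
    out = table.copy()
    below_n = out["fold_ptau_neurite"] < control_fold_neurite
    below_s = out["fold_ptau_soma"] < control_fold_soma
    eligible = ~out["toxic"] & out["qc_pass"]
    out["hit"] = below_n & below_s & eligible
    out["neurite_selective"] = below_n & ~below_s & eligible
    out["soma_selective"] = below_s & ~below_n & eligible
    return out


@dataclass
class ScreenResult:
    """Normalized per-treatment screen table plus plate-level statistics."""

    table: pd.DataFrame
    qc: QCReport
    z_factors: dict[str, float] = field(default_factory=dict)
    control_fold_neurite: float = math.nan
    control_fold_soma: float = math.nan

    def waterfall(self, compartment: str = "neurite") -> pd.DataFrame:
        col = f"fold_ptau_{compartment}"
        return self.table.sort_values(col).reset_index(drop=True)


#: per-field metrics normalized against the DMSO reference
_FOLD_METRICS = ("mean_ptau_neurite", "mean_ptau_soma", "neurite_area",
                 "ratio_ptau_ttau_neurite", "ratio_ptau_ttau_soma")
_FOLD_NAMES = ("fold_ptau_neurite", "fold_ptau_soma", "fold_neurite_area",
               "fold_ratio_neurite", "fold_ratio_soma")


def run_screen(fields: pd.DataFrame, layout: PlateLayout,
               thresholds: QCThresholds | None = None) -> ScreenResult:
    """Full plate analysis: QC, normalization, z-factors, toxicity, hits.

    ``fields`` is a field-metrics table (one row per imaged field).  Returns a
    :class:`ScreenResult` whose table has one row per compound x dose (and one
    per control kind), carrying fold changes ± SEM, toxicity/hit flags, and
    whose ``z_factors`` are computed from well-level raw control means.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    qc = apply_field_qc(fields, layout, thresholds)

    excluded = qc.excluded_keys()
    keys = list(zip(fields["well_id"], fields["field_index"].astype(int)))
    usable = fields[[k not in excluded for k in keys]].copy()

    dmso_wells = set(layout.wells_of_kind("dmso"))
    dmso = usable[usable["well_id"].isin(dmso_wells)]
    if not len(dmso):
        raise MissingControlError("missing control: no usable DMSO fields")

    for metric, name in zip(_FOLD_METRICS, _FOLD_NAMES):
        usable[name] = fold_change_vs_dmso(usable[metric], dmso[metric])

    def well_kind(w: str) -> str:
        return layout.wells[w].kind

    usable["kind"] = [well_kind(w) for w in usable["well_id"]]
    usable["compound_id"] = [layout.wells[w].compound_id for w in usable["well_id"]]
    usable["dose"] = [layout.wells[w].dose for w in usable["well_id"]]

    # well-level raw means for z-factors
    well_means = usable.groupby("well_id").agg(
        mean_ptau_neurite=("mean_ptau_neurite", "mean"),
        mean_ptau_soma=("mean_ptau_soma", "mean"),
        ratio_neurite=("ratio_ptau_ttau_neurite", "mean"),
        ratio_soma=("ratio_ptau_ttau_soma", "mean"),
    )
    pos_wells = set(layout.wells_of_kind("positive_control"))
    zf: dict[str, float] = {}
    pos_idx = [w for w in well_means.index if w in pos_wells]
    neg_idx = [w for w in well_means.index if w in dmso_wells]
    if len(pos_idx) >= 2 and len(neg_idx) >= 2:
        for col, name in [("mean_ptau_neurite", "ptau_neurite"),
                          ("mean_ptau_soma", "ptau_soma"),
                          ("ratio_neurite", "ratio_neurite"),
                          ("ratio_soma", "ratio_soma")]:
            try:
                zf[name] = z_factor(well_means.loc[pos_idx, col],
                                    well_means.loc[neg_idx, col])
            except ZeroDynamicRangeError:
                zf[name] = math.nan

    # per-treatment aggregation of fold changes (SEM over fields)
    def _agg(grp: pd.DataFrame) -> dict:
        row: dict = {"n_fields": len(grp),
                     "n_wells": grp["well_id"].nunique()}
        for name in _FOLD_NAMES:
            v = grp[name].to_numpy(float)
            v = v[np.isfinite(v)]
            row[name] = v.mean() if v.size else math.nan
            row[f"{name}_sem"] = (v.std(ddof=1) / math.sqrt(v.size)
                                  if v.size >= 2 else math.nan)
        return row

    rows = []
    pos = usable[usable["kind"] == "positive_control"]
    ctrl_n = ctrl_s = math.nan
    if len(pos):
        row = _agg(pos)
        row.update(kind="positive_control", compound_id=None,
                   dose=thresholds.positive_control_dose)
        rows.append(row)
        ctrl_n = row["fold_ptau_neurite"]
        ctrl_s = row["fold_ptau_soma"]
    dm = usable[usable["kind"] == "dmso"]
    if len(dm):
        row = _agg(dm)
        row.update(kind="dmso", compound_id=None, dose=None)
        rows.append(row)
    comp = usable[usable["kind"] == "compound"]
    seen: set[tuple] = set()
    for (cid, dose), grp in comp.groupby(["compound_id", "dose"]):
        row = _agg(grp)
        row.update(kind="compound", compound_id=cid, dose=dose)
        rows.append(row)
        seen.add((cid, dose))
    # treatments whose every field was excluded stay visible, flagged unusable
    for w, t in layout.wells.items():
        if t.kind == "compound" and (t.compound_id, t.dose) not in seen:
            row = {name: math.nan for name in _FOLD_NAMES}
            row.update({f"{name}_sem": math.nan for name in _FOLD_NAMES})
            row.update(n_fields=0, n_wells=0, kind="compound",
                       compound_id=t.compound_id, dose=t.dose)
            rows.append(row)
            seen.add((t.compound_id, t.dose))

    table = pd.DataFrame(rows)
    table["toxic"] = [flag_toxicity(f, thresholds) if np.isfinite(f) else False
                      for f in table["fold_neurite_area"]]
    table["qc_pass"] = qc.plate_responsive & (table["n_fields"] > 0)
    if np.isfinite(ctrl_n) and np.isfinite(ctrl_s):
        table = call_hits(table, ctrl_n, ctrl_s)
        # controls themselves are never hits
        table.loc[table["kind"] != "compound",
                  ["hit", "neurite_selective", "soma_selective"]] = False
    else:
        table["hit"] = False
        table["neurite_selective"] = False
        table["soma_selective"] = False
    return ScreenResult(table=table, qc=qc, z_factors=zf,
                        control_fold_neurite=ctrl_n, control_fold_soma=ctrl_s)
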