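"""Object- and well-level quality control for the 96-well assay.

Cleaning proceeds in a fixed order: (1) drop non-animal objects (the MDHD
class and sub-165 µm debris), (2) compute per-well medians and drop wells
with implausible animal counts (outside 5..60 inclusive), (3) flag outlier
wells whose median falls outside 1.5 × IQR fences computed within
strain × treatment × plate-design groups.  Object filters strictly precede
count filters, which strictly precede outlier detection; the QC report
tallies removals at every stage per strain × treatment so either ordering
convention for reporting retained counts is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

WELL_KEYS = ["design_id", "treatment", "strain", "well"]
GROUP_KEYS = ["strain", "treatment", "design_id"]


@dataclass
class FilterConfig:
    """Thresholds for the exclusion rules.

    min_length_um
        Objects strictly shorter than this are treated as debris (µm).
    min_animals, max_animals
        Inclusive bounds on retained animals per well; wells with fewer than
        ``min_animals`` or more than ``max_animals`` are excluded.
    iqr_multiplier
        Half-width of the outlier fences in IQR units.
    exclude_classes
        Object classes removed outright (non-animal detections).
    min_group_size
        Groups with fewer wells than this skip outlier detection; quartiles
        of very few points are too unstable to define fences.
    """

    min_length_um: float = 165.0
    min_animals: int = 5
    max_animals: int = 60
    iqr_multiplier: float = 1.5
    exclude_classes: frozenset[str] = frozenset({"MDHD"})
    min_group_size: int = 4

    def __post_init__(self) -> None:
        if self.min_length_um <= 0:
            raise ValueError("min_length_um must be positive")
        if self.min_animals > self.max_animals:
            raise ValueError("min_animals must not exceed max_animals")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")
        self.exclude_classes = frozenset(self.exclude_classes)


@dataclass
class QCReport:
    """Per-stage removal accounting, shaped per strain × treatment."""

    objects_raw: int = 0
    objects_removed_class: int = 0
    objects_removed_debris: int = 0
    wells_raw: int = 0
    wells_removed_count: int = 0
    wells_removed_outlier: int = 0
    per_group: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def objects_retained(self) -> int:
        return self.objects_raw - self.objects_removed_class - self.objects_removed_debris

    @property
    def wells_retained(self) -> int:
        return self.wells_raw - self.wells_removed_count - self.wells_removed_outlier


class EmptyAfterQCError(RuntimeError):
    """Every well was removed by quality control."""


def filter_objects(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove excluded-class objects and debris.

    Retains rows with ``object_class`` outside ``cfg.exclude_classes`` and
    ``length_um >= cfg.min_length_um`` (the boundary value is an animal, the
    rule removes strictly shorter objects).  Returns the retained records and
    a per-well tally of removals by reason (columns MDHD_REMOVED and
    DEBRIS_REMOVED).  Empty input yields empty output.
    """
    cfg = cfg or FilterConfig()
    if len(records) == 0:
        tallies = pd.DataFrame(columns=WELL_KEYS + ["MDHD_REMOVED", "DEBRIS_REMOVED"])
        return records.copy(), tallies

    is_excluded_class = records["object_class"].isin(cfg.exclude_classes)
    # class exclusion takes precedence in the tallies; a short MDHD object
    # counts once, as a class removal
    is_debris = ~is_excluded_class & (records["length_um"] < cfg.min_length_um)
    retained = records[~is_excluded_class & ~is_debris].copy()

    tally = (
        records.assign(
            MDHD_REMOVED=is_excluded_class.astype(int),
            DEBRIS_REMOVED=is_debris.astype(int),
        )
        .groupby(WELL_KEYS, as_index=False)[["MDHD_REMOVED", "DEBRIS_REMOVED"]]
        .sum()
    )
    return retained, tally


def summarize_wells(records_raw: pd.DataFrame, records_retained: pd.DataFrame) -> pd.DataFrame:
    """Build per-well summaries: raw/retained counts and the retained median.

    Wells present in the raw records but emptied by object filtering keep a
    row with ``n_objects_retained = 0`` and an undefined median.
    """
    raw_counts = (
        records_raw.groupby(WELL_KEYS, as_index=False)
        .size()
        .rename(columns={"size": "n_objects_raw"})
    )
    if len(records_retained):
        kept = records_retained.groupby(WELL_KEYS, as_index=False).agg(
            n_objects_retained=("length_um", "size"),
            median_length_um=("length_um", "median"),
        )
    else:
        kept = pd.DataFrame(columns=WELL_KEYS + ["n_objects_retained", "median_length_um"])
    out = raw_counts.merge(kept, on=WELL_KEYS, how="left")
    out["n_objects_retained"] = out["n_objects_retained"].astype("float64").fillna(0).astype(int)
    out["qc_flags"] = [set() for _ in range(len(out))]
    return out


def filter_wells_by_count(wells: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Flag wells whose retained animal count lies outside [min, max].

    The rule reads "fewer than five or more than 60": counts of exactly 5 or
    exactly 60 are kept.  Flags are added to ``qc_flags``; nothing else is
    mutated.
    """
    cfg = cfg or FilterConfig()
    wells = wells.copy()
    wells["qc_flags"] = [set(f) for f in wells["qc_flags"]]
    bad = (wells["n_objects_retained"] < cfg.min_animals) | (
        wells["n_objects_retained"] > cfg.max_animals
    )
    for i in np.flatnonzero(bad.to_numpy()):
        wells["qc_flags"].iat[i].add("COUNT_FAIL")
    return wells


def flag_outlier_wells(
    wells: pd.DataFrame,
    cfg: FilterConfig | None = None,
    group_keys: Iterable[str] = GROUP_KEYS,
) -> pd.DataFrame:
    """Flag wells whose median falls outside the IQR fences of its group.

    Within each ``group_keys`` group of wells not already flagged, Q1 and Q3
    are linear-interpolation quantiles of the well medians; fences sit at
    Q1 − k·IQR and Q3 + k·IQR with k = ``cfg.iqr_multiplier``.  The fences
    are open: a median exactly on a fence is retained.  Groups with fewer
    than ``cfg.min_group_size`` eligible wells are skipped.
    """
    cfg = cfg or FilterConfig()
    wells = wells.copy()
    wells["qc_flags"] = [set(f) for f in wells["qc_flags"]]
    eligible = wells["qc_flags"].map(len) == 0
    eligible &= wells["median_length_um"].notna()

    for _, idx in wells[eligible].groupby(list(group_keys)).groups.items():
        med = wells.loc[idx, "median_length_um"].to_numpy(float)
        if len(med) < cfg.min_group_size:
            continue
        q1, q3 = np.quantile(med, [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo = q1 - cfg.iqr_multiplier * iqr
        hi = q3 + cfg.iqr_multiplier * iqr
        out = (med < lo) | (med > hi)
        for i in np.asarray(idx)[out]:
            wells["qc_flags"].loc[i].add("OUTLIER_WELL")
    return wells


def run_qc(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full cleaning cascade and return the phenotype table.

    Object filters, then per-well medians with the count filter, then
    outlier-well flagging.  The returned phenotype table holds only
    unflagged wells (columns: design_id, treatment, strain, well,
    n_objects_raw, n_objects_retained, median_length_um).  The report gives
    removal counts at each stage, overall and per strain × treatment.

    Raises :class:`EmptyAfterQCError` if no well survives.
    """
    cfg = cfg or FilterConfig()
    report = QCReport(objects_raw=len(records))

    retained, tallies = filter_objects(records, cfg)
    if len(tallies):
        report.objects_removed_class = int(tallies["MDHD_REMOVED"].sum())
        report.objects_removed_debris = int(tallies["DEBRIS_REMOVED"].sum())

    wells = summarize_wells(records, retained)
    report.wells_raw = len(wells)
    wells = filter_wells_by_count(wells, cfg)
    wells = flag_outlier_wells(wells, cfg)

    flags = wells["qc_flags"]
    report.wells_removed_count = int(sum("COUNT_FAIL" in f for f in flags))
    report.wells_removed_outlier = int(sum("OUTLIER_WELL" in f for f in flags))

    clean = wells[flags.map(len) == 0].drop(columns=["qc_flags"]).reset_index(drop=True)
    if len(clean) == 0:
        raise EmptyAfterQCError("no wells remain after quality control")

    report.per_group = _per_group_table(wells, clean)
    return clean, report


def _per_group_table(wells: pd.DataFrame, clean: pd.DataFrame) -> pd.DataFrame:
    """Retained animals and wells per strain × treatment (Table-1 shape)."""
    g = clean.groupby(["strain", "treatment"], as_index=False).agg(
        animals=("n_objects_retained", "sum"), wells=("well", "size")
    )
    raw = wells.groupby(["strain", "treatment"], as_index=False).agg(
        wells_raw=("well", "size")
    )
    out = raw.merge(g, on=["strain", "treatment"], how="left")
    out[["animals", "wells"]] = out[["animals", "wells"]].astype("float64").fillna(0).astype(int)
    return out.sort_values(["strain", "treatment"]).reset_index(drop=True)
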