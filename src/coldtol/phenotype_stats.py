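"""Well-median phenotypes, reaction norms and the cold-tolerance delta.

The unit of analysis is the well median: the median body length (µm) of the
retained animals in one well.  Cold tolerance is summarised per treatment
well as

    delta = mean(control well medians for the same strain and plate design)
            − (treatment well median)

so a larger delta means a stronger developmental slowdown under cold, i.e.
lower cold tolerance.  Reaction norms are per-strain means of well medians
in each environment; their slope (cold − control) is the strain's
plasticity.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def well_median(lengths: Sequence[float]) -> float:
    """Median of a non-empty set of animal lengths.

    Even counts give the midpoint of the two central order statistics.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("well_median of an empty collection is undefined")
    return float(np.median(arr))


def cold_tolerance_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment-well cold-tolerance difference statistic.

    ``table`` is a post-QC phenotype table (columns strain, design_id,
    treatment, well, median_length_um) containing both treatments.  For each
    strain × plate design, each cold well's median is subtracted from the
    mean of the surviving control well medians, giving one delta per
    surviving cold well.  Cold wells of a strain × design with no surviving
    control wells are dropped with a warning.
    """
    levels = set(table["treatment"].unique())
    if len(levels) < 2:
        raise ValueError("no contrast available: table has a single treatment level")

    control = (
        table[table["treatment"] == "control"]
        .groupby(["strain", "design_id"], as_index=False)["median_length_um"]
        .mean()
        .rename(columns={"median_length_um": "control_mean_um"})
    )
    treat = table[table["treatment"] != "control"]
    merged = treat.merge(control, on=["strain", "design_id"], how="left")
    missing = merged["control_mean_um"].isna()
    if missing.any():
        for _, row in merged[missing].iterrows():
            logger.warning(
                "dropping treatment well %s (strain %s, design %s): "
                "no surviving control wells",
                row["well"], row["strain"], row["design_id"],
            )
        merged = merged[~missing]
    out = merged[["strain", "design_id", "well"]].copy()
    out["delta_um"] = merged["control_mean_um"] - merged["median_length_um"]
    return out.reset_index(drop=True)


def reaction_norm(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per strain × treatment means of well medians, plus per-strain slopes.

    Returns ``(means, slopes)`` where ``means`` has one row per strain ×
    treatment with the arithmetic mean of well medians, and ``slopes`` has
    one row per strain with ``slope_um`` = cold mean − control mean.
    """
    means = (
        table.groupby(["strain", "treatment"], as_index=False)["median_length_um"]
        .mean()
        .rename(columns={"median_length_um": "mean_length_um"})
    )
    wide = means.pivot(index="strain", columns="treatment", values="mean_length_um")
    slopes = pd.DataFrame(
        {
            "strain": wide.index,
            "slope_um": (
                wide.get("cold", pd.Series(np.nan, index=wide.index))
                - wide.get("control", pd.Series(np.nan, index=wide.index))
            ).to_numpy(),
        }
    ).reset_index(drop=True)
    return means, slopes


def strain_mean_differences(
    deltas: pd.DataFrame, per_design_first: bool = False
) -> pd.DataFrame:
    """Mean cold-tolerance delta per strain.

    By default all surviving treatment wells are pooled; with
    ``per_design_first`` the deltas are averaged within each plate design
    first and the design means are then averaged with equal weight (the two
    conventions coincide for balanced designs).
    """
    if per_design_first:
        by_design = deltas.groupby(["strain", "design_id"], as_index=False)["delta_um"].mean()
        out = by_design.groupby("strain", as_index=False)["delta_um"].mean()
    else:
        out = deltas.groupby("strain", as_index=False)["delta_um"].mean()
    return out.rename(columns={"delta_um": "mean_delta_um"})
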