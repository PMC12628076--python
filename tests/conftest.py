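"""Shared fixtures: a hand-built toy assay whose QC outcome is known exactly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def _well_rows(design, well, strain, treatment, lengths, object_class="L3"):
    return [
        {
            "plate_id": f"{design}-{treatment}",
            "design_id": design,
            "well": well,
            "strain": strain,
            "treatment": treatment,
            "object_class": object_class,
            "length_um": float(x),
        }
        for x in lengths
    ]


def _ten_animals(median):
    """Ten lengths whose median is exactly ``median``."""
    offsets = [-20, -15, -10, -5, -1, 1, 5, 10, 15, 20]
    return [median + o for o in offsets]


@pytest.fixture
def toy_objects() -> pd.DataFrame:
    """Toy object table constructed to lose exactly one well to COUNT_FAIL
    and one to OUTLIER_WELL, with known debris/MDHD removals.

    Control group (S1, control, D1): wells A1-A4 with 10 animals each and
    medians 500/502/504/506; A5 has 10 animals with median 600 (the outlier:
    fences are [496, 512]); A6 has only 4 animals (count failure).  A1 also
    carries 3 debris objects (<165 µm) and A2 carries 2 MDHD objects.  Cold
    group (S1, cold, D1): wells B1-B4 with 10 animals each, medians
    400/402/404/406 — no artifacts.

    Expected outcome: 99 raw objects, 3 debris + 2 MDHD removed, 10 raw
    wells, 1 COUNT_FAIL, 1 OUTLIER_WELL, 8 wells and 80 animals retained.
    """
    rows = []
    for i, med in enumerate([500, 502, 504, 506]):
        rows += _well_rows("D1", f"A{i + 1}", "S1", "control", _ten_animals(med))
    rows += _well_rows("D1", "A5", "S1", "control", _ten_animals(600))
    rows += _well_rows("D1", "A6", "S1", "control", [480, 490, 500, 510])
    rows += _well_rows("D1", "A1", "S1", "control", [100, 120, 150])  # debris
    rows += _well_rows("D1", "A2", "S1", "control", [400, 420], object_class="MDHD")
    for i, med in enumerate([400, 402, 404, 406]):
        rows += _well_rows("D1", f"B{i + 1}", "S1", "cold", _ten_animals(med))
    return pd.DataFrame(rows)


TOY_EXPECT = {
    "objects_raw": 99,
    "objects_removed_debris": 3,
    "objects_removed_class": 2,
    "wells_raw": 10,
    "wells_removed_count": 1,
    "wells_removed_outlier": 1,
    "wells_retained": 8,
    "animals_retained": 80,
}


@pytest.fixture
def balanced_oneway() -> pd.DataFrame:
    """Balanced one-way layout with closed-form REML: A{1,2} B{3,4} C{5,6}."""
    return pd.DataFrame(
        {"y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "group": list("AABBCC")}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
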