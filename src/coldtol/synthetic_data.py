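"""Synthetic assay generator mirroring the analysis model.

The generator is the exact generative mirror of the mixed model the
pipeline fits: a well's median length is

    y = grand_mean + treatment_effect·[cold] + design_effect
        + a_strain + g_strain,treatment + e_well

with a ~ N(0, sd_strain²), g ~ N(0, sd_gxe²) and e ~ N(0, sd_well²).  The
object layer draws per-animal lengths around each well's mean and injects
the artefacts the QC stage exists to remove: sub-165 µm debris detections,
MDHD-class objects, and wells with implausible animal counts.

Default sizes copy the assay layout: 7 strains × one row of 12 wells per
plate × 3 plate designs × {control, cold}, ≈50 animals per well.  Default
effect sizes and variance shares are chosen so a fitted model lands near
H²_strain ≈ 0.2 and H²_strain:treatment ≈ 0.45 — illustrative of a strong
G×E regime, not ground truth for any real strain panel.

Randomness: one ``numpy`` SeedSequence derived from the single ``seed``
field; child sequences are spawned in a fixed order (well layer first,
object layer second) so the well-level table is identical whether or not
objects are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGH"


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic assay.

    Lengths are µm; standard deviations are on the well-median scale except
    ``sd_object_um``, the within-well animal-length spread.
    """

    n_strains: int = 7
    wells_per_strain_per_plate: int = 12
    n_designs: int = 3
    animals_per_well_mean: float = 50.0
    animals_per_well_dispersion: float = 0.0  # 0 → Poisson counts
    grand_mean_um: float = 750.0
    treatment_effect_um: float = -130.0
    design_effects_um: tuple[float, ...] = (-12.0, 2.0, 10.0)
    sd_strain_um: float = 26.83
    sd_gxe_um: float = 40.25
    sd_well_um: float = 35.50
    sd_object_um: float = 50.0
    debris_rate: float = 0.0
    mdhd_rate: float = 0.0
    count_anomaly_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_strain_um", "sd_gxe_um", "sd_well_um", "sd_object_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("debris_rate", "mdhd_rate", "count_anomaly_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if len(self.design_effects_um) != self.n_designs:
            raise ValueError("design_effects_um must have one entry per design")
        if abs(sum(self.design_effects_um)) > 1e-8:
            raise ValueError("design_effects_um must sum to zero")

    def with_artifacts(self, debris=0.02, mdhd=0.01, count_anomaly=0.03):
        """Copy with the QC-exercising contamination rates switched on."""
        return replace(
            self, debris_rate=debris, mdhd_rate=mdhd, count_anomaly_rate=count_anomaly
        )


def _strains(cfg: SimulationConfig) -> list[str]:
    return [f"ST{i + 1:02d}" for i in range(cfg.n_strains)]


def _rngs(cfg: SimulationConfig) -> tuple[np.random.Generator, np.random.Generator]:
    well_ss, object_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    return np.random.default_rng(well_ss), np.random.default_rng(object_ss)


def simulate_well_medians(
    cfg: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a well-level phenotype table straight from the mixed model.

    Returns the table (design_id, treatment, strain, well, median_length_um)
    and a record of the true draws: the strain effects ``a`` and the
    strain-by-treatment effects ``g``, keyed by level, plus the fixed-effect
    truth.  Identical seeds give identical tables.
    """
    cfg = cfg or SimulationConfig()
    rng, _ = _rngs(cfg)
    strains = _strains(cfg)
    treatments = ("control", "cold")

    a = rng.normal(0.0, cfg.sd_strain_um, size=cfg.n_strains)
    g = rng.normal(0.0, cfg.sd_gxe_um, size=(cfg.n_strains, 2))

    rows = []
    for d in range(cfg.n_designs):
        design = f"D{d + 1}"
        for t_idx, trt in enumerate(treatments):
            for s_idx, strain in enumerate(strains):
                row_letter = ROW_LETTERS[s_idx % len(ROW_LETTERS)]
                mu = (
                    cfg.grand_mean_um
                    + (cfg.treatment_effect_um if trt == "cold" else 0.0)
                    + cfg.design_effects_um[d]
                    + a[s_idx]
                    + g[s_idx, t_idx]
                )
                e = rng.normal(0.0, cfg.sd_well_um, size=cfg.wells_per_strain_per_plate)
                for w in range(cfg.wells_per_strain_per_plate):
                    col = w % 12 + 1
                    rows.append(
                        {
                            "design_id": design,
                            "treatment": trt,
                            "strain": strain,
                            "well": f"{row_letter}{col}" if cfg.wells_per_strain_per_plate <= 12
                            else f"{ROW_LETTERS[w // 12]}{col}",
                            "median_length_um": mu + e[w],
                        }
                    )
    table = pd.DataFrame(rows)
    truth = {
        "a": dict(zip(strains, a)),
        "g": {
            f"{s}:{t}": g[i, j]
            for i, s in enumerate(strains)
            for j, t in enumerate(treatments)
        },
        "grand_mean_um": cfg.grand_mean_um,
        "treatment_effect_um": cfg.treatment_effect_um,
        "design_effects_um": cfg.design_effects_um,
    }
    return table, truth


_COUNT_RANGE = (5, 60)  # usable animal counts; anomalies are injected explicitly


def _draw_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Animals dispensed into one well.

    Poisson around the target (gamma-Poisson when over-dispersion is
    requested), resampled into the assay's usable range so that
    ``count_anomaly_rate`` is the sole source of count-failure wells.
    """
    m = cfg.animals_per_well_mean
    lo, hi = _COUNT_RANGE
    while True:
        if cfg.animals_per_well_dispersion > 0:
            shape = 1.0 / cfg.animals_per_well_dispersion
            n = int(rng.poisson(rng.gamma(shape, m / shape)))
        else:
            n = int(rng.poisson(m))
        if lo <= n <= hi:
            return n


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated to > 0 by resampling (preserves unimodality)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_object_table(cfg: SimulationConfig | None = None) -> pd.DataFrame:
    """Generate a per-animal object table under the well model.

    Each well's animals are drawn Normal(well mean, sd_object²) truncated
    positive.  Contamination, all per-well and seeded: debris objects with
    lengths below 165 µm at ``debris_rate`` (expected debris per well =
    rate × mean count), MDHD-class objects at ``mdhd_rate``, and count
    anomalies at ``count_anomaly_rate`` (the well's animal count is forced
    below 5 or above 60 with equal probability).
    """
    cfg = cfg or SimulationConfig()
    wells, _ = simulate_well_medians(cfg)
    _, rng = _rngs(cfg)

    classes = ("L2", "L3", "L4")
    rows = []
    for rec in wells.itertuples(index=False):
        plate_id = f"{rec.design_id}-{rec.treatment}"
        n = _draw_count(rng, cfg)
        if cfg.count_anomaly_rate and rng.random() < cfg.count_anomaly_rate:
            n = int(rng.integers(0, 5)) if rng.random() < 0.5 else int(rng.integers(61, 91))
        lengths = _positive_normal(rng, rec.median_length_um, cfg.sd_object_um, n)
        for x in lengths:
            rows.append(
                (plate_id, rec.design_id, rec.well, rec.strain, rec.treatment,
                 classes[int(rng.integers(len(classes)))], float(x))
            )
        n_debris = rng.poisson(cfg.debris_rate * cfg.animals_per_well_mean) if cfg.debris_rate else 0
        for _ in range(n_debris):
            rows.append(
                (plate_id, rec.design_id, rec.well, rec.strain, rec.treatment,
                 "L1", float(rng.uniform(40.0, 164.0)))
            )
        n_mdhd = rng.poisson(cfg.mdhd_rate * cfg.animals_per_well_mean) if cfg.mdhd_rate else 0
        for _ in range(n_mdhd):
            rows.append(
                (plate_id, rec.design_id, rec.well, rec.strain, rec.treatment,
                 "MDHD", float(rng.uniform(30.0, 120.0)))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id", "design_id", "well", "strain",
            "treatment", "object_class", "length_um",
        ],
    )
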