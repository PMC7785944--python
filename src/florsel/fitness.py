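"""Female and male fitness components and herbivory proportions from raw plant records.

Female fitness per plant is total seed production: the mean number of ripe seeds per
fruit (over up to three sampled fruits) times total fruit production.  Male fitness is
estimated from pollen-count assays: the grains remaining in sampled anthers after
pollination are scaled up by the suspension/subsample volumes and the number of anthers
per flower, and subtracted from the population's mean per-flower pollen production to
give dispersed grains per flower; total male fitness multiplies by the number of
hermaphrodite flowers.  Female components use all flowers (female fitness is
independent of flower gender in this system), male components only hermaphrodite ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantRecord",
    "FitnessComponents",
    "female_fitness_components",
    "male_fitness_components",
    "herbivory_components",
    "fitness_table",
    "POLLEN_COUNT_COLUMNS",
]

logger = logging.getLogger(__name__)

POLLEN_COUNT_COLUMNS = tuple(f"pollen_count_{i}" for i in range(1, 11))


def _missing(x):
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class PlantRecord:
    """One plant's raw measurements; any field may be missing (None/NaN)."""

    plant_id: str
    population: str | None = None
    corolla_color: float | None = None
    calyx_color: float | None = None
    corolla_area: float | None = None
    calyx_length: float | None = None
    floral_display: float | None = None
    flowers_total: float | None = None
    flowers_hermaphrodite: float | None = None
    fruits_total: float | None = None
    fruit_counts: tuple = ()  # (ripe, aborted) per sampled fruit, up to 3
    percent_corolla_predated: float | None = None
    ovaries_predated: float | None = None
    pollen_counts: tuple = ()
    anthers_counted: int | None = None
    suspension_volume_ul: float | None = None
    subsample_volume_ul: float | None = None

    def __post_init__(self):
        for name in ("flowers_total", "flowers_hermaphrodite", "fruits_total",
                     "ovaries_predated"):
            v = getattr(self, name)
            if not _missing(v) and v < 0:
                raise ValueError(f"{name} must be non-negative for {self.plant_id}")
        ft, fh = self.flowers_total, self.flowers_hermaphrodite
        if not _missing(ft) and not _missing(fh) and fh > ft:
            raise ValueError(f"flowers_hermaphrodite > flowers_total for {self.plant_id}")
        if not _missing(ft) and not _missing(self.fruits_total) and self.fruits_total > ft:
            raise ValueError(f"fruits_total > flowers_total for {self.plant_id}")
        p = self.percent_corolla_predated
        if not _missing(p) and not (0 <= p <= 100):
            raise ValueError(f"percent_corolla_predated outside [0, 100] for {self.plant_id}")

    @classmethod
    def from_series(cls, row):
        """Build a record from one row of the pipeline CSV schema."""
        def get(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        fruit_counts = []
        for k in (1, 2, 3):
            ripe, ab = get(f"fruit{k}_ripe"), get(f"fruit{k}_aborted")
            if ripe is not None and ab is not None:
                fruit_counts.append((float(ripe), float(ab)))
        pollen = []
        for col in POLLEN_COUNT_COLUMNS:
            v = get(col)
            if v is not None:
                pollen.append(float(v))
        return cls(
            plant_id=str(row.get("plant_id", "")),
            population=get("population"),
            corolla_color=get("corolla_color"),
            calyx_color=get("calyx_color"),
            corolla_area=get("corolla_area"),
            calyx_length=get("calyx_length"),
            floral_display=get("floral_display"),
            flowers_total=get("flowers_total"),
            flowers_hermaphrodite=get("flowers_hermaphrodite"),
            fruits_total=get("fruits_total"),
            fruit_counts=tuple(fruit_counts),
            percent_corolla_predated=get("percent_corolla_predated"),
            ovaries_predated=get("ovaries_predated"),
            pollen_counts=tuple(pollen),
            anthers_counted=None if get("anthers_counted") is None
            else int(row["anthers_counted"]),
            suspension_volume_ul=get("suspension_volume_ul"),
            subsample_volume_ul=get("subsample_volume_ul"),
        )


@dataclass
class FitnessComponents:
    """Per-plant derived fitness components; missing inputs propagate as None."""

    fruit_set: float | None = None
    seed_set: float | None = None
    ovules_per_flower: float | None = None
    seeds_per_fruit: float | None = None
    seeds_per_plant: float | None = None
    undispersed_per_flower: float | None = None
    dispersed_per_flower: float | None = None
    dispersed_per_plant: float | None = None
    proportion_ovaries_predated: float | None = None
    dispersed_clamped: bool = False
    excluded_fruits: int = 0

    def as_dict(self):
        return {
            k: getattr(self, k)
            for k in (
                "fruit_set", "seed_set", "ovules_per_flower", "seeds_per_fruit",
                "seeds_per_plant", "undispersed_per_flower", "dispersed_per_flower",
                "dispersed_per_plant", "proportion_ovaries_predated",
            )
        }


def female_fitness_components(rec):
    """Fruit-set, seed-set, ovules/flower, seeds/fruit and total seed production."""
    out = FitnessComponents()
    flowers, fruits = rec.flowers_total, rec.fruits_total
    if not _missing(flowers) and flowers >= 1 and not _missing(fruits):
        out.fruit_set = float(fruits) / float(flowers)
    valid = []
    for ripe, aborted in rec.fruit_counts:
        ovules = ripe + aborted
        if ovules <= 0:
            out.excluded_fruits += 1
            logger.info("plant %s: fruit with zero ovules excluded", rec.plant_id)
            continue
        valid.append((ripe, ovules))
    if valid:
        out.ovules_per_flower = float(np.mean([ov for _, ov in valid]))
        out.seeds_per_fruit = float(np.mean([ripe for ripe, _ in valid]))
        out.seed_set = float(np.mean([ripe / ov for ripe, ov in valid]))
    if not _missing(fruits):
        if fruits == 0:
            out.seeds_per_plant = 0.0
        elif out.seeds_per_fruit is not None:
            out.seeds_per_plant = out.seeds_per_fruit * float(fruits)
    return out


def male_fitness_components(rec, pop_mean_production, anthers_per_flower=10):
    """Undispersed and dispersed pollen grains per flower and per plant.

    ``pop_mean_production`` is the population's mean pollen production per flower;
    ``anthers_per_flower`` defaults to 10 (the species' stamen number).  A negative
    dispersed estimate (sampling noise pushing the undispersed count above the
    population mean production) is clamped to 0 and flagged.
    """
    out = FitnessComponents()
    if pop_mean_production is None or pop_mean_production <= 0:
        raise ValueError("pop_mean_production must be positive")
    if not rec.pollen_counts:
        return out
    if rec.anthers_counted not in (1, 2):
        raise ValueError(f"anthers_counted must be 1 or 2 for {rec.plant_id}")
    susp, sub = rec.suspension_volume_ul, rec.subsample_volume_ul
    if _missing(susp) or _missing(sub) or susp <= 0 or sub <= 0:
        raise ValueError(f"assay volumes must be positive for {rec.plant_id}")
    grains_sampled = float(np.mean(rec.pollen_counts)) * (susp / sub)
    per_anther = grains_sampled / rec.anthers_counted
    out.undispersed_per_flower = per_anther * anthers_per_flower
    dispersed = pop_mean_production - out.undispersed_per_flower
    if dispersed < 0:
        dispersed = 0.0
        out.dispersed_clamped = True
    out.dispersed_per_flower = dispersed
    fh = rec.flowers_hermaphrodite
    if not _missing(fh):
        out.dispersed_per_plant = out.dispersed_per_flower * float(fh)
    return out


def herbivory_components(rec):
    """Proportion of predated ovaries relative to total ovaries (one ovary per flower)."""
    flowers, predated = rec.flowers_total, rec.ovaries_predated
    if _missing(flowers) or flowers < 1 or _missing(predated):
        return None
    if predated > flowers:
        raise ValueError(f"ovaries_predated > flowers_total for {rec.plant_id}")
    return float(predated) / float(flowers)


def fitness_table(df, pollen_production_means=None, anthers_per_flower=10):
    """Derive all fitness components for every row of a plant table.

    ``pollen_production_means`` maps population label -> mean pollen grains produced
    per flower; male components are left missing for populations without an entry or
    plants without assay data.  Returns a DataFrame aligned with ``df``.
    """
    pollen_production_means = pollen_production_means or {}
    rows = []
    for _, r in df.iterrows():
        rec = PlantRecord.from_series(r)
        comp = female_fitness_components(rec)
        prod = pollen_production_means.get(rec.population)
        if prod is not None and rec.pollen_counts:
            male = male_fitness_components(rec, prod, anthers_per_flower)
            comp.undispersed_per_flower = male.undispersed_per_flower
            comp.dispersed_per_flower = male.dispersed_per_flower
            comp.dispersed_per_plant = male.dispersed_per_plant
            comp.dispersed_clamped = male.dispersed_clamped
        comp.proportion_ovaries_predated = herbivory_components(rec)
        d = comp.as_dict()
        d["plant_id"] = rec.plant_id
        d["population"] = rec.population
        d["dispersed_clamped"] = comp.dispersed_clamped
        rows.append(d)
    out = pd.DataFrame(rows, index=df.index)
    cols = ["plant_id", "population"] + [c for c in out.columns
                                         if c not in ("plant_id", "population")]
    return out[cols]
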