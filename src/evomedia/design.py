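"""96-well plate layouts and stock-solution recipes.

A scored generation becomes wet-lab instructions in two parts: a pair of
plate layouts (one plate receiving cells, one cell-free background plate with
the identical treatment map) and, per treatment, a pipetting recipe giving
the volume of each amino-acid stock to add so the final medium reaches the
decoded target concentration, with the basal-medium/DIW make-up volume
reduced accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import ParameterSpace
from .errors import InfeasibleDesignError, ValidationError
from .ga import Generation, Individual

__all__ = [
    "PlateLayout",
    "Recipe",
    "WELLS",
    "default_stock_table",
    "volumes_for_treatment",
    "design_plates",
    "layouts_to_frame",
    "recipes_to_frame",
]

#: All 96 well coordinates in row-major order (A1..A12, B1..B12, ...).
WELLS: tuple[str, ...] = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))

#: Default amino-acid stock concentrations, g/L.  Aspartic and glutamic acid
#: stocks are diluted by the sodium hydroxide needed to solubilize them.
DEFAULT_STOCK_G_PER_L = 5.0
NAOH_DILUTED_STOCK_G_PER_L = 4.6
_NAOH_DILUTED = ("aspartic", "glutamic")


@dataclass(frozen=True)
class PlateLayout:
    """Map of occupied wells to (treatment/control label, replicate, role)."""

    plate_id: str
    wells: dict[str, tuple[str, int, str]]
    fill_volume_ul: float = 200.0

    def __post_init__(self) -> None:
        bad = [w for w in self.wells if w not in WELLS]
        if bad:
            raise ValidationError(f"invalid well coordinates: {bad}")

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for label, _, _ in self.wells.values():
            if label not in seen:
                seen.append(label)
        return tuple(seen)


@dataclass(frozen=True)
class Recipe:
    """Stock additions (µl) plus diluent make-up for one treatment volume."""

    treatment_id: str
    total_volume_ml: float
    additions: tuple[tuple[str, float, float], ...]  # (stock, g/L, volume µl)
    diluent_volume_ul: float

    def __post_init__(self) -> None:
        total_ul = self.total_volume_ml * 1000.0
        vol_sum = sum(v for _, _, v in self.additions) + self.diluent_volume_ul
        if abs(vol_sum - total_ul) > 1e-6:
            raise ValidationError(
                f"{self.treatment_id}: volumes sum to {vol_sum} µl, expected {total_ul}"
            )
        if any(v < 0 for _, _, v in self.additions) or self.diluent_volume_ul < 0:
            raise ValidationError(f"{self.treatment_id}: negative volume in recipe")

    def achieved_concentrations(self, space: ParameterSpace) -> np.ndarray:
        """Final-medium µg/ml implied by the recipe (basal + additions)."""
        by_name = {name: (g_per_l, vol) for name, g_per_l, vol in self.additions}
        out = []
        for spec in space.optimizable_specs:
            g_per_l, vol_ul = by_name[spec.name]
            # stock g/L ≡ µg/µl, so added µg = g_per_l × vol_ul
            out.append(spec.basal_conc + g_per_l * vol_ul / self.total_volume_ml)
        return np.array(out)


def default_stock_table(space: ParameterSpace) -> dict[str, float]:
    """Stock concentration (g/L) per optimizable component."""
    stocks = {}
    for spec in space.optimizable_specs:
        diluted = any(tag in spec.name.lower() for tag in _NAOH_DILUTED)
        stocks[spec.name] = NAOH_DILUTED_STOCK_G_PER_L if diluted else DEFAULT_STOCK_G_PER_L
    return stocks


def volumes_for_treatment(
    individual: Individual,
    space: ParameterSpace,
    stocks: Mapping[str, float] | None = None,
    total_volume_ml: float = 10.0,
) -> Recipe:
    """Stock volumes realizing the individual's decoded concentrations.

    For each component the mass to add on top of the basal medium is
    ``(target − basal) µg/ml × total ml``; at a stock of ``S`` g/L
    (= ``S`` µg/µl) this takes ``(target − basal) × total / S`` µl.  The
    diluent (DIW/basal make-up) absorbs the remaining volume.
    """
    stocks = default_stock_table(space) if stocks is None else dict(stocks)
    additions: list[tuple[str, float, float]] = []
    for spec, target in zip(space.optimizable_specs, individual.concentrations):
        if spec.name not in stocks:
            raise ValidationError(f"no stock concentration for {spec.name}")
        if target < spec.basal_conc - 1e-9:
            raise InfeasibleDesignError(
                f"{individual.treatment_id}: target {target} µg/ml of {spec.name} "
                f"below basal {spec.basal_conc} (cannot remove from basal medium)"
            )
        stock_g_per_l = float(stocks[spec.name])
        vol_ul = (target - spec.basal_conc) * total_volume_ml / stock_g_per_l
        additions.append((spec.name, stock_g_per_l, vol_ul))
    total_ul = total_volume_ml * 1000.0
    added_ul = sum(v for _, _, v in additions)
    if added_ul > total_ul:
        worst = sorted(additions, key=lambda a: -a[2])[:3]
        raise InfeasibleDesignError(
            f"{individual.treatment_id}: stock additions ({added_ul:.1f} µl) exceed "
            f"total volume ({total_ul:.1f} µl); largest: "
            + ", ".join(f"{n} {v:.1f} µl" for n, _, v in worst)
        )
    return Recipe(
        treatment_id=individual.treatment_id,
        total_volume_ml=total_volume_ml,
        additions=tuple(additions),
        diluent_volume_ul=total_ul - added_ul,
    )


def design_plates(
    generation: Generation | Sequence[str],
    n_replicates: int = 3,
    controls: Sequence[str] = ("M199",),
    fill_volume_ul: float = 200.0,
    randomize: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[PlateLayout, PlateLayout]:
    """Paired cells / cell-free layouts for a generation plus controls.

    Treatments fill the plate row-major in replicate blocks, controls follow
    in the remaining wells.  Both plates carry the identical treatment map and
    differ only in role.  Well assignment is deterministic unless
    ``randomize`` is set (then a seeded permutation of the occupied wells is
    applied identically to both plates).
    """
    if isinstance(generation, Generation):
        labels = [ind.treatment_id for ind in generation.individuals]
        plate_tag = f"G{generation.index}"
    else:
        labels = list(generation)
        plate_tag = "plate"
    entries: list[tuple[str, int]] = [
        (label, rep)
        for label in list(labels) + list(controls)
        for rep in range(1, n_replicates + 1)
    ]
    if len(entries) > len(WELLS):
        raise InfeasibleDesignError(
            f"layout needs {len(entries)} wells but a plate has {len(WELLS)}"
        )
    wells = list(WELLS[: len(entries)])
    if randomize:
        rng = np.random.default_rng() if rng is None else rng
        wells = [wells[i] for i in rng.permutation(len(wells))]
    cells = {w: (label, rep, "cells") for w, (label, rep) in zip(wells, entries)}
    cell_free = {w: (label, rep, "cell_free") for w, (label, rep) in zip(wells, entries)}
    return (
        PlateLayout(f"{plate_tag}-cells", cells, fill_volume_ul),
        PlateLayout(f"{plate_tag}-cellfree", cell_free, fill_volume_ul),
    )


def layouts_to_frame(*layouts: PlateLayout) -> pd.DataFrame:
    """Long-format plate map: plate_id, well, treatment_id, replicate, role."""
    rows = [
        {"plate_id": lay.plate_id, "well": w, "treatment_id": label,
         "replicate": rep, "role": role}
        for lay in layouts
        for w, (label, rep, role) in sorted(lay.wells.items(), key=lambda kv: WELLS.index(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["plate_id", "well", "treatment_id", "replicate", "role"])


def recipes_to_frame(recipes: Iterable[Recipe]) -> pd.DataFrame:
    """Long-format recipes: one row per stock addition plus a diluent row."""
    rows = []
    for r in recipes:
        for name, g_per_l, vol in r.additions:
            rows.append(
                {"treatment_id": r.treatment_id, "stock": name,
                 "stock_g_per_L": g_per_l, "volume_ul": vol}
            )
        rows.append(
            {"treatment_id": r.treatment_id, "stock": "diluent",
             "stock_g_per_L": np.nan, "volume_ul": r.diluent_volume_ul}
        )
    return pd.DataFrame(rows, columns=["treatment_id", "stock", "stock_g_per_L", "volume_ul"])
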