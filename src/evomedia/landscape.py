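"""Synthetic fitness landscapes and simulated plate-reader assays.

Real campaigns score media on live cells; for testing and benchmarking this
module plants a smooth single-optimum response surface over the concentration
space and simulates the full assay: triplicate fluorescence readings for a
cells plate and a paired cell-free background plate, multiplicative
per-animal (biological individual) effects, and additive replicate noise.

The surface is a Gaussian-bowl multiplicative response

    surface(x) = max_gain ** (1 − d(x)),

where ``d`` is a non-negative quadratic form in the component-wise normalized
distances from the planted optimum θ*, including optional sparse pairwise
interaction terms, normalized so that ``d = 1`` exactly at the basal-medium
(control) composition and clipped to ``[0, d_max]``.  Hence the noiseless
signal equals ``baseline × max_gain`` at θ* and exactly ``baseline`` for the
control, so the scored RIMA of the control is 1 and of the optimum is
``max_gain``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import compute_fitness
from .design import PlateLayout, design_plates
from .encoding import ParameterSpace, ParameterSpec
from .errors import ReconciliationError, ValidationError
from .ga import Campaign, GAConfig

__all__ = [
    "LandscapeModel",
    "sample_landscape",
    "simulate_assay",
    "recovery_experiment",
    "make_demo_space",
    "grid_distance",
]


@dataclass
class LandscapeModel:
    """Planted response surface plus assay noise model."""

    space: ParameterSpace
    optimum: np.ndarray                  # θ*, µg/ml per optimizable component
    curvature: np.ndarray                # q_i ≥ 0 per component
    interactions: tuple[tuple[int, int, float], ...] = ()
    baseline_rfu: float = 1000.0         # biological signal of the control
    max_gain: float = 1.6                # surface value at θ* relative to control
    background_rfu: float = 100.0        # cell-free signal level
    noise_sd: float = 0.0                # additive replicate SD on RFU
    individual_effects: dict[str, float] = field(default_factory=lambda: {"I1": 1.0})
    d_max: float = 1.25                  # clip of the normalized distance
    control_conc: np.ndarray | None = None  # defaults to the basal composition

    def __post_init__(self) -> None:
        self.optimum = np.asarray(self.optimum, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        n = len(self.space.optimizable_specs)
        if self.optimum.size != n or self.curvature.size != n:
            raise ValidationError("optimum/curvature size must match optimizable specs")
        if (self.curvature < 0).any():
            raise ValidationError("curvature terms must be non-negative")
        if self.control_conc is None:
            self.control_conc = self.space.basal_concentrations
        self.control_conc = np.asarray(self.control_conc, dtype=float)
        self._ranges = np.array(
            [s.upper - s.lower for s in self.space.optimizable_specs], dtype=float
        )
        d0_control = self._raw_distance(self.control_conc)
        if d0_control <= 1e-12:
            raise ValidationError(
                "control composition coincides with the planted optimum; "
                "the surface cannot be normalized"
            )
        self._d_norm = d0_control

    def _raw_distance(self, x: np.ndarray) -> float:
        z = (np.asarray(x, dtype=float) - self.optimum) / self._ranges
        d0 = float(self.curvature @ (z * z))
        for i, j, coef in self.interactions:
            d0 += coef * z[i] * z[j]
        return max(d0, 0.0)

    def distance(self, x: np.ndarray) -> float:
        """Normalized quadratic distance from θ*: 0 at θ*, 1 at the control."""
        return min(self._raw_distance(x) / self._d_norm, self.d_max)

    def surface(self, x: np.ndarray) -> float:
        """Noiseless biological signal relative to the control (RIMA scale)."""
        return float(self.max_gain ** (1.0 - self.distance(x)))

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "optimum": self.optimum.tolist(),
            "curvature": self.curvature.tolist(),
            "interactions": [list(t) for t in self.interactions],
            "baseline_rfu": self.baseline_rfu,
            "max_gain": self.max_gain,
            "background_rfu": self.background_rfu,
            "noise_sd": self.noise_sd,
            "individual_effects": self.individual_effects,
            "d_max": self.d_max,
            "control_conc": self.control_conc.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeModel":
        return cls(
            space=ParameterSpace.from_dict(d["space"]),
            optimum=np.array(d["optimum"]),
            curvature=np.array(d["curvature"]),
            interactions=tuple((int(i), int(j), float(c)) for i, j, c in d["interactions"]),
            baseline_rfu=d["baseline_rfu"],
            max_gain=d["max_gain"],
            background_rfu=d["background_rfu"],
            noise_sd=d["noise_sd"],
            individual_effects=dict(d["individual_effects"]),
            d_max=d["d_max"],
            control_conc=np.array(d["control_conc"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LandscapeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sample_landscape(
    space: ParameterSpace,
    seed: int,
    interaction_sparsity: float = 0.0,
    max_gain: float = 1.6,
    baseline_rfu: float = 1000.0,
    background_rfu: float = 100.0,
    noise_cv: float = 0.0,
    curvature_range: tuple[float, float] = (0.5, 2.0),
    interaction_scale: float = 0.3,
    individual_effects: Mapping[str, float] | None = None,
) -> LandscapeModel:
    """Draw a random landscape: on-grid optimum, log-uniform curvatures, and a
    configured fraction of pairwise interaction terms.  ``noise_cv`` sets the
    replicate SD as a fraction of the control's biological signal.

    Curvatures are drawn log-uniform over ``curvature_range`` and then scaled
    by each component's squared normalized control offset (floored at half the
    component's in-box reach).  This spreads the control-to-optimum contrast
    across components: without it, components whose basal concentration sits
    far below their optimizable range dominate the normalization and the
    surface comes out nearly flat across the design space, quite unlike the
    wide treatment-to-treatment spread the assay actually shows.
    """
    rng = np.random.default_rng(seed)
    specs = space.optimizable_specs
    optimum = np.array(
        [s.decode_index(int(rng.integers(0, s.n_steps + 1))) for s in specs]
    )
    lo, hi = curvature_range
    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(specs)))
    ranges = np.array([s.upper - s.lower for s in specs])
    lower = np.array([s.lower for s in specs])
    upper = np.array([s.upper for s in specs])
    z_ctrl = (space.basal_concentrations - optimum) / ranges
    z_box = np.maximum(np.abs(lower - optimum), np.abs(upper - optimum)) / ranges
    curvature = raw / np.maximum(z_ctrl**2, (0.5 * z_box) ** 2)
    interactions: list[tuple[int, int, float]] = []
    if interaction_sparsity > 0:
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                if rng.random() < interaction_sparsity:
                    interactions.append(
                        (i, j, float(rng.uniform(-interaction_scale, interaction_scale)))
                    )
    return LandscapeModel(
        space=space,
        optimum=optimum,
        curvature=curvature,
        interactions=tuple(interactions),
        baseline_rfu=baseline_rfu,
        max_gain=max_gain,
        background_rfu=background_rfu,
        noise_sd=noise_cv * baseline_rfu,
        individual_effects=dict(individual_effects) if individual_effects else {"I1": 1.0},
    )


def simulate_assay(
    model: LandscapeModel,
    layout_cells: PlateLayout,
    layout_cell_free: PlateLayout,
    concentrations: Mapping[str, Sequence[float]],
    rng: np.random.Generator | int,
    control_tags: Mapping[str, Sequence[float]] | None = None,
    individual_id: str | None = None,
) -> pd.DataFrame:
    """Simulate RFU readings for a paired cells / cell-free layout.

    ``concentrations`` maps treatment ids to decoded concentration vectors;
    control labels default to the model's control composition.  Cells wells
    read ``background + baseline × individual_effect × surface(x) + noise``,
    cell-free wells ``background + noise``, truncated at zero.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    known = dict(concentrations)
    controls = {"M199": model.control_conc}
    if control_tags:
        controls.update({k: np.asarray(v, dtype=float) for k, v in control_tags.items()})
    if individual_id is None:
        individual_id = next(iter(model.individual_effects))
    effect = model.individual_effects.get(individual_id, 1.0)
    rows = []
    for layout in (layout_cells, layout_cell_free):
        for well, (label, rep, role) in layout.wells.items():
            if label in known:
                x = np.asarray(known[label], dtype=float)
            elif label in controls:
                x = controls[label]
            else:
                raise ReconciliationError(
                    f"no decoded concentrations for treatment {label!r}"
                )
            signal = 0.0
            if role == "cells":
                signal = model.baseline_rfu * effect * model.surface(x)
            rfu = model.background_rfu + signal
            if model.noise_sd > 0:
                rfu += rng.normal(0.0, model.noise_sd)
            rows.append(
                {
                    "plate_id": layout.plate_id,
                    "well": well,
                    "treatment_id": label,
                    "replicate": rep,
                    "role": role,
                    "rfu": max(rfu, 0.0),
                    "individual_id": individual_id,
                }
            )
    return pd.DataFrame(rows)


def make_demo_space(
    n_components: int = 5,
    n_steps: int = 15,
    lower: float = 25.0,
    step: float = 3.125,
    basal: float | None = None,
) -> ParameterSpace:
    """A small amino-acid-like space for simulation studies.

    Defaults mirror the typical optimizable row of the packaged table: the
    lower bound equals the basal concentration and the grid step is
    3.125 µg/ml.
    """
    basal = lower if basal is None else basal
    return ParameterSpace(
        tuple(
            ParameterSpec(
                name=f"AA{i + 1}",
                basal_conc=basal,
                lower=lower,
                upper=lower + n_steps * step,
                n_steps=n_steps,
            )
            for i in range(n_components)
        )
    )


def grid_distance(conc: np.ndarray, model: LandscapeModel) -> np.ndarray:
    """Per-component distance, in grid steps, between a composition and θ*."""
    space = model.space
    return np.abs(space.grid_indices(conc) - space.grid_indices(model.optimum))


def recovery_experiment(
    space: ParameterSpace,
    config: GAConfig,
    model: LandscapeModel,
    n_generations: int,
    seed: int,
    n_replicates: int = 3,
    control_tag: str = "M199",
) -> dict:
    """Run a full simulated ask/tell campaign and report optimum recovery.

    Each generation is laid out on paired 96-well plates, simulated, scored
    (RIMA against the basal-medium control), and fed back to the optimizer.
    The report carries the per-generation best-RIMA trajectory and, for both
    the final generation's best individual and the best individual found over
    the whole campaign (the composition an experimenter would carry forward),
    the per-component grid distance to the planted optimum.
    """
    config = GAConfig(**{**config.to_dict(), "seed": seed})
    campaign = Campaign(space, config)
    assay_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA55A]))
    best_rima: list[float] = []
    for _ in range(n_generations):
        gen = campaign.ask()
        cells, cell_free = design_plates(
            gen, n_replicates=n_replicates, controls=(control_tag,)
        )
        conc = {ind.treatment_id: ind.concentrations for ind in gen.individuals}
        table = simulate_assay(model, cells, cell_free, conc, assay_rng)
        fitness = compute_fitness(table, control_tag=control_tag)
        fitness = fitness[fitness["treatment_id"] != control_tag]
        campaign.tell(fitness[["treatment_id", "fitness"]])
        best_rima.append(float(campaign.generations[-1].fitnesses.max()))
    final_best = campaign.generations[-1].best()
    best_ever = max(
        (ind for g in campaign.generations for ind in g.individuals),
        key=lambda ind: ind.fitness,
    )
    return {
        "best_rima": best_rima,
        "final_best": final_best,
        "grid_distance_final": grid_distance(final_best.concentrations, model),
        "best_ever": best_ever,
        "grid_distance": grid_distance(best_ever.concentrations, model),
        "campaign": campaign,
    }
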