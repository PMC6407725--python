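"""Binary encoding of medium-component concentration grids.

Each optimizable medium component spans a concentration range
``[lower, upper]`` (µg/ml, final medium, basal contribution included)
discretized into ``n_steps + 1`` equally spaced grid values.  A *gene* of
``b = ceil(log2(n_steps + 1))`` bits indexes this grid, most-significant bit
first; bit codes larger than ``n_steps`` (possible whenever ``2**b`` exceeds
the grid size) are clipped to the upper endpoint so every decoded
concentration lies on the printed grid.  Genes are concatenated in declared
component order to form the *chromosome*; one chromosome fully specifies a
medium composition.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ParameterSpec",
    "ParameterSpace",
    "optimal_bit_length",
    "decode_gene",
    "encode_concentration",
    "load_parameter_table",
    "builtin_space",
    "bits_to_str",
    "str_to_bits",
]

TABLE_COLUMNS = ["name", "basal_conc", "lower", "upper", "n_steps"]


def optimal_bit_length(n_steps: int) -> int:
    """Smallest ``b`` with ``2**b >= n_steps + 1`` grid values.

    A grid of ``n_steps`` steps holds ``n_steps + 1`` values including both
    endpoints, so e.g. 15 steps need 4 bits (16 codes).
    """
    n_steps = int(n_steps)
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1 for an optimizable gene, got {n_steps}")
    return n_steps.bit_length()


@dataclass(frozen=True)
class ParameterSpec:
    """One medium component: concentration bounds and its discrete grid.

    Concentrations are final-medium µg/ml and include the basal medium's own
    contribution, so ``lower >= basal_conc`` always (components can only be
    added on top of the basal medium, never removed).
    """

    name: str
    basal_conc: float
    lower: float
    upper: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError(f"{self.name}: lower {self.lower} > upper {self.upper}")
        if self.lower < self.basal_conc:
            raise ValidationError(
                f"{self.name}: lower {self.lower} below basal {self.basal_conc} "
                "(components cannot be removed from the basal medium)"
            )
        if self.n_steps < 0:
            raise ValidationError(f"{self.name}: negative n_steps {self.n_steps}")
        if self.n_steps == 0 and self.lower != self.upper:
            raise ValidationError(f"{self.name}: n_steps 0 requires lower == upper")

    @property
    def optimizable(self) -> bool:
        return self.n_steps >= 1

    @property
    def step_size(self) -> float:
        """Grid spacing in µg/ml (0 for fixed components)."""
        if not self.optimizable:
            return 0.0
        return (self.upper - self.lower) / self.n_steps

    @property
    def bit_length(self) -> int:
        return optimal_bit_length(self.n_steps) if self.optimizable else 0

    @property
    def grid(self) -> np.ndarray:
        """All ``n_steps + 1`` concentrations on the grid."""
        return self.lower + self.step_size * np.arange(self.n_steps + 1)

    def decode_index(self, index: int) -> float:
        """Concentration at grid ``index``; surplus codes clip to the upper bound."""
        return self.lower + min(int(index), self.n_steps) * self.step_size

    def encode_index(self, conc: float) -> int:
        """Nearest grid index for ``conc`` (ties round half to even)."""
        if not self.optimizable:
            raise ValidationError(f"{self.name} is not optimizable")
        if conc < self.lower - 1e-9 or conc > self.upper + 1e-9:
            raise ValidationError(
                f"{self.name}: concentration {conc} outside [{self.lower}, {self.upper}]"
            )
        idx = int(np.round((conc - self.lower) / self.step_size))
        return min(max(idx, 0), self.n_steps)


def bits_to_str(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in np.asarray(bits, dtype=np.uint8))


def str_to_bits(s: str) -> np.ndarray:
    if not set(s) <= {"0", "1"}:
        raise ValidationError(f"not a bit string: {s!r}")
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def decode_gene(bits: Sequence[int] | np.ndarray, spec: ParameterSpec) -> float:
    """Map a gene's bits (MSB first) to a concentration in µg/ml."""
    bits = np.asarray(bits, dtype=np.uint8)
    if not spec.optimizable:
        raise ValidationError(f"{spec.name} carries no gene")
    if bits.size != spec.bit_length:
        raise ValidationError(
            f"{spec.name}: expected {spec.bit_length} bits, got {bits.size}"
        )
    value = int(bits @ (1 << np.arange(bits.size - 1, -1, -1)))
    return spec.decode_index(value)


def encode_concentration(conc: float, spec: ParameterSpec) -> np.ndarray:
    """Bits (MSB first) of the grid index nearest to ``conc``."""
    idx = spec.encode_index(conc)
    return np.array(
        [(idx >> k) & 1 for k in range(spec.bit_length - 1, -1, -1)], dtype=np.uint8
    )


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of component specs defining the chromosome layout."""

    specs: tuple[ParameterSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate component names in parameter space")

    @property
    def optimizable_specs(self) -> tuple[ParameterSpec, ...]:
        return tuple(s for s in self.specs if s.optimizable)

    @property
    def chromosome_length(self) -> int:
        return sum(s.bit_length for s in self.optimizable_specs)

    @property
    def gene_offsets(self) -> tuple[tuple[int, int], ...]:
        """Per optimizable spec: (start, length) within the chromosome."""
        offsets, start = [], 0
        for s in self.optimizable_specs:
            offsets.append((start, s.bit_length))
            start += s.bit_length
        return tuple(offsets)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.optimizable_specs)

    @property
    def basal_concentrations(self) -> np.ndarray:
        """Basal-medium concentration of each optimizable component."""
        return np.array([s.basal_conc for s in self.optimizable_specs])

    def decode_chromosome(self, chromosome: np.ndarray) -> np.ndarray:
        """Concentration vector (µg/ml) of the optimizable components."""
        chromosome = np.asarray(chromosome, dtype=np.uint8)
        if chromosome.size != self.chromosome_length:
            raise ValidationError(
                f"chromosome has {chromosome.size} bits, expected {self.chromosome_length}"
            )
        return np.array(
            [
                decode_gene(chromosome[start : start + length], spec)
                for (start, length), spec in zip(self.gene_offsets, self.optimizable_specs)
            ]
        )

    def encode_concentrations(self, concentrations: Sequence[float]) -> np.ndarray:
        """Chromosome of the nearest on-grid composition."""
        concentrations = np.asarray(concentrations, dtype=float)
        if concentrations.size != len(self.optimizable_specs):
            raise ValidationError("one concentration per optimizable component required")
        return np.concatenate(
            [encode_concentration(c, s) for c, s in zip(concentrations, self.optimizable_specs)]
        )

    def grid_indices(self, concentrations: Sequence[float]) -> np.ndarray:
        """Nearest grid index of each component's concentration."""
        return np.array(
            [s.encode_index(c) for c, s in zip(concentrations, self.optimizable_specs)]
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "specs": [
                {
                    "name": s.name,
                    "basal_conc": s.basal_conc,
                    "lower": s.lower,
                    "upper": s.upper,
                    "n_steps": s.n_steps,
                    "bit_length": s.bit_length,
                }
                for s in self.specs
            ],
            "chromosome_length": self.chromosome_length,
            "gene_offsets": [list(o) for o in self.gene_offsets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(
            tuple(
                ParameterSpec(
                    name=s["name"],
                    basal_conc=float(s["basal_conc"]),
                    lower=float(s["lower"]),
                    upper=float(s["upper"]),
                    n_steps=int(s["n_steps"]),
                )
                for s in d["specs"]
            )
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSpace":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_parameter_table(path: str | Path | io.IOBase) -> ParameterSpace:
    """Read a component-range CSV (``name,basal_conc,lower,upper,n_steps``).

    Lines starting with ``#`` are comments.  Rows with ``n_steps = 0`` are
    retained as fixed (non-optimizable) components.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse parameter table: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing columns: {missing}")
    specs = []
    for _, row in df.iterrows():
        try:
            specs.append(
                ParameterSpec(
                    name=str(row["name"]),
                    basal_conc=float(row["basal_conc"]),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    n_steps=int(row["n_steps"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {row['name']!r}: {exc}") from exc
    return ParameterSpace(tuple(specs))


def builtin_space() -> ParameterSpace:
    """The packaged 22-component amino-acid space (20 optimizable genes)."""
    ref = resources.files("evomedia.data").joinpath("sponge_aa_ranges.csv")
    with resources.as_file(ref) as path:
        return load_parameter_table(path)
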