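"""Fitness scoring and statistics for plate-reader fluorescence tables.

The raw readout is fluorescence (RFU) from a resazurin-reduction metabolic
assay measured on two paired plates: one with cells, one cell-free background
plate with the identical treatment map.  Scoring proceeds replicate-wise:

1. net RFU = cells RFU − matching cell-free RFU (background subtraction,
   paired by replicate index);
2. per-treatment mean and SD of net RFU over replicates;
3. RIMA (relative increase in metabolic activity) = treatment mean net RFU
   divided by the basal-medium control's mean net RFU.  RIMA > 1 means the
   composition outperformed the unmodified basal medium.

Subtracting first and dividing second makes RIMA background-free and
invariant to any common rescaling of the reader's gain.  Each treatment is
compared with the control by a two-sided equal-variance (Student's) t test on
the net replicate values, uncorrected for multiple testing.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import ParameterSpace
from .errors import ReconciliationError, StateError, ValidationError

__all__ = [
    "ASSAY_COLUMNS",
    "validate_assay_table",
    "net_replicates",
    "compare_to_control",
    "compute_fitness",
    "anova_across_individuals",
    "improvement_summary",
    "convergence_report",
]

ASSAY_COLUMNS = ["plate_id", "well", "treatment_id", "replicate", "role", "rfu"]
ALPHA = 0.05


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the assay table schema and basic invariants; returns the table."""
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"assay table missing columns: {missing}")
    rfu = pd.to_numeric(table["rfu"], errors="coerce")
    if rfu.isna().any() or np.isinf(rfu).any():
        raise ValidationError("assay table contains non-finite RFU values")
    if (rfu < 0).any():
        raise ValidationError("assay table contains negative RFU values")
    bad_roles = set(table["role"].unique()) - {"cells", "cell_free"}
    if bad_roles:
        raise ValidationError(f"unknown roles in assay table: {sorted(bad_roles)}")
    return table


def net_replicates(table: pd.DataFrame, treatment_id: str) -> np.ndarray:
    """Per-replicate background-subtracted RFU for one treatment.

    Replicates are paired across the cells and cell-free plates by replicate
    index; replicates present in only one role are dropped with a warning.
    """
    sub = table[table["treatment_id"] == treatment_id]
    if sub.empty:
        raise ReconciliationError(f"treatment {treatment_id!r} absent from assay table")
    wide = sub.pivot_table(index="replicate", columns="role", values="rfu", aggfunc="mean")
    for role in ("cells", "cell_free"):
        if role not in wide.columns:
            raise ReconciliationError(
                f"treatment {treatment_id!r} has no {role!r} wells"
            )
    unmatched = wide.index[wide.isna().any(axis=1)]
    if len(unmatched):
        warnings.warn(
            f"treatment {treatment_id!r}: dropping unmatched replicates {list(unmatched)}",
            stacklevel=2,
        )
        wide = wide.dropna()
    return (wide["cells"] - wide["cell_free"]).to_numpy(dtype=float)


def compare_to_control(
    treatment_nets: np.ndarray, control_nets: np.ndarray
) -> tuple[float, float]:
    """Two-sided equal-variance t test of net RFU replicates; returns (t, p).

    Zero pooled variance (possible for noiseless simulated data) is handled
    explicitly: equal means give (0, 1), unequal means (±inf, 0).
    """
    a = np.asarray(treatment_nets, dtype=float)
    b = np.asarray(control_nets, dtype=float)
    if _degenerate(a) and _degenerate(b):
        if np.isclose(a.mean(), b.mean(), rtol=1e-9, atol=1e-12):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _degenerate(x: np.ndarray) -> bool:
    # variance indistinguishable from float round-off on this scale
    return x.var(ddof=1) <= (1e-9 * max(1.0, abs(float(x.mean())))) ** 2


def compute_fitness(
    table: pd.DataFrame, control_tag: str = "M199", correction: str | None = None
) -> pd.DataFrame:
    """Score every treatment in an assay table against the basal-medium control.

    Returns one row per treatment (control included) with columns
    ``treatment_id, fitness, fitness_sd, n_replicates, mean_net_rfu,
    sd_net_rfu, rima, rima_sd, p_value, significant``.  ``fitness`` is RIMA
    floored at zero, the value fed to the genetic algorithm; the control's
    RIMA is exactly 1 with ``p_value`` 1 by convention.

    Significance calls are uncorrected by default (each treatment-vs-control
    comparison stands alone, as is conventional for this assay);
    ``correction="bh"`` applies a Benjamini-Hochberg false-discovery-rate
    adjustment across the non-control treatments before thresholding.
    """
    if correction not in (None, "bh"):
        raise ValidationError(f"unknown multiple-testing correction {correction!r}")
    table = validate_assay_table(table)
    treatments = list(dict.fromkeys(table["treatment_id"].astype(str)))
    if control_tag not in treatments:
        raise ReconciliationError(f"control {control_tag!r} absent from assay table")
    control_nets = net_replicates(table, control_tag)
    if control_nets.size < 2:
        raise ValidationError(f"control {control_tag!r} needs >= 2 matched replicates")
    control_mean = control_nets.mean()
    if control_mean <= 0:
        raise ValidationError(
            f"control mean net RFU is {control_mean:.3g} <= 0; RIMA undefined"
        )
    rows = []
    for tid in treatments:
        nets = net_replicates(table, tid)
        mean_net = nets.mean()
        sd_net = nets.std(ddof=1) if nets.size > 1 else np.nan
        if tid == control_tag:
            rima, p = 1.0, 1.0
        else:
            rima = mean_net / control_mean
            _, p = compare_to_control(nets, control_nets)
        rima_sd = sd_net / control_mean
        rows.append(
            {
                "treatment_id": tid,
                "fitness": max(rima, 0.0),
                "fitness_sd": rima_sd,
                "n_replicates": int(nets.size),
                "mean_net_rfu": mean_net,
                "sd_net_rfu": sd_net,
                "rima": rima,
                "rima_sd": rima_sd,
                "p_value": p,
                "significant": bool(p < ALPHA) and tid != control_tag,
            }
        )
    out = pd.DataFrame(rows)
    if correction == "bh":
        mask = out["treatment_id"] != control_tag
        adjusted = stats.false_discovery_control(out.loc[mask, "p_value"], method="bh")
        out.loc[mask, "significant"] = adjusted < ALPHA
    return out


def anova_across_individuals(
    table: pd.DataFrame, treatment_id: str, individual_col: str = "individual_id"
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of net RFU across biological individuals.

    Used to ask whether cells sourced from different animals respond
    differently to the same medium composition.  Returns (F, p).
    """
    if individual_col not in table.columns:
        raise ValidationError(f"assay table has no {individual_col!r} column")
    groups = []
    for _, sub in table.groupby(individual_col, sort=True):
        nets = net_replicates(sub, treatment_id)
        if nets.size >= 2:
            groups.append(nets)
    if len(groups) < 2:
        raise ValidationError(
            f"ANOVA for {treatment_id!r} needs >= 2 individuals with >= 2 replicates"
        )
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0.0:
        # no variation at all: no evidence of group differences
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def improvement_summary(
    fitness: pd.DataFrame, control_tag: str = "M199"
) -> tuple[int, int]:
    """(n_improved, n_significant): treatments with RIMA > 1, and of those,
    the ones significantly different from the control at α = 0.05."""
    sub = fitness[fitness["treatment_id"] != control_tag]
    improved = sub["rima"] > 1.0
    significant = improved & (sub["p_value"] < ALPHA)
    return int(improved.sum()), int(significant.sum())


def convergence_report(
    generations: Sequence,
    space: ParameterSpace,
    top_k: int = 1,
    bottom_k: int = 1,
) -> dict:
    """Convergence diagnostics across scored generations.

    For every optimizable component: the concentrations of the ``top_k`` and
    ``bottom_k`` treatments per generation (against the component's allowed
    range), the min–max envelope width of the top set per generation, and the
    Pearson correlation between the component's concentration and fitness
    pooled over all scored treatments.  A shrinking top envelope indicates
    convergence on an optimal concentration; a strong per-component
    correlation flags a component that drives the response on its own.
    """
    scored = [g for g in generations]
    if len(scored) < 2:
        raise StateError("convergence report needs >= 2 scored generations")
    for g in scored:
        if not g.scored:
            raise StateError(f"generation {g.index} is not fully scored")
    names = space.component_names
    all_conc = np.vstack(
        [ind.concentrations for g in scored for ind in g.individuals]
    )
    all_fit = np.array([ind.fitness for g in scored for ind in g.individuals])
    report: dict = {"components": {}, "generations": [g.index for g in scored]}
    for j, (name, spec) in enumerate(zip(names, space.optimizable_specs)):
        per_gen = []
        for g in scored:
            order = np.argsort(-g.fitnesses)
            top = [float(g.individuals[i].concentrations[j]) for i in order[:top_k]]
            bottom = [float(g.individuals[i].concentrations[j]) for i in order[::-1][:bottom_k]]
            per_gen.append(
                {
                    "generation": g.index,
                    "top": top,
                    "bottom": bottom,
                    "top_envelope_width": float(max(top) - min(top)),
                }
            )
        if np.ptp(all_conc[:, j]) > 0 and np.ptp(all_fit) > 0:
            r, _ = stats.pearsonr(all_conc[:, j], all_fit)
        else:
            r = np.nan
        report["components"][name] = {
            "lower": spec.lower,
            "upper": spec.upper,
            "per_generation": per_gen,
            "fitness_correlation": float(r) if np.isfinite(r) else None,
        }
    return report
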