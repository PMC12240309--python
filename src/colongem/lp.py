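"""Linear-programming core: FBA, FVA, exchange classification, knockouts.

All solves go through HiGHS (``scipy.optimize.linprog``). Flux balance
analysis maximizes c·v subject to S·v = 0 and lb <= v <= ub; flux
variability analysis additionally constrains the objective to a fraction of
its optimum and minimizes/maximizes each reaction flux in turn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .core import (
    MetabolicModel,
    StoichiometricSystem,
    build_system,
    evaluate_gpr,
)

logger = logging.getLogger("colongem")

#: Numerical tolerance for feasibility and direction classification.
DEFAULT_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """FVA interval for one reaction."""

    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class KnockoutRecord:
    """Effect of a single-gene knockout on a target flux maximum."""

    gene_id: str
    wt_flux: float
    ko_flux: float
    ratio: float | None  # (wt - ko) / wt; None when wt == 0 (undefined)

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def _solve_lp(
    system: StoichiometricSystem,
    c: np.ndarray,
    maximize: bool = True,
    extra_A_ub: np.ndarray | None = None,
    extra_b_ub: np.ndarray | None = None,
):
    res = linprog(
        -c if maximize else c,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        A_eq=system.S,
        b_eq=np.zeros(system.S.shape[0]),
        bounds=list(zip(system.lb, system.ub)),
        method="highs",
    )
    return res


def optimize(
    model: MetabolicModel,
    objective: dict[str, float] | None = None,
    system: StoichiometricSystem | None = None,
) -> FluxSolution:
    """Flux balance analysis: maximize the objective at steady state.

    Infeasible or unbounded problems surface through ``status``, never as
    exceptions. Validation errors (lb > ub, dangling references) do raise.
    """
    sys_ = system if system is not None else build_system(model)
    c = sys_.c.copy()
    if objective is not None:
        c[:] = 0.0
        for rid, w in objective.items():
            c[sys_.col_index[rid]] = w
    res = _solve_lp(sys_, c, maximize=True)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=math.nan, fluxes={})
    fluxes = {rid: float(res.x[j]) for rid, j in sys_.col_index.items()}
    return FluxSolution(status="optimal", objective_value=float(c @ res.x), fluxes=fluxes)


def fva(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    fraction_of_optimum: float = 0.0,
    system: StoichiometricSystem | None = None,
) -> list[FluxRange]:
    """Flux variability analysis: per-reaction min/max attainable flux.

    With ``fraction_of_optimum`` > 0, the objective value is first maximized
    and the constraint c·v >= fraction * optimum is imposed (two LPs per
    reaction thereafter).
    """
    sys_ = system if system is not None else build_system(model)
    rxns = list(model.reactions) if reactions is None else list(reactions)
    for rid in rxns:
        if rid not in sys_.col_index:
            raise KeyError(f"unknown reaction {rid!r}")

    A_ub = b_ub = None
    if fraction_of_optimum > 0 and np.any(sys_.c):
        base = _solve_lp(sys_, sys_.c, maximize=True)
        if base.status != 0:
            raise RuntimeError(
                f"base model not solvable for FVA (status {_STATUS.get(base.status)})"
            )
        opt = float(sys_.c @ base.x)
        A_ub = -sys_.c.reshape(1, -1)
        b_ub = np.array([-fraction_of_optimum * opt])

    out = []
    n = len(sys_.lb)
    for rid in rxns:
        j = sys_.col_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve_lp(sys_, c, maximize=False, extra_A_ub=A_ub, extra_b_ub=b_ub)
        hi = _solve_lp(sys_, c, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem failed for reaction {rid!r}")
        out.append(FluxRange(rid, float(lo.x[j]), float(hi.x[j])))
    return out


def fva_max(
    model: MetabolicModel,
    reaction: str,
    fraction_of_optimum: float = 0.0,
    system: StoichiometricSystem | None = None,
) -> float:
    """Maximum attainable flux of one reaction (single LP)."""
    sys_ = system if system is not None else build_system(model)
    A_ub = b_ub = None
    if fraction_of_optimum > 0 and np.any(sys_.c):
        base = _solve_lp(sys_, sys_.c, maximize=True)
        if base.status != 0:
            raise RuntimeError("base model not solvable")
        A_ub = -sys_.c.reshape(1, -1)
        b_ub = np.array([-fraction_of_optimum * float(sys_.c @ base.x)])
    j = sys_.col_index[reaction]
    c = np.zeros(len(sys_.lb))
    c[j] = 1.0
    res = _solve_lp(sys_, c, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
    if res.status != 0:
        raise RuntimeError(f"FVA max failed for {reaction!r}")
    return float(res.x[j])


def classify_exchange(rng: FluxRange, tol: float = DEFAULT_TOL) -> str:
    """Classify an exchange FVA interval into a transport direction.

    Negative minimum flux = the network can take the metabolite up; positive
    maximum flux = it can secrete it.
    """
    can_uptake = rng.min_flux < -tol
    can_secrete = rng.max_flux > tol
    if can_uptake and can_secrete:
        return "both"
    if can_uptake:
        return "uptake_only"
    if can_secrete:
        return "secretion_only"
    return "inactive"


def delete_genes(
    model: MetabolicModel, genes, inplace: bool = False
) -> MetabolicModel:
    """Force bounds to [0, 0] for every reaction whose GPR turns off when the
    listed genes are deleted. The input model is untouched unless ``inplace``."""
    genes = set(genes)
    unknown = genes - model.genes
    if unknown:
        logger.warning("delete_genes: ignoring unknown gene ids %s", sorted(unknown))
    out = model if inplace else model.copy()
    states = {g: (g not in genes) for g in out.genes}
    for rxn in out.reactions.values():
        if rxn.gpr and not evaluate_gpr(rxn.gpr, states):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def knockout_screen(
    model: MetabolicModel,
    genes: list[str] | None = None,
    target_reaction: str | None = None,
    fraction_of_optimum: float = 0.0,
) -> list[KnockoutRecord]:
    """Single-gene deletion screen against the maximum flux of a target.

    The wild-type value is the FVA maximum of the target reaction on the
    intact model; each knockout repeats the measurement with the gene's
    dependent reactions disabled. The reported effect is (WT - KO) / WT,
    undefined (None) when WT is zero. An infeasible knockout model counts as
    complete loss (KO flux 0).
    """
    if target_reaction is None:
        if len(model.objective) != 1:
            raise ValueError("target_reaction required when objective is not unique")
        target_reaction = next(iter(model.objective))
    if target_reaction not in model.reactions:
        raise KeyError(f"unknown target reaction {target_reaction!r}")
    gene_list = sorted(model.genes) if genes is None else list(genes)
    wt = fva_max(model, target_reaction, fraction_of_optimum)
    records = []
    for gene in gene_list:
        ko_model = delete_genes(model, {gene})
        try:
            ko = fva_max(ko_model, target_reaction, fraction_of_optimum)
        except RuntimeError:
            ko = 0.0  # infeasible knockout: complete loss
        if abs(wt) <= DEFAULT_TOL:
            ratio = None
        else:
            ratio = (wt - ko) / wt
            if -DEFAULT_TOL < ratio < 0:
                ratio = 0.0
        records.append(KnockoutRecord(gene, wt, ko, ratio))
    return records


def find_blocked(model: MetabolicModel, tol: float = DEFAULT_TOL) -> list[str]:
    """Reactions that cannot carry flux anywhere in the polytope.

    A reaction is blocked when both its FVA minimum and maximum (no objective
    constraint) are within ``tol`` of zero. Because a blocked reaction's flux
    is identically zero, removing blocked reactions never changes the
    variability of the remainder, so one pass reaches the fixpoint.
    """
    system = build_system(model)
    ranges = fva(model, fraction_of_optimum=0.0, system=system)
    return [
        r.reaction_id
        for r in ranges
        if abs(r.min_flux) < tol and abs(r.max_flux) < tol
    ]


def prune_blocked(model: MetabolicModel, tol: float = DEFAULT_TOL) -> MetabolicModel:
    """Return a copy with blocked reactions removed (flux-consistent model)."""
    blocked = set(find_blocked(model, tol))
    keep = [rid for rid in model.reactions if rid not in blocked]
    return model.subset(keep)


def ranges_to_frame(ranges: list[FluxRange]):
    """Export FVA results as a pandas DataFrame (reaction_id, min, max)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.reaction_id, r.min_flux, r.max_flux) for r in ranges],
        columns=["reaction_id", "min", "max"],
    )


def knockouts_to_frame(records: list[KnockoutRecord]):
    """Export knockout records as a pandas DataFrame (gene, wt, ko, ratio)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.gene_id, r.wt_flux, r.ko_flux, r.ratio) for r in records],
        columns=["gene", "wt", "ko", "ratio"],
    )
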