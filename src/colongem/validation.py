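"""Metabolic-task feasibility protocol and model sanity checks.

A metabolic task asks whether the network can synthesize stated products
from stated substrates. The protocol closes the model (all exchange and sink
lower bounds to 0), opens each task input at an uptake bound of 1, adds a
sink for each product and maximizes it; the task passes when every product
sink achieves a flux above threshold.

Sanity checks mirror the standard reconstruction quality battery: a leak
test (nothing producible from a fully closed network), energy-from-water
tests (no ATP out of thin air, with or without oxygen, including the
reversed-ATP-demand variant) and flux consistency (no blocked reactions).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import MetabolicModel, Metabolite, Reaction, split_met_id
from .lp import DEFAULT_TOL, find_blocked, optimize

logger = logging.getLogger("colongem")

#: A task product must exceed this flux to count as achieved.
DEFAULT_PASS_THRESHOLD = 1e-6

#: Uptake bound granted to each task input (exchange/sink lower bound).
TASK_INPUT_BOUND = 1.0


@dataclass
class MetabolicTask:
    """Feasibility query: can the network turn `inputs` into each `output`?"""

    id: str
    description: str = ""
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    pass_threshold: float = DEFAULT_PASS_THRESHOLD

    def __post_init__(self):
        if not self.outputs:
            raise ValueError(f"task {self.id}: outputs must be non-empty")


@dataclass
class TaskResult:
    task_id: str
    passed: bool
    achieved_flux: float
    reason: str  # ok | infeasible | unmappable

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "passed": self.passed,
            "achieved_flux": self.achieved_flux,
            "reason": self.reason,
        }


def _close_boundary(model: MetabolicModel) -> None:
    """Set lower bounds of all exchange and sink reactions to 0 in place."""
    for rxn in model.reactions.values():
        if rxn.kind in ("exchange", "sink"):
            rxn.lower_bound = max(rxn.lower_bound, 0.0)


def run_task(model: MetabolicModel, task: MetabolicTask) -> TaskResult:
    """Run one metabolic task on a pristine copy of the model.

    Multi-output tasks must achieve each product individually (one sink per
    product, maximized in sequence). The input model is never mutated.
    """
    for met_id in task.inputs + task.outputs:
        if met_id not in model.metabolites:
            return TaskResult(task.id, False, 0.0, "unmappable")

    work = model.copy()
    _close_boundary(work)

    for met_id in task.inputs:
        boundary = work.boundary_for(met_id)
        if boundary is not None and boundary.kind in ("exchange", "sink"):
            boundary.lower_bound = -TASK_INPUT_BOUND
        else:
            # grant supply through a dedicated sink when the metabolite has
            # no boundary reaction of its own
            work.add_reaction(
                Reaction(
                    f"TASK_SUPPLY_{met_id}",
                    stoichiometry={met_id: -1.0},
                    lower_bound=-TASK_INPUT_BOUND,
                    upper_bound=0.0,
                    kind="sink" if split_met_id(met_id)[1] not in ("e", "lu") else "exchange",
                )
            )

    min_flux = float("inf")
    for met_id in task.outputs:
        probe = work.copy()
        sink_id = f"TASK_SINK_{met_id}"
        if sink_id not in probe.reactions:
            probe.add_reaction(
                Reaction(
                    sink_id,
                    stoichiometry={met_id: -1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    kind="demand" if split_met_id(met_id)[1] not in ("e", "lu") else "exchange",
                )
            )
        sol = optimize(probe, objective={sink_id: 1.0})
        flux = sol.objective_value if sol.optimal else 0.0
        min_flux = min(min_flux, flux)
        if not sol.optimal or flux <= task.pass_threshold:
            return TaskResult(task.id, False, flux if sol.optimal else 0.0, "infeasible")
    return TaskResult(task.id, True, min_flux, "ok")


@dataclass
class TaskSuiteReport:
    results: list[TaskResult]

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.results)

    @property
    def pass_fraction(self) -> float:
        return self.n_passed / len(self.results)

    @property
    def pass_percent(self) -> float:
        return 100.0 * self.pass_fraction

    def to_dict(self) -> dict:
        return {
            "n_tasks": len(self.results),
            "n_passed": self.n_passed,
            "pass_percent": self.pass_percent,
            "results": [r.to_dict() for r in self.results],
        }


def run_task_suite(model: MetabolicModel, tasks: list[MetabolicTask]) -> TaskSuiteReport:
    """Run every task independently from a pristine model copy."""
    if not tasks:
        raise ValueError("no tasks")
    return TaskSuiteReport([run_task(model, task) for task in tasks])


# ---------------------------------------------------------------------------
# Sanity checks
# ---------------------------------------------------------------------------


def _close_all_boundary(model: MetabolicModel) -> None:
    """Close demand, sink and exchange reactions entirely (both directions)."""
    for rxn in model.reactions.values():
        if rxn.is_boundary:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0


def leak_test(model: MetabolicModel, tol: float = DEFAULT_TOL) -> list[str]:
    """Metabolites producible from nothing in the fully closed network.

    With every boundary reaction closed, each metabolite in turn receives a
    temporary demand; any demand able to carry flux above ``tol`` marks a
    stoichiometric leak (mass created from nothing).
    """
    closed = model.copy()
    _close_all_boundary(closed)
    leaking = []
    for met_id in closed.metabolites:
        probe = closed.copy()
        probe.add_reaction(
            Reaction(
                f"LEAK_DM_{met_id}",
                stoichiometry={met_id: -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="demand" if split_met_id(met_id)[1] not in ("e", "lu") else "exchange",
            )
        )
        sol = optimize(probe, objective={f"LEAK_DM_{met_id}": 1.0})
        if sol.optimal and sol.objective_value > tol:
            leaking.append(met_id)
    return leaking


def _find_atp_demand(model: MetabolicModel) -> str:
    """Locate the ATP-hydrolysis demand (ATP + H2O -> ADP + Pi [+ H])."""
    for rid, rxn in model.reactions.items():
        if rid.upper() in ("ATPM", "DM_ATP_C_", "DM_ATP[C]"):
            return rid
    for rid, rxn in model.reactions.items():
        consumed = {split_met_id(m)[0].lower() for m, c in rxn.stoichiometry.items() if c < 0}
        produced = {split_met_id(m)[0].lower() for m, c in rxn.stoichiometry.items() if c > 0}
        if {"atp", "h2o"} <= consumed and {"adp", "pi"} <= produced and len(consumed) == 2:
            return rid
    raise ValueError("model declares no ATP-hydrolysis demand reaction")


@dataclass
class EnergyTestResult:
    passed: bool
    max_atp_flux: float
    reversed_demand_leaks: list[str]
    allow_oxygen: bool


def energy_from_water_test(
    model: MetabolicModel,
    allow_oxygen: bool = False,
    atp_demand: str | None = None,
    tol: float = DEFAULT_TOL,
) -> EnergyTestResult:
    """Check that no ATP can be generated from water (optionally + oxygen).

    Everything is closed except the water (and optionally oxygen) exchanges,
    then the ATP-hydrolysis demand is maximized; the test passes when the
    optimum stays at zero. A second variant reverses the ATP demand and
    reruns the leak test, catching networks that fabricate metabolites once
    ATP is freely regenerated.
    """
    atp_demand = atp_demand or _find_atp_demand(model)
    closed = model.copy()
    _close_all_boundary(closed)
    open_bases = {"h2o"} | ({"o2"} if allow_oxygen else set())
    for rxn in closed.reactions.values():
        if rxn.kind == "exchange":
            base = split_met_id(rxn.boundary_metabolite)[0].lower()
            if base in open_bases:
                rxn.lower_bound = -1000.0
                rxn.upper_bound = 1000.0
    closed.reactions[atp_demand].upper_bound = 1000.0
    closed.reactions[atp_demand].lower_bound = 0.0
    sol = optimize(closed, objective={atp_demand: 1.0})
    max_atp = sol.objective_value if sol.optimal else 0.0

    reversed_model = model.copy()
    rev = reversed_model.reactions[atp_demand]
    rev.lower_bound, rev.upper_bound = -1000.0, 0.0
    # only leaks *introduced* by the reversed demand count against the
    # energy test; pre-existing leaks belong to the leak test proper
    baseline = set(leak_test(model, tol=tol))
    rev_leaks = sorted(set(leak_test(reversed_model, tol=tol)) - baseline)

    return EnergyTestResult(
        passed=(max_atp <= tol and not rev_leaks),
        max_atp_flux=max_atp,
        reversed_demand_leaks=rev_leaks,
        allow_oxygen=allow_oxygen,
    )


def sanity_report(
    model: MetabolicModel,
    tasks: list[MetabolicTask] | None = None,
    tol: float = DEFAULT_TOL,
) -> dict:
    """Aggregate leak, energy, flux-consistency and task checks.

    Returns a JSON-serializable report with a top-level ``all_passed`` flag.
    """
    leaks = leak_test(model, tol=tol)
    try:
        energy = energy_from_water_test(model, allow_oxygen=False, tol=tol)
        energy_o2 = energy_from_water_test(model, allow_oxygen=True, tol=tol)
        energy_section = {
            "water_only": {"passed": energy.passed, "max_atp_flux": energy.max_atp_flux,
                           "reversed_demand_leaks": energy.reversed_demand_leaks},
            "water_and_oxygen": {"passed": energy_o2.passed,
                                 "max_atp_flux": energy_o2.max_atp_flux,
                                 "reversed_demand_leaks": energy_o2.reversed_demand_leaks},
            "passed": energy.passed and energy_o2.passed,
        }
    except ValueError as exc:
        energy_section = {"passed": False, "error": str(exc)}
    blocked = find_blocked(model, tol=tol)
    report = {
        "model_id": model.id,
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
        "leak_test": {"passed": not leaks, "leaking_metabolites": leaks},
        "energy_tests": energy_section,
        "flux_consistency": {"passed": not blocked, "blocked_reactions": blocked},
    }
    if tasks:
        suite = run_task_suite(model, tasks)
        report["tasks"] = suite.to_dict()
    report["all_passed"] = all(
        section.get("passed", True)
        for key, section in report.items()
        if isinstance(section, dict) and key != "tasks"
    )
    return report


# ---------------------------------------------------------------------------
# Task file I/O (task_id, description, inputs ;-list, outputs ;-list)
# ---------------------------------------------------------------------------


def load_tasks(path) -> list[MetabolicTask]:
    """Read a task list from TSV (semicolon-separated input/output columns)
    or JSON."""
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [
            MetabolicTask(
                t["id"],
                description=t.get("description", ""),
                inputs=list(t.get("inputs", [])),
                outputs=list(t["outputs"]),
                pass_threshold=float(t.get("pass_threshold", DEFAULT_PASS_THRESHOLD)),
            )
            for t in data
        ]
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    tasks = []
    for _, row in df.iterrows():
        tasks.append(
            MetabolicTask(
                row["task_id"],
                description=row.get("description", ""),
                inputs=[m for m in row.get("inputs", "").split(";") if m],
                outputs=[m for m in row["outputs"].split(";") if m],
            )
        )
    return tasks


def write_tasks(tasks: list[MetabolicTask], path) -> Path:
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(
                [
                    {
                        "id": t.id,
                        "description": t.description,
                        "inputs": t.inputs,
                        "outputs": t.outputs,
                    }
                    for t in tasks
                ],
                indent=1,
            )
            + "\n"
        )
        return path
    pd.DataFrame(
        [
            {
                "task_id": t.id,
                "description": t.description,
                "inputs": ";".join(t.inputs),
                "outputs": ";".join(t.outputs),
            }
            for t in tasks
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
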