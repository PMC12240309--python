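"""Expression preprocessing and iMAT context-specific model extraction.

The preprocessing chain mirrors the standard context-extraction recipe:
a percentile cutoff over all expression values (default 30th), per-gene
ubiquity scores (fraction of samples above cutoff), log2 gene activity
(median across samples, zeroed below cutoff), and GPR-folded reaction
scores (AND -> min, OR -> max). Reactions split into a high set (score
above the median of non-zero scores) and a low set (score zero with a
non-empty GPR); iMAT then solves a MILP rewarding flux through high
reactions and silence of low reactions, and the context model keeps the
agreeing reactions plus everything unscored, pruned to flux consistency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from .core import MetabolicModel, build_system, score_gpr
from .lp import DEFAULT_TOL, prune_blocked

logger = logging.getLogger("colongem")

DEFAULT_PERCENTILE = 30.0
DEFAULT_EPS = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional group labels."""

    values: pd.DataFrame  # rows = genes, columns = samples
    groups: dict[str, str] = field(default_factory=dict)  # sample -> label

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        for sample in self.groups:
            if sample not in self.values.columns:
                raise ValueError(f"group label for unknown sample {sample!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_column(self, sample: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[[sample]], groups={})


def load_expression(values_path, groups_path=None) -> ExpressionMatrix:
    """Read a gene x sample TSV (and an optional sample/group sidecar TSV)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
        groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return ExpressionMatrix(values, groups)


def expression_cutoff(matrix: ExpressionMatrix, percentile: float = DEFAULT_PERCENTILE) -> float:
    """Linear-interpolation percentile over all matrix entries.

    Uses the rank convention ``rank = 1 + (p/100)(n-1)`` on the sorted
    values, i.e. numpy's linear interpolation.
    """
    vals = matrix.values.to_numpy().ravel()
    if vals.size == 0:
        raise ValueError("empty expression matrix")
    return float(np.percentile(vals, percentile, method="linear"))


def ubiquity_scores(matrix: ExpressionMatrix, cutoff: float) -> pd.Series:
    """Per-gene fraction of samples strictly above the cutoff."""
    above = matrix.values.gt(cutoff)
    return above.sum(axis=1) / matrix.values.shape[1]


def gene_activity(
    matrix: ExpressionMatrix, cutoff: float, aggregate: str = "median"
) -> pd.Series:
    """Per-gene activity: aggregate across samples, zero below cutoff, log2 above.

    Values equal to the cutoff count as expressed. Activities are clipped at
    zero so an expressed gene never scores below an unexpressed one.
    """
    if aggregate == "median":
        agg = matrix.values.median(axis=1)
    elif aggregate == "mean":
        agg = matrix.values.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    out = pd.Series(0.0, index=agg.index)
    expressed = agg >= cutoff
    out[expressed] = np.log2(agg[expressed]).clip(lower=0.0)
    return out


@dataclass
class GeneScoreSet:
    cutoff: float
    ubiquity: pd.Series
    activity: pd.Series


def gene_scores(
    matrix: ExpressionMatrix,
    percentile: float = DEFAULT_PERCENTILE,
    aggregate: str = "median",
) -> GeneScoreSet:
    """Convenience bundle: cutoff + ubiquity + activity in one pass."""
    cutoff = expression_cutoff(matrix, percentile)
    return GeneScoreSet(
        cutoff=cutoff,
        ubiquity=ubiquity_scores(matrix, cutoff),
        activity=gene_activity(matrix, cutoff, aggregate),
    )


@dataclass
class ReactionScoreSet:
    """GPR-folded reaction scores and the derived iMAT high/low partition."""

    scores: dict[str, float]  # only reactions with a non-empty GPR
    high_set: set[str]
    low_set: set[str]
    high_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    rid,
                    s,
                    "high" if rid in self.high_set else ("low" if rid in self.low_set else "mid"),
                )
                for rid, s in sorted(self.scores.items())
            ],
            columns=["reaction_id", "score", "set"],
        )


def reaction_scores(
    model: MetabolicModel,
    activity: pd.Series | dict[str, float],
    high_threshold: float | None = None,
) -> ReactionScoreSet:
    """Fold gene activities through GPRs and partition reactions for iMAT.

    ``high_threshold`` defaults to the median of the non-zero reaction
    scores; reactions scoring strictly above it form the high set, reactions
    scoring zero (with a non-empty GPR) form the low set, everything else is
    left unscored for the extraction.
    """
    acts = dict(activity) if not isinstance(activity, dict) else activity
    scores: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        s = score_gpr(rxn.gpr, acts)
        if s is not None:
            scores[rid] = s
    nonzero = [s for s in scores.values() if s > 0]
    if high_threshold is None:
        high_threshold = float(np.median(nonzero)) if nonzero else 0.0
    high = {rid for rid, s in scores.items() if s > high_threshold}
    low = {rid for rid, s in scores.items() if s == 0.0}
    return ReactionScoreSet(scores, high, low, high_threshold)


# ---------------------------------------------------------------------------
# iMAT MILP
# ---------------------------------------------------------------------------


@dataclass
class ImatResult:
    status: str
    objective: float
    context: MetabolicModel | None
    active_high: set[str]
    inactive_low: set[str]
    kept_reactions: set[str]


def _imat_milp(system, high_idx, low_idx, eps):
    """Assemble and solve the iMAT MILP on a stoichiometric system.

    Variables: fluxes v (continuous) then, per high reaction, activation
    binaries y+ and y-, then per low reaction a suppression binary x.
    Objective: maximize sum(y+ + y-) + sum(x).
    """
    n = len(system.lb)
    nh, nl = len(high_idx), len(low_idx)
    nvar = n + 2 * nh + nl
    c = np.zeros(nvar)
    c[n:] = -1.0  # milp minimizes

    rows, lbs, ubs = [], [], []

    # steady state S v = 0
    A_eq = np.zeros((system.S.shape[0], nvar))
    A_eq[:, :n] = system.S
    rows.append(A_eq)
    lbs.append(np.zeros(system.S.shape[0]))
    ubs.append(np.zeros(system.S.shape[0]))

    # high-reaction activation: v_i + y+ (lb_i - eps) >= lb_i
    #                           v_i + y- (ub_i + eps) <= ub_i
    for k, j in enumerate(high_idx):
        row = np.zeros(nvar)
        row[j] = 1.0
        row[n + 2 * k] = system.lb[j] - eps
        rows.append(row.reshape(1, -1))
        lbs.append(np.array([system.lb[j]]))
        ubs.append(np.array([np.inf]))

        row = np.zeros(nvar)
        row[j] = 1.0
        row[n + 2 * k + 1] = system.ub[j] + eps
        rows.append(row.reshape(1, -1))
        lbs.append(np.array([-np.inf]))
        ubs.append(np.array([system.ub[j]]))

        # activating in both directions at once is contradictory
        row = np.zeros(nvar)
        row[n + 2 * k] = 1.0
        row[n + 2 * k + 1] = 1.0
        rows.append(row.reshape(1, -1))
        lbs.append(np.array([0.0]))
        ubs.append(np.array([1.0]))

    # low-reaction suppression: lb_i (1 - x_i) <= v_i <= ub_i (1 - x_i)
    for k, j in enumerate(low_idx):
        xcol = n + 2 * nh + k
        row = np.zeros(nvar)
        row[j] = 1.0
        row[xcol] = system.lb[j]
        rows.append(row.reshape(1, -1))
        lbs.append(np.array([system.lb[j]]))
        ubs.append(np.array([np.inf]))

        row = np.zeros(nvar)
        row[j] = 1.0
        row[xcol] = system.ub[j]
        rows.append(row.reshape(1, -1))
        lbs.append(np.array([-np.inf]))
        ubs.append(np.array([system.ub[j]]))

    A = np.vstack(rows)
    con = LinearConstraint(A, np.concatenate(lbs), np.concatenate(ubs))
    lb = np.concatenate([system.lb, np.zeros(2 * nh + nl)])
    ub = np.concatenate([system.ub, np.ones(2 * nh + nl)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nh + nl)])
    res = milp(
        c,
        constraints=[con],
        bounds=OptBounds(lb, ub),
        integrality=integrality,
        options={"presolve": True},
    )
    return res


def imat_extract(
    model: MetabolicModel,
    scores: ReactionScoreSet,
    eps: float = DEFAULT_EPS,
    prune: bool = True,
    tol: float = DEFAULT_TOL,
) -> ImatResult:
    """Extract a context-specific submodel with the iMAT MILP.

    The optimum maximizes the number of high-scoring reactions carrying at
    least ``eps`` flux (in either direction) plus the number of low-scoring
    reactions forced silent. The context model keeps all unscored reactions,
    high reactions with an active binary in the found optimum, and low
    reactions not suppressed; newly blocked reactions are then pruned.
    Membership follows the single optimum the solver returns (deterministic
    for fixed inputs), since iMAT optima need not be unique.
    """
    system = build_system(model)
    high = sorted(scores.high_set & set(model.reactions))
    low = sorted(scores.low_set & set(model.reactions))
    high_idx = [system.col_index[r] for r in high]
    low_idx = [system.col_index[r] for r in low]
    res = _imat_milp(system, high_idx, low_idx, eps)
    if not res.success:
        logger.warning("iMAT MILP did not reach optimality: %s", res.message)
        return ImatResult("infeasible", math.nan, None, set(), set(), set())

    n = len(system.lb)
    nh = len(high)
    yvals = res.x[n : n + 2 * nh]
    xvals = res.x[n + 2 * nh :]
    active_high = {
        rid
        for k, rid in enumerate(high)
        if yvals[2 * k] > 0.5 or yvals[2 * k + 1] > 0.5
    }
    inactive_low = {rid for k, rid in enumerate(low) if xvals[k] > 0.5}

    keep = [
        rid
        for rid in model.reactions
        if (rid not in scores.high_set and rid not in scores.low_set)
        or (rid in active_high)
        or (rid in scores.low_set and rid not in inactive_low)
    ]
    context = model.subset(keep)
    if prune:
        context = prune_blocked(context, tol=tol)
    context.id = f"{model.id}_context"
    return ImatResult(
        status="optimal",
        objective=float(-res.fun),
        context=context,
        active_high=active_high,
        inactive_low=inactive_low,
        kept_reactions=set(context.reactions),
    )
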