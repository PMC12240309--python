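"""Core domain types for compartmentalized metabolic networks.

A genome-scale metabolic model (GEM) is represented as a set of metabolites
(species with a compartment), reactions (signed stoichiometry maps with flux
bounds and a boolean gene-protein-reaction rule), and an objective. The
module also provides model I/O (JSON dialect, TSV tables, SBML L3+FBC via
cobra), GPR evaluation, consensus merging of draft reconstructions, gut-lumen
module construction, growth-medium application, and model-overlap reporting.

Conventions
-----------
* Metabolite ids are BIGG-style with a bracketed compartment suffix,
  e.g. ``ac[lu]`` for luminal acetate.
* Exchange reactions are written ``m ->`` (single metabolite, coefficient
  -1); negative flux is uptake, positive flux is secretion.
* Default bounds: irreversible internal reactions [0, 1000], reversible
  [-1000, 1000], units mmol·gDW^-1·h^-1 (relabelable, never rescaled).
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("colongem")

#: Reserved compartment codes.
COMPARTMENTS = {
    "c": "cytosol",
    "m": "mitochondria",
    "e": "extracellular",
    "lu": "lumen",
    "g": "golgi",
    "l": "lysosome",
    "n": "nucleus",
}

#: Compartments that touch the environment; exchanges live here.
BOUNDARY_COMPARTMENTS = {"e", "lu"}

DEFAULT_UB = 1000.0
DEFAULT_LB_REV = -1000.0

REACTION_KINDS = ("internal", "exchange", "sink", "demand", "transport")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


class GPRSyntaxError(ValueError):
    """Raised for malformed gene-protein-reaction expressions."""


class MergeConflictError(ValueError):
    """Raised when drafts disagree on the stoichiometry of a shared reaction."""


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_GPR_CACHE: dict[str, tuple] = {}


def _parse_gpr(rule: str) -> tuple | None:
    """Parse a GPR rule into a nested tuple AST.

    Grammar: ``or_expr := and_expr ('or' and_expr)*``;
    ``and_expr := atom ('and' atom)*``; ``atom := '(' or_expr ')' | gene``.
    An empty rule parses to ``None`` (reaction is not gene-controlled).
    """
    rule = rule.strip()
    if not rule:
        return None
    cached = _GPR_CACHE.get(rule)
    if cached is not None:
        return cached
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", *terms)

    def parse_and():
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", *terms)

    def parse_atom():
        tok = take()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            inner = parse_or()
            if take() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR rule: {rule!r}")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"misplaced token {tok!r} in GPR rule: {rule!r}")
        return ("gene", tok)

    ast = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR rule: {rule!r}")
    _GPR_CACHE[rule] = ast
    return ast


def gpr_genes(rule: str) -> set[str]:
    """Return the set of gene ids referenced by a GPR rule."""
    ast = _parse_gpr(rule)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            for child in node[1:]:
                walk(child)

    walk(ast)
    return out


def evaluate_gpr(rule: str, gene_states: dict[str, bool]) -> bool:
    """Evaluate a boolean GPR rule given per-gene on/off states.

    AND is conjunction (enzyme complex), OR is disjunction (isozymes). An
    empty rule evaluates True (the reaction is not gene-controlled). Genes
    absent from ``gene_states`` evaluate False (conservative knockout
    semantics).
    """
    ast = _parse_gpr(rule)
    if ast is None:
        return True

    def walk(node) -> bool:
        op = node[0]
        if op == "gene":
            return bool(gene_states.get(node[1], False))
        if op == "and":
            return all(walk(child) for child in node[1:])
        return any(walk(child) for child in node[1:])

    return walk(ast)


def score_gpr(rule: str, activities: dict[str, float]) -> float | None:
    """Fold gene activity scores through a GPR: AND -> min, OR -> max.

    Missing genes score 0. Returns None for an empty rule (unscored).
    """
    ast = _parse_gpr(rule)
    if ast is None:
        return None

    def walk(node) -> float:
        op = node[0]
        if op == "gene":
            return float(activities.get(node[1], 0.0))
        vals = [walk(child) for child in node[1:]]
        return min(vals) if op == "and" else max(vals)

    return walk(ast)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_MET_ID = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")


def split_met_id(met_id: str) -> tuple[str, str]:
    """Split ``base[comp]`` into (base, compartment); raises on bad ids."""
    m = _MET_ID.match(met_id)
    if not m:
        raise ModelValidationError(
            f"metabolite id {met_id!r} lacks a [compartment] suffix"
        )
    return m.group("base"), m.group("comp")


@dataclass
class Metabolite:
    """A chemical species localized to one compartment."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self):
        base, comp = split_met_id(self.id)
        if not self.compartment:
            self.compartment = comp
        elif self.compartment != comp:
            raise ModelValidationError(
                f"metabolite {self.id}: compartment field {self.compartment!r} "
                f"does not match id suffix [{comp}]"
            )
        if not self.name:
            self.name = base

    @property
    def base_id(self) -> str:
        return split_met_id(self.id)[0]

    def copy(self) -> "Metabolite":
        return _copy.copy(self)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed). ``kind`` distinguishes internal conversions from boundary
    reactions: exchanges (environment), sinks (unconditional supply/removal)
    and demands (unconditional removal), plus cross-compartment transports.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    gpr: str = ""
    subsystem: str = ""
    kind: str | None = None

    def __post_init__(self):
        if not self.name:
            self.name = self.id
        if self.kind is None:
            self.kind = self._infer_kind()
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")

    def _infer_kind(self) -> str:
        mets = list(self.stoichiometry)
        if len(mets) == 1:
            comp = split_met_id(mets[0])[1]
            if comp in BOUNDARY_COMPARTMENTS:
                return "exchange"
            up = self.id.upper()
            if up.startswith(("DM_", "DEMAND")):
                return "demand"
            return "sink"
        comps = {split_met_id(m)[1] for m in mets}
        if len(comps) > 1:
            return "transport"
        return "internal"

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    @property
    def is_boundary(self) -> bool:
        return self.kind in ("exchange", "sink", "demand")

    @property
    def boundary_metabolite(self) -> str:
        if not self.is_boundary or len(self.stoichiometry) != 1:
            raise ValueError(f"{self.id} is not a single-metabolite boundary reaction")
        return next(iter(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = _copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r

    def validate(self, model: "MetabolicModel") -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        for met_id in self.stoichiometry:
            if met_id not in model.metabolites:
                raise ModelValidationError(
                    f"reaction {self.id}: unresolved metabolite {met_id!r}"
                )
        if self.is_boundary and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"reaction {self.id}: {self.kind} reactions must touch exactly "
                f"one metabolite, got {len(self.stoichiometry)}"
            )
        if len(self.stoichiometry) == 1:
            comp = split_met_id(next(iter(self.stoichiometry)))[1]
            if self.kind == "exchange" and comp not in BOUNDARY_COMPARTMENTS:
                raise ModelValidationError(
                    f"reaction {self.id}: exchange metabolite must live in a "
                    f"boundary compartment (e/lu), got [{comp}]"
                )
            if comp in BOUNDARY_COMPARTMENTS and self.kind not in ("exchange",):
                raise ModelValidationError(
                    f"reaction {self.id}: single-metabolite boundary-compartment "
                    f"reaction must be kind=exchange, got {self.kind}"
                )


@dataclass
class MetabolicModel:
    """A compartmentalized reaction network with bounds, GPRs and objective."""

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    name: str = ""
    unit: str = "mmol/gDW/h"

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        rxn.validate(self)
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reactions(self, ids, prune_orphans: bool = False) -> None:
        for rid in ids:
            self.reactions.pop(rid, None)
            self.objective.pop(rid, None)
        if prune_orphans:
            used = {m for r in self.reactions.values() for m in r.stoichiometry}
            self.metabolites = {k: v for k, v in self.metabolites.items() if k in used}

    def subset(self, reaction_ids) -> "MetabolicModel":
        """Return a copy containing only the listed reactions (orphan
        metabolites pruned, objective intersected)."""
        keep = set(reaction_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise ModelValidationError(f"unknown reactions in subset: {sorted(missing)}")
        sub = MetabolicModel(id=self.id, name=self.name, unit=self.unit)
        used: set[str] = set()
        for rid, rxn in self.reactions.items():
            if rid in keep:
                used |= set(rxn.stoichiometry)
        for mid, met in self.metabolites.items():
            if mid in used:
                sub.metabolites[mid] = met.copy()
        for rid, rxn in self.reactions.items():
            if rid in keep:
                sub.reactions[rid] = rxn.copy()
        sub.objective = {k: v for k, v in self.objective.items() if k in keep}
        return sub

    def copy(self) -> "MetabolicModel":
        dup = MetabolicModel(id=self.id, name=self.name, unit=self.unit)
        dup.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        dup.reactions = {k: v.copy() for k, v in self.reactions.items()}
        dup.objective = dict(self.objective)
        return dup

    # -- queries ------------------------------------------------------------

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def boundary(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_boundary]

    def exchange_for(self, met_id: str) -> Reaction | None:
        """The exchange reaction touching a metabolite, if any."""
        for rxn in self.reactions.values():
            if rxn.kind == "exchange" and met_id in rxn.stoichiometry:
                return rxn
        return None

    def boundary_for(self, met_id: str) -> Reaction | None:
        """Any boundary (exchange/sink/demand) reaction touching a metabolite."""
        for rxn in self.reactions.values():
            if rxn.is_boundary and met_id in rxn.stoichiometry:
                return rxn
        return None

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate(self)
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelValidationError(f"objective references unknown reaction {rid!r}")

    def equal_ids(self, other: "MetabolicModel") -> bool:
        """Id-level equality: same reactions (stoichiometry, bounds, GPR),
        metabolites and objective."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if rxn.stoichiometry != o.stoichiometry:
                return False
            if not np.isclose(rxn.lower_bound, o.lower_bound) or not np.isclose(
                rxn.upper_bound, o.upper_bound
            ):
                return False
            if _parse_gpr(rxn.gpr) != _parse_gpr(o.gpr):
                return False
        return self.objective == other.objective


@dataclass
class StoichiometricSystem:
    """Matrix form of a model: S·v = 0, lb <= v <= ub, objective c."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    row_index: dict[str, int]
    col_index: dict[str, int]
    reactions: list[str]
    metabolites: list[str]


def build_system(model: MetabolicModel) -> StoichiometricSystem:
    """Assemble the stoichiometric matrix in deterministic insertion order."""
    model.validate()
    mets = list(model.metabolites)
    rxns = list(model.reactions)
    row_index = {m: i for i, m in enumerate(mets)}
    col_index = {r: j for j, r in enumerate(rxns)}
    S = np.zeros((len(mets), len(rxns)))
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    c = np.zeros(len(rxns))
    for j, rid in enumerate(rxns):
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for met_id, coeff in rxn.stoichiometry.items():
            S[row_index[met_id], j] = coeff
    for rid, w in model.objective.items():
        c[col_index[rid]] = w
    return StoichiometricSystem(S, lb, ub, c, row_index, col_index, rxns, mets)


# ---------------------------------------------------------------------------
# Consensus merging, lumen module, medium, overlap
# ---------------------------------------------------------------------------


def merge_consensus(
    drafts: list[tuple[str, MetabolicModel]],
    exclude_unique_from: str | None = None,
    template: MetabolicModel | None = None,
) -> MetabolicModel:
    """Merge draft reconstructions into a consensus model.

    The consensus reaction set is the union over drafts minus the reactions
    present *only* in the draft labelled ``exclude_unique_from``. Reaction
    entries (stoichiometry, bounds, GPR) are taken from ``template`` when
    given, otherwise from the first draft carrying the reaction; drafts that
    disagree on stoichiometry raise :class:`MergeConflictError`.
    """
    if len(drafts) < 2:
        raise ValueError("merge_consensus needs at least two drafts")
    labels = [lab for lab, _ in drafts]
    if exclude_unique_from is not None and exclude_unique_from not in labels:
        raise ValueError(f"unknown draft label {exclude_unique_from!r}")

    membership: dict[str, set[str]] = {}
    for lab, model in drafts:
        for rid in model.reactions:
            membership.setdefault(rid, set()).add(lab)
    keep = [
        rid
        for rid, labs in membership.items()
        if not (exclude_unique_from is not None and labs == {exclude_unique_from})
    ]

    source: dict[str, Reaction] = {}
    for rid in keep:
        if template is not None and rid in template.reactions:
            source[rid] = template.reactions[rid]
            continue
        entry = None
        for lab, model in drafts:
            if rid in model.reactions:
                rxn = model.reactions[rid]
                if entry is None:
                    entry = rxn
                elif rxn.stoichiometry != entry.stoichiometry:
                    raise MergeConflictError(
                        f"drafts disagree on stoichiometry of reaction {rid!r}"
                    )
        source[rid] = entry  # type: ignore[assignment]

    met_source: dict[str, Metabolite] = {}
    for lab, model in drafts:
        for mid, met in model.metabolites.items():
            met_source.setdefault(mid, met)
    if template is not None:
        met_source.update(
            {mid: met for mid, met in template.metabolites.items() if mid in met_source}
        )

    consensus = MetabolicModel(id="consensus")
    used: set[str] = set()
    for rid in keep:
        used |= set(source[rid].stoichiometry)
    for mid in met_source:
        if mid in used:
            consensus.metabolites[mid] = met_source[mid].copy()
    # deterministic order: template order first, then first-seen order
    order = list(template.reactions) if template is not None else []
    ordered = [r for r in order if r in source] + [r for r in source if r not in order]
    for rid in ordered:
        consensus.reactions[rid] = source[rid].copy()
    obj_src = template.objective if template is not None else drafts[0][1].objective
    consensus.objective = {k: v for k, v in obj_src.items() if k in consensus.reactions}
    consensus.validate()
    return consensus


def lumen_transport_id(base: str) -> str:
    return f"T_{base}_lu"


def lumen_exchange_id(base: str) -> str:
    return f"EX_{base}_lu"


def add_lumen_module(
    model: MetabolicModel, lumen_metabolites: list[str], inplace: bool = False
) -> MetabolicModel:
    """Attach a gut-lumen compartment for the listed extracellular metabolites.

    For each extracellular metabolite ``m[e]`` adds the luminal species
    ``m[lu]``, a reversible apical transport ``m[lu] <-> m[e]`` and a lumen
    exchange ``m[lu] ->``. Idempotent: re-adding an existing lumen entry is a
    no-op.
    """
    out = model if inplace else model.copy()
    for met_id in lumen_metabolites:
        base, comp = split_met_id(met_id)
        if comp != "e":
            raise ModelValidationError(
                f"lumen module expects extracellular metabolites, got {met_id!r}"
            )
        if met_id not in out.metabolites:
            raise ModelValidationError(
                f"metabolite {met_id!r} not present in model {out.id!r}"
            )
        lu_id = f"{base}[lu]"
        t_id = lumen_transport_id(base)
        ex_id = lumen_exchange_id(base)
        if lu_id not in out.metabolites:
            src = out.metabolites[met_id]
            out.add_metabolite(
                Metabolite(lu_id, name=src.name, formula=src.formula, charge=src.charge)
            )
        if t_id not in out.reactions:
            out.add_reaction(
                Reaction(
                    t_id,
                    name=f"{base} lumen transport",
                    stoichiometry={lu_id: -1.0, met_id: 1.0},
                    lower_bound=DEFAULT_LB_REV,
                    upper_bound=DEFAULT_UB,
                    subsystem="Transport, lumen",
                    kind="transport",
                )
            )
        if ex_id not in out.reactions:
            out.add_reaction(
                Reaction(
                    ex_id,
                    name=f"{base} lumen exchange",
                    stoichiometry={lu_id: -1.0},
                    lower_bound=DEFAULT_LB_REV,
                    upper_bound=DEFAULT_UB,
                    subsystem="Lumen exchange",
                    kind="exchange",
                )
            )
    return out


def apply_medium(
    model: MetabolicModel,
    medium: dict[str, float],
    default_uptake: float = 1.0,
    inplace: bool = False,
) -> MetabolicModel:
    """Constrain exchange uptake bounds to a growth-medium composition.

    ``medium`` maps metabolite id -> maximal uptake rate (positive number;
    the exchange lower bound becomes its negation). Every exchange whose
    metabolite is not listed gets lower bound 0. Secretion (upper bounds) is
    untouched.
    """
    out = model if inplace else model.copy()
    ex_by_met = {}
    for rxn in out.exchanges():
        ex_by_met[rxn.boundary_metabolite] = rxn
    for met_id in medium:
        if met_id not in ex_by_met:
            raise ModelValidationError(
                f"medium metabolite {met_id!r} has no exchange reaction"
            )
    for met_id, rxn in ex_by_met.items():
        if met_id in medium:
            bound = medium[met_id]
            rxn.lower_bound = -(default_uptake if bound is None else float(bound))
        else:
            rxn.lower_bound = 0.0
    return out


@dataclass
class ModelOverlap:
    """Id-level overlap between two models (counts and percent of model A)."""

    shared_reactions: int
    shared_metabolites: int
    shared_genes: int
    pct_of_A: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "shared_reactions": self.shared_reactions,
            "shared_metabolites": self.shared_metabolites,
            "shared_genes": self.shared_genes,
            "pct_of_A": dict(self.pct_of_A),
        }


def model_overlap(a: MetabolicModel, b: MetabolicModel) -> ModelOverlap:
    """Exact id-set intersections of reactions/metabolites/genes, plus the
    percentage of model A's items found in model B."""

    def pct(shared: int, total: int) -> float:
        return 100.0 * shared / total if total else 0.0

    ra, rb = set(a.reactions), set(b.reactions)
    ma, mb = set(a.metabolites), set(b.metabolites)
    ga, gb = a.genes, b.genes
    sr, sm, sg = len(ra & rb), len(ma & mb), len(ga & gb)
    return ModelOverlap(
        shared_reactions=sr,
        shared_metabolites=sm,
        shared_genes=sg,
        pct_of_A={
            "reactions": pct(sr, len(ra)),
            "metabolites": pct(sm, len(ma)),
            "genes": pct(sg, len(ga)),
        },
    )


# ---------------------------------------------------------------------------
# I/O — JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "name": model.name,
        "unit": model.unit,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
        "objective": {k: float(v) for k, v in sorted(model.objective.items())},
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=data.get("id", "model"),
            name=data.get("name", ""),
            unit=data.get("unit", "mmol/gDW/h"),
        )
        for m in data["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", ""),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
            )
        for r in data["reactions"]:
            model.add_reaction(
                Reaction(
                    r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_UB)),
                    gpr=r.get("gpr", ""),
                    subsystem=r.get("subsystem", ""),
                    kind=r.get("kind"),
                )
            )
        model.objective = {k: float(v) for k, v in data.get("objective", {}).items()}
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"malformed model document: {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# I/O — TSV tables (reactions.tsv / metabolites.tsv / genes.tsv)
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"<->|<=>|<--|-->|->|<-|=")


def parse_equation(eq: str) -> dict[str, float]:
    """Parse a reaction equation string into a stoichiometry map.

    Accepts either a coefficient map ``A[c]:-1;B[c]:1`` or an arrow equation
    ``2 A[c] + B[c] -> C[c]``.
    """
    eq = eq.strip()
    if not eq:
        raise ModelParseError("empty reaction equation")
    if ":" in eq and not _ARROW.search(eq):
        stoich: dict[str, float] = {}
        for part in eq.split(";"):
            part = part.strip()
            if not part:
                continue
            met, _, coeff = part.rpartition(":")
            try:
                stoich[met.strip()] = float(coeff)
            except ValueError as exc:
                raise ModelParseError(f"bad stoichiometry term {part!r}") from exc
        return stoich
    m = _ARROW.search(eq)
    if not m:
        raise ModelParseError(f"no arrow in equation {eq!r}")
    left, right = eq[: m.start()], eq[m.end():]
    stoich = {}

    def side(txt: str, sign: float):
        txt = txt.strip()
        if not txt:
            return
        for term in txt.split("+"):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coeff, met = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coeff, met = 1.0, bits[0]
            else:
                raise ModelParseError(f"bad equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    side(left, -1.0)
    side(right, +1.0)
    return {k: v for k, v in stoich.items() if v != 0.0}


def format_equation(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in sorted(stoich.items()))


def _load_tables(path: Path) -> MetabolicModel:
    import pandas as pd

    path = Path(path)
    rxn_path = path / "reactions.tsv" if path.is_dir() else path
    met_path = path / "metabolites.tsv" if path.is_dir() else None
    if not rxn_path.exists():
        raise ModelParseError(f"missing reactions table at {rxn_path}")
    model = MetabolicModel(id=path.stem if not path.is_dir() else path.name)
    if met_path is not None and met_path.exists():
        mets = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
        for _, row in mets.iterrows():
            model.add_metabolite(
                Metabolite(
                    row["id"],
                    name=row.get("name", ""),
                    formula=row.get("formula") or None,
                    charge=int(row["charge"]) if row.get("charge") else None,
                )
            )
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    if "id" not in rxns.columns or "equation" not in rxns.columns:
        raise ModelParseError("reactions table needs 'id' and 'equation' columns")
    for _, row in rxns.iterrows():
        stoich = parse_equation(row["equation"])
        for met_id in stoich:
            if met_id not in model.metabolites:
                model.add_metabolite(Metabolite(met_id))
        model.add_reaction(
            Reaction(
                row["id"],
                name=row.get("name", "") or row["id"],
                stoichiometry=stoich,
                lower_bound=float(row["lb"]) if row.get("lb", "") != "" else 0.0,
                upper_bound=float(row["ub"]) if row.get("ub", "") != "" else DEFAULT_UB,
                gpr=row.get("gpr", ""),
                subsystem=row.get("subsystem", ""),
                kind=(row.get("kind") or None),
            )
        )
        if row.get("objective", "") not in ("", "0", "0.0"):
            model.objective[row["id"]] = float(row["objective"])
    model.validate()
    return model


def _write_tables(model: MetabolicModel, path: Path) -> None:
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "kind": r.kind,
                "objective": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions.values()
        ]
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula or "",
                "charge": "" if m.charge is None else m.charge,
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame({"id": sorted(model.genes)}).to_csv(
        path / "genes.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# I/O — SBML L3 + FBC via cobra
# ---------------------------------------------------------------------------

_SID_ENC = [("[", "__91__"), ("]", "__93__")]


def _encode_sid(s: str) -> str:
    for raw, enc in _SID_ENC:
        s = s.replace(raw, enc)
    return s


def _decode_sid(s: str) -> str:
    for raw, enc in _SID_ENC:
        s = s.replace(enc, raw)
    return s


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (ids SId-sanitized for SBML)."""
    import cobra

    cm = cobra.Model(_encode_sid(model.id) or "model")
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            _encode_sid(m.id),
            name=m.name,
            compartment=m.compartment,
            formula=m.formula,
            charge=m.charge,
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(
            _encode_sid(r.id),
            name=r.name,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
        )
        cr.subsystem = r.subsystem
        rxns.append((cr, r))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, r in rxns:
        cr.add_metabolites({mets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    cm.objective = {
        cm.reactions.get_by_id(_encode_sid(rid)): w for rid, w in model.objective.items()
    }
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model into the package's model type."""
    model = MetabolicModel(id=_decode_sid(cm.id), name=cm.name or "")
    for cmet in cm.metabolites:
        mid = _decode_sid(cmet.id)
        try:
            split_met_id(mid)
        except ModelValidationError:
            mid = f"{mid}[{cmet.compartment or 'c'}]"
        model.add_metabolite(
            Metabolite(
                mid,
                name=cmet.name or "",
                formula=cmet.formula or None,
                charge=cmet.charge if cmet.charge is not None else None,
            )
        )
    id_map = {cmet.id: mid for cmet, mid in zip(cm.metabolites, model.metabolites)}
    from cobra.util.solver import linear_reaction_coefficients

    obj = {r.id: c for r, c in linear_reaction_coefficients(cm).items()}
    for cr in cm.reactions:
        model.add_reaction(
            Reaction(
                _decode_sid(cr.id),
                name=cr.name or "",
                stoichiometry={
                    id_map[cmet.id]: coeff for cmet, coeff in cr.metabolites.items()
                },
                lower_bound=cr.lower_bound,
                upper_bound=cr.upper_bound,
                gpr=cr.gene_reaction_rule or "",
                subsystem=cr.subsystem or "",
            )
        )
        if cr.id in obj:
            model.objective[_decode_sid(cr.id)] = obj[cr.id]
    model.validate()
    return model


# ---------------------------------------------------------------------------
# load_model / write_model front doors
# ---------------------------------------------------------------------------


def _guess_format(path: Path) -> str:
    if path.is_dir():
        return "tables"
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt"):
        return "tables"
    raise ModelParseError(f"cannot guess model format for {path}")


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML L3+FBC, the JSON dialect, or TSV tables."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON in {path}: {exc}") from exc
        return _model_from_dict(data)
    if fmt == "tables":
        return _load_tables(path)
    if fmt == "sbml":
        from cobra.io import read_sbml_model

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = read_sbml_model(str(path))
        return from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, format: str | None = None) -> Path:
    """Write a model; round-trips with :func:`load_model` at id level."""
    path = Path(path)
    fmt = format or _guess_format(path)
    model.validate()
    if fmt == "json":
        path.write_text(
            json.dumps(_model_to_dict(model), indent=1, sort_keys=True) + "\n"
        )
    elif fmt == "tables":
        _write_tables(model, path)
    elif fmt == "sbml":
        from cobra.io import write_sbml_model

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    return path
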