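"""Host-microbiome community modeling through a shared lumen compartment.

A community model couples the host (which must already carry a lumen
module) with abundance-weighted microbial members. Member reactions are
namespaced ``taxon__reaction``; each member exchange metabolite that maps
onto a luminal species is rewired into a community coupling reaction whose
lumen-side stoichiometry is scaled by the member's relative abundance a_i,
so the community-level flux of member i equals a_i times the member-level
flux. Diet enters as uptake bounds on the lumen exchanges.

Optimization is a staged cooperative tradeoff: (1) maximize community
growth sum(a_i mu_i); (2) constrain community growth to a fraction of that
optimum and maximize host biomass maintenance; (3) optionally fix the host
optimum and minimize sum(mu_i^2) to spread growth evenly (uniqueness).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction, split_met_id
from .lp import DEFAULT_TOL, _solve_lp
from .core import build_system

logger = logging.getLogger("colongem")

DEFAULT_TRADEOFF = 0.5
_SEP = "__"


@dataclass
class CommunityMember:
    taxon: str
    model: MetabolicModel
    abundance: float
    biomass_reaction: str  # namespaced id


@dataclass
class CommunityModel:
    """Merged host + members model sharing the lumen metabolite pool."""

    model: MetabolicModel
    host_biomass: str
    members: list[CommunityMember]
    coupling_reactions: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # lumen met id -> [(taxon, coupling reaction id)]
    host_lumen_transports: dict[str, str] = field(default_factory=dict)
    # lumen met id -> host transport reaction id (lumen -> host side)


def _member_objective(member: MetabolicModel) -> str:
    if len(member.objective) == 1:
        return next(iter(member.objective))
    for rid in member.reactions:
        if rid.upper().startswith("BIOMASS"):
            return rid
    raise ValueError(f"member {member.id!r} has no unique biomass objective")


def build_community(
    host: MetabolicModel,
    members: list[tuple[str, MetabolicModel, float]],
    diet: dict[str, float] | None = None,
    host_biomass: str = "BIOMASS_maintenance",
) -> CommunityModel:
    """Assemble the shared-lumen community model.

    ``members`` are (taxon, model, relative abundance) triples; abundances
    not summing to one are normalized with a warning. Each member exchange
    whose metabolite has a luminal counterpart in the host is replaced by a
    coupling reaction ``taxon__EX_..._lu`` moving the metabolite between the
    member's namespace and the shared lumen pool (abundance-scaled);
    unmappable member exchanges are kept as private exchanges and logged.
    ``diet`` maps luminal metabolite ids to uptake bounds on the lumen
    exchanges.
    """
    lumen_mets = {
        mid for mid in host.metabolites if split_met_id(mid)[1] == "lu"
    }
    if not lumen_mets:
        raise ValueError("host model has no lumen compartment; add a lumen module first")
    if host_biomass not in host.reactions:
        raise ValueError(f"host biomass reaction {host_biomass!r} not found")

    total = sum(a for _, _, a in members)
    if members and not math.isclose(total, 1.0, rel_tol=1e-9):
        logger.warning("abundances sum to %.4g; normalizing", total)
    merged = host.copy()
    merged.id = f"{host.id}_community"

    com_members = []
    coupling: dict[str, list[tuple[str, str]]] = {}
    for taxon, model, abundance in members:
        a = abundance / total if total else 0.0
        ns = lambda x: f"{taxon}{_SEP}{x}"
        # namespaced member metabolites
        for met in model.metabolites.values():
            base, comp = split_met_id(met.id)
            merged.add_metabolite(
                Metabolite(f"{taxon}{_SEP}{base}[{comp}]", name=f"{taxon} {met.name}")
            )
        biomass_id = _member_objective(model)
        for rxn in model.reactions.values():
            stoich = {
                f"{taxon}{_SEP}{split_met_id(m)[0]}[{split_met_id(m)[1]}]": c
                for m, c in rxn.stoichiometry.items()
            }
            if rxn.kind == "exchange":
                met_id = rxn.boundary_metabolite
                base = split_met_id(met_id)[0]
                lu_id = f"{base}[lu]"
                if lu_id in lumen_mets:
                    # coupling: member-side species <-> shared lumen pool,
                    # lumen side scaled by relative abundance
                    member_species = f"{taxon}{_SEP}{base}[{split_met_id(met_id)[1]}]"
                    rid = ns(rxn.id)
                    merged.add_reaction(
                        Reaction(
                            rid,
                            name=f"{taxon} {base} lumen coupling",
                            stoichiometry={member_species: -1.0, lu_id: a},
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound,
                            subsystem="Community coupling",
                            kind="transport",
                        )
                    )
                    coupling.setdefault(lu_id, []).append((taxon, rid))
                    continue
                logger.info(
                    "member %s exchange %s has no luminal counterpart; kept private",
                    taxon, rxn.id,
                )
            merged.add_reaction(
                Reaction(
                    ns(rxn.id),
                    name=f"{taxon} {rxn.name}",
                    stoichiometry=stoich,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    gpr=rxn.gpr,
                    subsystem=rxn.subsystem,
                    kind=rxn.kind if rxn.kind != "exchange" else "exchange",
                )
            )
        com_members.append(CommunityMember(taxon, model, a, ns(biomass_id)))

    if diet:
        from .core import apply_medium

        # constrain only lumen exchanges; host serosal exchanges keep their bounds
        ex_lu = {
            r.boundary_metabolite: r for r in merged.exchanges()
            if split_met_id(r.boundary_metabolite)[1] == "lu"
        }
        for met_id, bound in diet.items():
            if met_id not in ex_lu:
                raise ValueError(f"diet metabolite {met_id!r} has no lumen exchange")
        for met_id, rxn in ex_lu.items():
            rxn.lower_bound = -float(diet[met_id]) if met_id in diet else 0.0

    host_transports = {}
    for rid, rxn in host.reactions.items():
        if rxn.kind == "transport":
            lus = [m for m in rxn.stoichiometry if split_met_id(m)[1] == "lu"]
            if len(lus) == 1 and len(rxn.stoichiometry) == 2:
                host_transports[lus[0]] = rid

    merged.objective = {host_biomass: 1.0}
    merged.validate()
    return CommunityModel(
        model=merged,
        host_biomass=host_biomass,
        members=com_members,
        coupling_reactions=coupling,
        host_lumen_transports=host_transports,
    )


@dataclass
class CommunitySolution:
    status: str
    member_growth: dict[str, float]  # taxon -> mu_i (member-level flux)
    host_biomass_flux: float
    community_growth: float  # sum a_i mu_i
    fluxes: dict[str, float]
    community: CommunityModel

    def member_abundances(self) -> dict[str, float]:
        return {m.taxon: m.abundance for m in self.community.members}


def cooperative_tradeoff(
    community: CommunityModel,
    tradeoff_fraction: float = DEFAULT_TRADEOFF,
    l2_stage: bool = True,
) -> CommunitySolution:
    """Staged cooperative-tradeoff optimization of the community.

    Stage 1 maximizes community growth sum(a_i mu_i); stage 2 constrains it
    to ``tradeoff_fraction`` of the optimum and maximizes the host biomass
    maintenance flux; stage 3 (optional) fixes the host optimum and
    minimizes sum(mu_i^2) to distribute growth evenly among members.
    """
    system = build_system(community.model)
    n = len(system.lb)
    c_comm = np.zeros(n)
    for mem in community.members:
        c_comm[system.col_index[mem.biomass_reaction]] = mem.abundance
    c_host = np.zeros(n)
    c_host[system.col_index[community.host_biomass]] = 1.0

    res1 = _solve_lp(system, c_comm, maximize=True)
    if res1.status != 0:
        return CommunitySolution("infeasible", {}, math.nan, math.nan, {}, community)
    growth_opt = float(c_comm @ res1.x)

    A_ub = -c_comm.reshape(1, -1)
    b_ub = np.array([-tradeoff_fraction * growth_opt])
    res2 = _solve_lp(system, c_host, maximize=True, extra_A_ub=A_ub, extra_b_ub=b_ub)
    if res2.status != 0:
        return CommunitySolution("infeasible", {}, math.nan, math.nan, {}, community)
    host_opt = float(c_host @ res2.x)
    x = res2.x

    if l2_stage and community.members:
        x = _l2_distribute(system, community, c_comm, c_host,
                           tradeoff_fraction * growth_opt, host_opt, x)

    fluxes = {rid: float(x[j]) for rid, j in system.col_index.items()}
    member_growth = {
        mem.taxon: fluxes[mem.biomass_reaction] for mem in community.members
    }
    return CommunitySolution(
        status="optimal",
        member_growth=member_growth,
        host_biomass_flux=fluxes[community.host_biomass],
        community_growth=float(
            sum(mem.abundance * member_growth[mem.taxon] for mem in community.members)
        ),
        fluxes=fluxes,
        community=community,
    )


def _l2_distribute(system, community, c_comm, c_host, growth_floor, host_opt, x0):
    """Stage 3: minimize sum(mu_i^2) subject to the stage-1/2 achievements."""
    from scipy.optimize import LinearConstraint, minimize
    from scipy.optimize import Bounds as OptBounds

    idx = [system.col_index[m.biomass_reaction] for m in community.members]

    def fun(v):
        return float(sum(v[j] ** 2 for j in idx))

    def jac(v):
        g = np.zeros_like(v)
        for j in idx:
            g[j] = 2 * v[j]
        return g

    slack = 1e-9
    cons = [
        LinearConstraint(system.S, 0.0, 0.0),
        LinearConstraint(c_comm.reshape(1, -1), growth_floor - slack, np.inf),
        LinearConstraint(c_host.reshape(1, -1), host_opt - slack, np.inf),
    ]
    res = minimize(
        fun,
        x0,
        jac=jac,
        bounds=OptBounds(system.lb, system.ub),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success and np.max(np.abs(system.S @ res.x)) < 1e-6:
        return res.x
    logger.warning("L2 distribution stage failed (%s); keeping stage-2 solution",
                   getattr(res, "message", "?"))
    return x0


@dataclass
class ExchangeAccount:
    metabolite: str
    community_secretion: float  # abundance-weighted member flux into the lumen
    community_uptake: float
    host_uptake: float  # host flux out of the lumen pool
    host_secretion: float
    pct_of_production_taken_by_host: float | None


def exchange_accounting(
    solution: CommunitySolution, tol: float = DEFAULT_TOL
) -> list[ExchangeAccount]:
    """Per-lumen-metabolite accounting of who produces and who consumes.

    Community secretion/uptake are the abundance-weighted member coupling
    fluxes into/out of the shared lumen pool; host uptake/secretion read the
    host's lumen transport. The percentage of microbial production taken by
    the host is only defined when the community secretes above tolerance.
    """
    if solution.status != "optimal":
        raise ValueError("exchange accounting requires an optimal solution")
    com = solution.community
    out = []
    for lu_id in sorted(set(com.coupling_reactions) | set(com.host_lumen_transports)):
        sec = upt = 0.0
        for taxon, rid in com.coupling_reactions.get(lu_id, []):
            a = next(m.abundance for m in com.members if m.taxon == taxon)
            v = solution.fluxes.get(rid, 0.0) * a  # lumen-side flux
            if v > 0:
                sec += v
            else:
                upt += -v
        host_upt = host_sec = 0.0
        t_id = com.host_lumen_transports.get(lu_id)
        if t_id is not None and t_id in solution.fluxes:
            coeff = com.model.reactions[t_id].stoichiometry[lu_id]
            v_lu = solution.fluxes[t_id] * coeff  # flux into the lumen pool
            if v_lu < 0:
                host_upt = -v_lu
            else:
                host_sec = v_lu
        pct = None
        if sec > tol:
            pct = 100.0 * min(host_upt, sec) / sec
        out.append(
            ExchangeAccount(
                metabolite=lu_id,
                community_secretion=sec,
                community_uptake=upt,
                host_uptake=host_upt,
                host_secretion=host_sec,
                pct_of_production_taken_by_host=pct,
            )
        )
    return out


def directional_lists(
    accounts: list[ExchangeAccount], tol: float = DEFAULT_TOL
) -> dict[str, list[str]]:
    """The two headline metabolite lists: secreted by the host and taken up
    by the community, and vice versa."""
    host_to_community = [
        a.metabolite
        for a in accounts
        if a.host_secretion > tol and a.community_uptake > tol
    ]
    community_to_host = [
        a.metabolite
        for a in accounts
        if a.community_secretion > tol and a.host_uptake > tol
    ]
    return {
        "host_to_community": host_to_community,
        "community_to_host": community_to_host,
    }
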