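"""Synthetic study generators: toy colonocyte template, grouped expression,
toy microbes and a matching metabolic-task suite.

The template is a desk-scale colonocyte-like network with compartments
c/m/e/lu: glucose uptake feeding a lumped glycolysis, SCFA (butyrate,
acetate, propionate) lumen transport feeding lumped mitochondrial
beta-oxidation with fixed integer ATP yields (5/2/3 ATP), a lumped
respiration sink for lactate, an ATP-hydrolysis demand, and a biomass
maintenance reaction consuming ATP plus a precursor producible through two
parallel, disjointly gene-controlled routes: a tryptophan-like route (the
planted disease-relevant pathway) and a glutamine route. Every enzymatic
reaction carries a GPR; exchanges and pseudo-reactions do not.

Expression emulates grouped healthy/disease transcriptomes with a planted
down-regulated pathway. Genes fall into three baseline tiers — expressed
(150), intermediate (50) and off (2) — so the within-sample 30th-percentile
cutoff lands inside the intermediate tier, cleanly separating healthy
planted expression (150) from its disease value (150 * 2^-fold).
Intermediate-tier genes are redundant isozymes whose binarization noise
cannot change any flux capability; off-tier genes control a decoy pathway
excluded from every context model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
    add_lumen_module,
    apply_medium,
)
from .extraction import ExpressionMatrix
from .validation import MetabolicTask

logger = logging.getLogger("colongem")

#: baseline expression per tier (arbitrary normalized units)
TIER_BASELINES = {"expressed": 150.0, "intermediate": 50.0, "off": 2.0}

#: ATP yields of the lumped beta-oxidation pseudo-reactions, per SCFA
SCFA_ATP_YIELD = {"but": 5, "ac": 2, "ppa": 3}

#: default medium of the template (metabolite id -> uptake bound)
DEFAULT_MEDIUM = {
    "glc[e]": 10.0,
    "gln[e]": 4.0,
    "trp[e]": 10.0,
    "o2[e]": 10.0,
    "h2o[e]": 1000.0,
    "xa[e]": 1.0,
    "but[lu]": 1.0,
    "ac[lu]": 1.0,
    "ppa[lu]": 1.0,
}

#: the planted disease-relevant pathway (tryptophan-like route to the
#: biomass precursor) and its genes
PLANTED_REACTIONS = ("TRPt", "TRPOX", "PRECP")
PLANTED_GENES = ("g_p1", "g_p2", "g_p3")

#: decoy pathway controlled by constitutively unexpressed genes
OFF_GENES = ("g_d1", "g_d2", "g_d3")

INTERMEDIATE_GENES = tuple(f"g_mid{i}" for i in range(1, 12))


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study; the seed fully determines all outputs."""

    seed: int = 0
    n_healthy: int = 5
    n_disease: int = 5
    fold_change: float = 2.0  # disease mean = healthy mean * 2**(-fold)
    sigma: float = 0.25  # log-normal multiplicative noise (natural-log sd)
    n_parallel_pathways: int = 2
    planted_off: bool = False  # True -> planted genes exactly 0 in disease
    planted_genes: tuple[str, ...] = PLANTED_GENES
    planted_reactions: tuple[str, ...] = PLANTED_REACTIONS

    def __post_init__(self):
        if self.fold_change < 0 or self.sigma < 0:
            raise ValueError("fold_change and sigma must be non-negative")
        if self.n_parallel_pathways < 2:
            raise ValueError("template needs at least two parallel pathways")


def _rxn(model, rid, stoich, lb, ub, gpr="", subsystem="", kind=None, name=""):
    model.add_reaction(
        Reaction(
            rid,
            name=name or rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            subsystem=subsystem,
            kind=kind,
        )
    )


def make_toy_template(spec: SyntheticSpec | None = None) -> MetabolicModel:
    """Build the toy colonocyte template model (seed-independent topology).

    The returned model has the default medium applied, passes the full
    sanity battery (no leaks, no energy from water, flux-consistent) and
    reaches a biomass-maintenance optimum of 14 on the default medium
    (10 units of precursor through the tryptophan route + 4 through the
    glutamine route).
    """
    spec = spec or SyntheticSpec()
    m = MetabolicModel(id="toy_colonocyte")

    for mid in [
        "glc[e]", "glc[c]", "gln[e]", "gln[c]", "trp[e]", "trp[c]", "htrp[c]",
        "prec[c]", "atp[c]", "adp[c]", "pi[c]", "h2o[e]", "h2o[c]", "lac[c]",
        "lac[e]", "o2[e]", "o2[c]", "co2[c]", "co2[e]", "xa[e]", "xa[c]",
        "xb[c]", "xb[e]", "atp[m]", "but[e]", "but[m]", "ac[e]", "ac[m]",
        "ppa[e]", "ppa[m]",
    ]:
        m.add_metabolite(Metabolite(mid))

    ex = "Extracellular exchange"
    te = "Transport, extracellular"
    tm = "Transport, mitochondrial"
    fao = "Fatty acid oxidation"

    # environment
    _rxn(m, "EX_glc_e", {"glc[e]": -1}, -10, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_gln_e", {"gln[e]": -1}, -4, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_trp_e", {"trp[e]": -1}, -10, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_o2_e", {"o2[e]": -1}, -10, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_h2o_e", {"h2o[e]": -1}, -1000, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_lac_e", {"lac[e]": -1}, 0, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_co2_e", {"co2[e]": -1}, 0, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_xa_e", {"xa[e]": -1}, -1, DEFAULT_UB, subsystem=ex)
    _rxn(m, "EX_xb_e", {"xb[e]": -1}, 0, DEFAULT_UB, subsystem=ex)

    # core carbon and energy metabolism
    _rxn(m, "GLCt", {"glc[e]": -1, "glc[c]": 1}, 0, DEFAULT_UB,
         gpr="g_glct or g_mid1", subsystem=te)
    _rxn(m, "GLYC", {"glc[c]": -1, "adp[c]": -2, "pi[c]": -2,
                     "atp[c]": 2, "lac[c]": 2, "h2o[c]": 2}, 0, DEFAULT_UB,
         gpr="g_glyc or g_mid2", subsystem="Glycolysis", name="lumped glycolysis")
    _rxn(m, "LACt", {"lac[c]": -1, "lac[e]": 1}, -1000, DEFAULT_UB,
         gpr="g_lact or g_mid3", subsystem=te)
    _rxn(m, "RESP", {"lac[c]": -1, "o2[c]": -1, "adp[c]": -10, "pi[c]": -10,
                     "atp[c]": 10, "co2[c]": 1, "h2o[c]": 10}, 0, DEFAULT_UB,
         gpr="g_resp or g_mid4", subsystem="Oxidative phosphorylation",
         name="lumped lactate respiration")
    _rxn(m, "O2t", {"o2[e]": -1, "o2[c]": 1}, 0, DEFAULT_UB,
         gpr="g_o2t or g_mid5", subsystem=te)
    _rxn(m, "CO2t", {"co2[c]": -1, "co2[e]": 1}, 0, DEFAULT_UB,
         gpr="g_co2t or g_mid6", subsystem=te)
    _rxn(m, "H2Ot", {"h2o[e]": -1, "h2o[c]": 1}, -1000, DEFAULT_UB,
         gpr="g_aqp or g_mid11", subsystem=te)

    # SCFA uptake and lumped mitochondrial beta-oxidation
    for i, (scfa, yield_atp) in enumerate(SCFA_ATP_YIELD.items()):
        _rxn(m, f"SCFAt_{scfa}", {f"{scfa}[e]": -1, f"{scfa}[m]": 1}, 0, DEFAULT_UB,
             gpr=f"g_{scfa}t or g_mid{7 + i}", subsystem=tm)
        _rxn(m, f"BOX_{scfa}", {f"{scfa}[m]": -1, "atp[m]": yield_atp}, 0, DEFAULT_UB,
             gpr=f"g_box{scfa[0]}", subsystem=fao,
             name=f"lumped {scfa} beta-oxidation ({yield_atp} ATP)")
    _rxn(m, "ATPtm", {"atp[m]": -1, "atp[c]": 1}, 0, DEFAULT_UB,
         gpr="g_atpt or g_mid10", subsystem=tm)

    # biomass precursor routes: planted tryptophan-like route (capacity 10)
    # and constitutive glutamine route (capacity 4)
    _rxn(m, "TRPt", {"trp[e]": -1, "trp[c]": 1}, 0, DEFAULT_UB,
         gpr="g_p1", subsystem=te)
    _rxn(m, "TRPOX", {"trp[c]": -1, "htrp[c]": 1}, 0, DEFAULT_UB,
         gpr="g_p2", subsystem="Tryptophan metabolism")
    _rxn(m, "PRECP", {"htrp[c]": -1, "prec[c]": 1}, 0, DEFAULT_UB,
         gpr="g_p3", subsystem="Tryptophan metabolism")
    _rxn(m, "GLNt", {"gln[e]": -1, "gln[c]": 1}, 0, DEFAULT_UB,
         gpr="g_q1", subsystem=te)
    _rxn(m, "PRECQ", {"gln[c]": -1, "prec[c]": 1}, 0, DEFAULT_UB,
         gpr="g_q2", subsystem="Glutamine metabolism")

    # extra parallel precursor routes when requested (block of 3 reactions)
    for k in range(3, spec.n_parallel_pathways + 1):
        aa_e, aa_c = f"aa{k}[e]", f"aa{k}[c]"
        m.add_metabolite(Metabolite(aa_e))
        m.add_metabolite(Metabolite(aa_c))
        _rxn(m, f"EX_aa{k}_e", {aa_e: -1}, -4, DEFAULT_UB, subsystem=ex)
        _rxn(m, f"AAt{k}", {aa_e: -1, aa_c: 1}, 0, DEFAULT_UB,
             gpr=f"g_r{k}a", subsystem=te)
        _rxn(m, f"PREC{k}", {aa_c: -1, "prec[c]": 1}, 0, DEFAULT_UB,
             gpr=f"g_r{k}b", subsystem="Amino acid metabolism")

    # maintenance pseudo-reactions
    _rxn(m, "BIOMASS_maintenance",
         {"prec[c]": -1, "atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1},
         0, DEFAULT_UB, subsystem="Biomass", name="biomass maintenance")
    _rxn(m, "ATPM", {"atp[c]": -1, "h2o[c]": -1, "adp[c]": 1, "pi[c]": 1},
         0, DEFAULT_UB, subsystem="Miscellaneous", name="ATP hydrolysis demand")
    # open adenylate/phosphate pools: mitochondrial ATP import would otherwise
    # be frozen by strict moiety conservation (all ATP consumers return ADP)
    _rxn(m, "SK_adp_c", {"adp[c]": -1}, -1000, DEFAULT_UB, kind="sink",
         subsystem="Intracellular source/sink")
    _rxn(m, "SK_pi_c", {"pi[c]": -1}, -1000, DEFAULT_UB, kind="sink",
         subsystem="Intracellular source/sink")

    # decoy pathway under constitutively unexpressed genes
    _rxn(m, "XAt", {"xa[e]": -1, "xa[c]": 1}, 0, DEFAULT_UB,
         gpr="g_d1", subsystem=te)
    _rxn(m, "XAB", {"xa[c]": -1, "xb[c]": 1}, 0, DEFAULT_UB,
         gpr="g_d2", subsystem="Miscellaneous")
    _rxn(m, "XBt", {"xb[c]": -1, "xb[e]": 1}, 0, DEFAULT_UB,
         gpr="g_d3", subsystem=te)

    m.objective = {"BIOMASS_maintenance": 1.0}

    # gut-lumen module for the SCFAs, then the default medium
    m = add_lumen_module(m, ["but[e]", "ac[e]", "ppa[e]"], inplace=True)
    medium = dict(DEFAULT_MEDIUM)
    for k in range(3, spec.n_parallel_pathways + 1):
        medium[f"aa{k}[e]"] = 4.0
    apply_medium(m, medium, inplace=True)
    m.validate()
    return m


def gene_tier(gene: str) -> str:
    """Expression tier of a template gene (by naming convention)."""
    if gene in OFF_GENES:
        return "off"
    if gene in INTERMEDIATE_GENES:
        return "intermediate"
    return "expressed"


def make_expression(
    spec: SyntheticSpec, template: MetabolicModel
) -> ExpressionMatrix:
    """Grouped expression for the template's genes with the planted effect.

    Healthy baselines follow the gene's tier; disease samples multiply the
    planted genes by ``2**(-fold_change)`` (or set them to zero with the
    ``planted_off`` flag); every value carries multiplicative log-normal
    noise with parameter ``sigma``. Fully seed-reproducible.
    """
    genes = sorted(template.genes)
    unknown = set(spec.planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted pathway references unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    samples = [f"H{i + 1}" for i in range(spec.n_healthy)] + [
        f"D{i + 1}" for i in range(spec.n_disease)
    ]
    groups = {s: ("healthy" if s.startswith("H") else "disease") for s in samples}
    base = np.array([TIER_BASELINES[gene_tier(g)] for g in genes])
    planted_mask = np.array([g in spec.planted_genes for g in genes])
    data = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        mean = base.copy()
        if groups[s] == "disease":
            if spec.planted_off:
                mean[planted_mask] = 0.0
            else:
                mean[planted_mask] *= 2.0 ** (-spec.fold_change)
        noise = np.exp(rng.normal(0.0, spec.sigma, size=len(genes)))
        data[:, j] = mean * noise
    values = pd.DataFrame(data, index=genes, columns=samples)
    return ExpressionMatrix(values, groups)


def make_toy_microbiome(
    spec: SyntheticSpec | None = None,
) -> list[tuple[str, MetabolicModel, float]]:
    """Small SCFA-fermenting gut microbes with Dirichlet-drawn abundances.

    Each member takes up luminal glucose and ferments it to one SCFA with
    growth coupled to fermentation; every member grows on the default diet
    by itself.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed + 1)
    recipes = [
        ("butyrogen", "but", 2.0, 0.10),
        ("acetogen", "ac", 3.0, 0.12),
        ("propionogen", "ppa", 2.0, 0.08),
    ]
    members = []
    abundances = rng.dirichlet(np.ones(len(recipes)))
    for (taxon, scfa, yield_scfa, yield_x), a in zip(recipes, abundances):
        mm = MetabolicModel(id=taxon)
        for mid in ["glc[e]", "glc[c]", f"{scfa}[c]", f"{scfa}[e]", "x[c]"]:
            mm.add_metabolite(Metabolite(mid))
        _rxn(mm, "EX_glc_e", {"glc[e]": -1}, -10, 0, subsystem="Extracellular exchange")
        _rxn(mm, "GLCt", {"glc[e]": -1, "glc[c]": 1}, 0, DEFAULT_UB,
             gpr=f"{taxon}_g1", subsystem="Transport, extracellular")
        _rxn(mm, "FERM",
             {"glc[c]": -1, f"{scfa}[c]": yield_scfa, "x[c]": yield_x},
             0, DEFAULT_UB, gpr=f"{taxon}_g2", subsystem="Fermentation")
        _rxn(mm, "SCFAt", {f"{scfa}[c]": -1, f"{scfa}[e]": 1}, 0, DEFAULT_UB,
             gpr=f"{taxon}_g3", subsystem="Transport, extracellular")
        _rxn(mm, f"EX_{scfa}_e", {f"{scfa}[e]": -1}, 0, DEFAULT_UB,
             subsystem="Extracellular exchange")
        _rxn(mm, "BIOMASS", {"x[c]": -1}, 0, DEFAULT_UB, kind="demand",
             subsystem="Biomass")
        mm.objective = {"BIOMASS": 1.0}
        members.append((taxon, mm, float(a)))
    return members


def make_task_suite(template: MetabolicModel) -> tuple[list[MetabolicTask], dict[str, bool]]:
    """20-task suite for the toy template with ground-truth labels.

    18 tasks are feasible by construction (including SCFA beta-oxidation to
    ATP); 2 are negative controls (ATP from a closed model; a precursor from
    glucose, which no route provides). Returns (tasks, {task_id: feasible}).
    """
    cof = ["adp[c]", "pi[c]"]
    defs: list[tuple[str, str, list[str], list[str], bool]] = [
        ("T01", "glycolytic lactate from glucose", ["glc[e]"] + cof, ["lac[c]"], True),
        ("T02", "butyrate beta-oxidation to cytosolic ATP", ["but[lu]"], ["atp[c]"], True),
        ("T03", "acetate beta-oxidation to cytosolic ATP", ["ac[lu]"], ["atp[c]"], True),
        ("T04", "propionate beta-oxidation to cytosolic ATP", ["ppa[lu]"], ["atp[c]"], True),
        ("T05", "butyrate beta-oxidation to mitochondrial ATP", ["but[lu]"], ["atp[m]"], True),
        ("T06", "glycolytic ATP from glucose", ["glc[e]"] + cof, ["atp[c]"], True),
        ("T07", "tryptophan hydroxylation", ["trp[e]"], ["htrp[c]"], True),
        ("T08", "biomass precursor from tryptophan", ["trp[e]"], ["prec[c]"], True),
        ("T09", "biomass precursor from glutamine", ["gln[e]"], ["prec[c]"], True),
        ("T10", "lactate secretion from glucose", ["glc[e]"] + cof, ["lac[e]"], True),
        ("T11", "lactate respiration to CO2", ["lac[e]", "o2[e]"] + cof, ["co2[c]"], True),
        ("T12", "xenobiotic conversion", ["xa[e]"], ["xb[e]"], True),
        ("T13", "aerobic glucose oxidation to CO2", ["glc[e]", "o2[e]"] + cof, ["co2[c]"], True),
        ("T14", "luminal butyrate transport", ["but[lu]"], ["but[e]"], True),
        ("T15", "luminal acetate into mitochondria", ["ac[lu]"], ["ac[m]"], True),
        ("T16", "precursor from mixed amino acids", ["gln[e]", "trp[e]"], ["prec[c]"], True),
        ("T17", "water permeation", ["h2o[e]"], ["h2o[c]"], True),
        ("T18", "precursor on rich substrate", ["glc[e]", "gln[e]", "trp[e]"] + cof,
         ["prec[c]"], True),
        ("T19", "ATP from a closed network (negative control)", [], ["atp[c]"], False),
        ("T20", "precursor from glucose (negative control)", ["glc[e]"] + cof,
         ["prec[c]"], False),
    ]
    tasks = [
        MetabolicTask(tid, description=desc, inputs=ins, outputs=outs)
        for tid, desc, ins, outs, _ in defs
    ]
    labels = {tid: feasible for tid, _, _, _, feasible in defs}
    return tasks, labels


@dataclass
class GroundTruth:
    """What the generator planted; used by recovery tests and reports."""

    planted_genes: tuple[str, ...]
    planted_reactions: tuple[str, ...]
    off_genes: tuple[str, ...] = OFF_GENES
    decoy_reactions: tuple[str, ...] = ("XAt", "XAB", "XBt")


def ground_truth(spec: SyntheticSpec | None = None) -> GroundTruth:
    spec = spec or SyntheticSpec()
    return GroundTruth(tuple(spec.planted_genes), tuple(spec.planted_reactions))
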