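"""Disease case-study pipeline: per-sample context models, FVA-maxima group
tests, knockout volcano statistics and medium direction-consistency checks.

Given a template model and a grouped (healthy/disease) expression matrix,
each sample is integrated separately with iMAT to yield a context-specific
model. Group comparisons then run on per-sample quantities: Student's
t-tests on FVA maxima per reaction, and on single-gene knockout effect
ratios (WT-KO)/WT per gene, summarized volcano-style as
log2(disease mean / healthy mean) against the t-test p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MetabolicModel
from .extraction import (
    DEFAULT_EPS,
    DEFAULT_PERCENTILE,
    ExpressionMatrix,
    expression_cutoff,
    gene_activity,
    imat_extract,
    reaction_scores,
)
from .lp import DEFAULT_TOL, classify_exchange, fva, FluxRange, knockout_screen

logger = logging.getLogger("colongem")

DEFAULT_ALPHA = 0.05


@dataclass
class GroupedStudy:
    """Template + grouped expression + one context model per sample."""

    template: MetabolicModel
    expression: ExpressionMatrix
    groups: dict[str, str]  # sample -> healthy | disease
    context_models: dict[str, MetabolicModel] = field(default_factory=dict)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.expression.samples if self.groups[s] == group]


def build_context_models(
    template: MetabolicModel,
    expression: ExpressionMatrix,
    groups: dict[str, str] | None = None,
    percentile: float = DEFAULT_PERCENTILE,
    eps: float = DEFAULT_EPS,
    cutoff_mode: str = "per_sample",
) -> GroupedStudy:
    """One iMAT extraction per sample.

    The expression cutoff is computed within each sample by default
    (``cutoff_mode='per_sample'``); ``'global'`` shares one cutoff computed
    over the whole matrix. Deterministic for fixed inputs.
    """
    groups = dict(groups or expression.groups)
    missing = [s for s in expression.samples if s not in groups]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    if not set(expression.genes) & template.genes:
        raise ValueError("expression matrix shares no genes with the template")
    study = GroupedStudy(template, expression, groups)
    global_cutoff = (
        expression_cutoff(expression, percentile) if cutoff_mode == "global" else None
    )
    for sample in expression.samples:
        col = expression.sample_column(sample)
        if not np.any(col.values.to_numpy() > 0):
            raise ValueError(f"sample {sample!r} has all-zero expression")
        cutoff = global_cutoff if global_cutoff is not None else expression_cutoff(
            col, percentile
        )
        activity = gene_activity(col, cutoff)
        scores = reaction_scores(template, activity)
        result = imat_extract(template, scores, eps=eps)
        if result.context is None:
            raise RuntimeError(f"iMAT infeasible for sample {sample!r}")
        result.context.id = f"{template.id}__{sample}"
        study.context_models[sample] = result.context
    return study


def _group_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Equal-variance two-sample t-test with explicit degenerate handling.

    Returns (t, p, degenerate). When the pooled variance vanishes, p is 1
    for equal means and 0 otherwise (infinite t), both flagged degenerate.
    """
    if np.var(a, ddof=0) == 0.0 and np.var(b, ddof=0) == 0.0:
        if math.isclose(a.mean(), b.mean(), rel_tol=0, abs_tol=1e-12):
            return 0.0, 1.0, True
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0, True
    import warnings

    with warnings.catch_warnings():
        # near-identical per-sample values are routine for context models
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), False


@dataclass
class ReactionGroupTest:
    reaction_id: str
    subsystem: str
    mean_healthy: float
    mean_disease: float
    t_statistic: float
    p_value: float
    p_adjusted: float = math.nan
    degenerate: bool = False


def compare_fva_max(
    study: GroupedStudy,
    fraction_of_optimum: float = 0.0,
    alpha: float = DEFAULT_ALPHA,
) -> list[ReactionGroupTest]:
    """Per-reaction Student's t-test on FVA maxima between the groups.

    Only reactions present in at least two context models per group are
    tested. Raw p-values carry the headline significance call (no
    multiplicity correction); a Benjamini-Hochberg-adjusted column is
    emitted alongside.
    """
    healthy = study.samples_in("healthy")
    disease = study.samples_in("disease")
    if len(healthy) < 2 or len(disease) < 2:
        raise ValueError("need at least two samples per group")

    maxima: dict[str, dict[str, float]] = {}
    for sample, model in study.context_models.items():
        for rng in fva(model, fraction_of_optimum=fraction_of_optimum):
            maxima.setdefault(rng.reaction_id, {})[sample] = rng.max_flux

    tests = []
    for rid, per_sample in maxima.items():
        h = np.array([per_sample[s] for s in healthy if s in per_sample])
        d = np.array([per_sample[s] for s in disease if s in per_sample])
        if len(h) < 2 or len(d) < 2:
            logger.info("reaction %s present in <2 models per group; skipped", rid)
            continue
        t, p, degenerate = _group_ttest(d, h)
        tests.append(
            ReactionGroupTest(
                reaction_id=rid,
                subsystem=study.template.reactions[rid].subsystem
                if rid in study.template.reactions
                else "",
                mean_healthy=float(h.mean()),
                mean_disease=float(d.mean()),
                t_statistic=t,
                p_value=p,
                degenerate=degenerate,
            )
        )
    _bh_adjust(tests)
    return sorted(tests, key=lambda r: r.p_value)


def _bh_adjust(tests) -> None:
    """Benjamini-Hochberg adjusted p-values, written in place."""
    m = len(tests)
    if not m:
        return
    order = sorted(range(m), key=lambda i: tests[i].p_value)
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        adj = min(prev, tests[i].p_value * m / rank)
        tests[i].p_adjusted = adj
        prev = adj


@dataclass
class GroupKnockoutStat:
    gene_id: str
    mean_ratio_healthy: float
    mean_ratio_disease: float
    log2_ratio: float  # log2(disease mean / healthy mean); +-inf when one mean is 0
    p_value: float
    effect_size: float  # mean ratio across all samples
    undefined: bool = False  # healthy mean 0 with disease mean > 0 (outlier rule)
    infinite: bool = False
    degenerate_test: bool = False


def knockout_volcano(
    study: GroupedStudy,
    target: str = "BIOMASS_maintenance",
    genes: list[str] | None = None,
) -> list[GroupKnockoutStat]:
    """Single-gene knockout effects compared between the groups.

    Per sample, each gene's knockout effect is (WT-KO)/WT on the target's
    maximum flux in that sample's context model; genes absent from a context
    model score 0 there (their reactions are already excluded). The volcano
    coordinates are log2(disease mean / healthy mean) and the two-sample
    t-test p-value on the per-sample ratios. A gene whose healthy mean is 0
    while the disease mean is positive has no finite, sign-stable log2 ratio
    and is flagged ``undefined`` (excluded from plot tables); a zero disease
    mean is kept as -inf, flagged ``infinite``.
    """
    gene_list = sorted(study.template.genes) if genes is None else list(genes)
    healthy = study.samples_in("healthy")
    disease = study.samples_in("disease")

    ratios: dict[str, dict[str, float]] = {g: {} for g in gene_list}
    for sample, model in study.context_models.items():
        model_genes = model.genes
        present = [g for g in gene_list if g in model_genes]
        if target not in model.reactions:
            raise ValueError(f"target {target!r} missing from context model {model.id}")
        records = {
            r.gene_id: r for r in knockout_screen(model, present, target)
        }
        for g in gene_list:
            rec = records.get(g)
            if rec is None:
                ratios[g][sample] = 0.0
            elif rec.ratio is None:
                ratios[g][sample] = math.nan
            else:
                ratios[g][sample] = rec.ratio

    out = []
    for g in gene_list:
        h = np.array([ratios[g][s] for s in healthy])
        d = np.array([ratios[g][s] for s in disease])
        if np.isnan(h).any() or np.isnan(d).any():
            logger.warning("gene %s: undefined knockout ratio in some sample", g)
            h, d = np.nan_to_num(h), np.nan_to_num(d)
        mh, md = float(h.mean()), float(d.mean())
        undefined = infinite = False
        if mh <= 0.0 and md > 0.0:
            log2_ratio, undefined = math.nan, True
        elif md <= 0.0 and mh > 0.0:
            log2_ratio, infinite = -math.inf, True
        elif mh <= 0.0 and md <= 0.0:
            log2_ratio = 0.0
        else:
            log2_ratio = math.log2(md / mh)
        t, p, degenerate = _group_ttest(d, h)
        out.append(
            GroupKnockoutStat(
                gene_id=g,
                mean_ratio_healthy=mh,
                mean_ratio_disease=md,
                log2_ratio=log2_ratio,
                p_value=p,
                effect_size=float(np.concatenate([h, d]).mean()),
                undefined=undefined,
                infinite=infinite,
                degenerate_test=degenerate,
            )
        )
    return out


def volcano_to_frame(stats_: list[GroupKnockoutStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene_id,
                "log2_ratio": s.log2_ratio,
                "p_value": s.p_value,
                "effect_size": s.effect_size,
                "mean_ratio_healthy": s.mean_ratio_healthy,
                "mean_ratio_disease": s.mean_ratio_disease,
                "undefined": s.undefined,
            }
            for s in stats_
        ]
    )


def tests_to_frame(tests: list[ReactionGroupTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction": t.reaction_id,
                "subsystem": t.subsystem,
                "mean_healthy": t.mean_healthy,
                "mean_disease": t.mean_disease,
                "t": t.t_statistic,
                "p_value": t.p_value,
                "p_adjusted": t.p_adjusted,
            }
            for t in tests
        ]
    )


# ---------------------------------------------------------------------------
# Medium direction-consistency check
# ---------------------------------------------------------------------------


@dataclass
class DirectionConsistency:
    metabolite: str
    observed: str  # uptake | secretion
    predicted: str  # uptake_only | secretion_only | both | inactive
    consistent: bool
    percent_change: float | None  # (before - after) / before * 100


def direction_consistency(
    fva_ranges: dict[str, FluxRange] | list[FluxRange],
    medium_before: dict[str, float],
    medium_after: dict[str, float],
    tol: float = DEFAULT_TOL,
) -> list[DirectionConsistency]:
    """Compare observed medium concentration changes with FVA directions.

    A metabolite whose concentration rose is observed as secreted and is
    consistent when the exchange FVA maximum is positive; a fall is observed
    uptake and needs a negative FVA minimum. Percent change is
    (before - after)/before * 100, undefined (None) when before is 0.
    """
    if not isinstance(fva_ranges, dict):
        fva_ranges = {r.reaction_id: r for r in fva_ranges}
    out = []
    for met, before in medium_before.items():
        if met not in medium_after or met not in fva_ranges:
            continue
        after = medium_after[met]
        rng = fva_ranges[met]
        observed = "secretion" if after > before else "uptake"
        if observed == "uptake":
            consistent = rng.min_flux < -tol
        else:
            consistent = rng.max_flux > tol
        pct = None if before == 0 else (before - after) / before * 100.0
        out.append(
            DirectionConsistency(
                metabolite=met,
                observed=observed,
                predicted=classify_exchange(rng, tol),
                consistent=bool(consistent),
                percent_change=pct,
            )
        )
    return out


#: Bundled reference dataset: targeted metabolomics of Caco-2 spent culture
#: medium (concentration in the fresh DMEM+FBS medium vs after 2 days of
#: culture, ng/uL) together with the exchange-reaction FVA flux ranges of a
#: colonocyte reconstruction constrained to that medium. Negative minimum
#: flux = the network can take the metabolite up; positive maximum = it can
#: secrete it.
CACO2_REFERENCE = pd.DataFrame(
    [
        # metabolite, medium_before (fresh), medium_after (spent), fva_min, fva_max
        ("Butyrate", 0.06, 0.04, -1.0, 0.0),
        ("Acetate", 18.43, 8.49, -1.0, 42.15),
        ("Propionate", 17.02, 3.45, -1.0, 24.50),
        ("Alanine", 12.55, 116.28, -1.0, 21.03),
        ("Arginine", 110.89, 53.93, -1.0, 5.56),
        ("Cysteine", 0.02, 0.13, -1.0, 2.0),
        ("Glutamine", 172.48, 62.10, -1.0, 10.13),
        ("Glutamate", 8.15, 1.31, -1.0, 16.60),
        ("Histidine", 43.28, 54.82, -1.0, 0.0),
        ("Isoleucine", 214.70, 91.51, -1.0, 0.0),
        ("Leucine", 176.23, 55.22, -1.0, 0.0),
        ("Lysine", 160.63, 110.97, -1.0, 0.0),
        ("Methionine", 91.39, 47.36, -1.0, 0.0),
        ("Phenylalanine", 3372.22, 1724.69, -1.0, 0.0),
        ("Proline", 7.80, 40.61, -1.0, 16.78),
        ("Serine", 42.08, 20.23, -1.0, 8.97),
        ("Threonine", 54.92, 34.82, -1.0, 0.0),
        ("Tryptophan", 22.94, 12.43, -1.0, 0.0),
        ("Tyrosine", 667.66, 329.51, -1.0, 1.0),
        ("Valine", 260.68, 115.72, -1.0, 0.0),
        ("Glycine", 20.84, 28.90, -1.0, 18.74),
    ],
    columns=["metabolite", "before", "after", "fva_min", "fva_max"],
)


def caco2_consistency(tol: float = DEFAULT_TOL) -> list[DirectionConsistency]:
    """Direction-consistency table for the bundled Caco-2 reference data."""
    ranges = {
        row.metabolite: FluxRange(row.metabolite, row.fva_min, row.fva_max)
        for row in CACO2_REFERENCE.itertuples()
    }
    before = dict(zip(CACO2_REFERENCE.metabolite, CACO2_REFERENCE.before))
    after = dict(zip(CACO2_REFERENCE.metabolite, CACO2_REFERENCE.after))
    return direction_consistency(ranges, before, after, tol=tol)
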