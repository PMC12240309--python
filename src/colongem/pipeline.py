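"""End-to-end pipeline runner and configuration.

A pipeline run executes, in order and only for the stages its configuration
enables: consensus merge -> lumen module -> medium -> sanity/task validation
-> per-sample context extraction -> FVA group comparison / knockout volcano
/ flux sampling -> community optimization. Every output lands in a run
directory stamped with the seed and a hash of the resolved configuration;
rerunning the same configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, disease, extraction, sampling, synth, validation
from .community import (
    build_community,
    cooperative_tradeoff,
    directional_lists,
    exchange_accounting,
)
from .lp import fva, ranges_to_frame

logger = logging.getLogger("colongem")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    percentile: float = 30.0
    eps: float = 1.0
    fva_fraction: float = 0.0
    thinning: int = 1000
    n_samples: int = 0
    alpha: float = 0.05
    tradeoff_fraction: float = 0.5
    tolerance: float = 1e-6
    unit: str = "mmol/gDW/h"
    cutoff_mode: str = "per_sample"

    # inputs; a stage without its inputs is skipped
    synthetic: bool = False  # generate template/expression/tasks/microbiome
    template: str | None = None
    drafts: dict[str, str] = field(default_factory=dict)  # label -> path
    exclude_unique_from: str | None = None
    expression: str | None = None
    groups: str | None = None
    tasks: str | None = None
    lumen_metabolites: str | None = None
    medium: str | None = None
    abundances: str | None = None
    member_models: dict[str, str] = field(default_factory=dict)
    diet: str | None = None
    sample_reactions: list[str] = field(default_factory=list)
    run_sanity: bool = True
    run_community: bool = False

    def __post_init__(self):
        if not (0 <= self.percentile <= 100):
            raise ValueError("percentile must be in [0, 100]")
        if not (0 <= self.fva_fraction <= 1):
            raise ValueError("fva_fraction must be in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.tradeoff_fraction <= 1):
            raise ValueError("tradeoff_fraction must be in [0, 1]")
        if self.thinning < 1 or self.n_samples < 0:
            raise ValueError("thinning must be >= 1 and n_samples >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _read_tsv_map(path, value_col=1) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, value_col].astype(float)))


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    (out / "run.json").write_text(
        json.dumps({"seed": config.seed, "config_hash": config.hash()}, indent=1) + "\n"
    )
    logger.info("pipeline run %s (seed %d)", config.hash(), config.seed)

    spec = synth.SyntheticSpec(seed=config.seed)

    # --- template acquisition -------------------------------------------
    stage = "template"
    try:
        if config.drafts:
            drafts = [
                (label, core.load_model(path)) for label, path in config.drafts.items()
            ]
            template_model = (
                core.load_model(config.template) if config.template else None
            )
            model = core.merge_consensus(
                drafts, config.exclude_unique_from, template=template_model
            )
        elif config.template:
            model = core.load_model(config.template)
        elif config.synthetic:
            model = synth.make_toy_template(spec)
        else:
            raise ValueError("no template, drafts, or synthetic flag configured")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "lumen"
    try:
        if config.lumen_metabolites:
            mets = [
                line.strip()
                for line in Path(config.lumen_metabolites).read_text().splitlines()
                if line.strip()
            ]
            model = core.add_lumen_module(model, mets)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "medium"
    try:
        if config.medium:
            model = core.apply_medium(model, _read_tsv_map(config.medium))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    core.write_model(model, out / "model.json")

    # --- validation ------------------------------------------------------
    stage = "validate"
    try:
        tasks = None
        if config.tasks:
            tasks = validation.load_tasks(config.tasks)
        elif config.synthetic:
            tasks, _ = synth.make_task_suite(model)
        if config.run_sanity:
            report = validation.sanity_report(model, tasks, tol=config.tolerance)
            (out / "sanity_report.json").write_text(json.dumps(report, indent=1) + "\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- context extraction and disease statistics -----------------------
    study = None
    stage = "extract"
    try:
        expr = None
        if config.expression:
            expr = extraction.load_expression(config.expression, config.groups)
        elif config.synthetic:
            expr = synth.make_expression(spec, model)
        if expr is not None and expr.groups:
            study = disease.build_context_models(
                model,
                expr,
                percentile=config.percentile,
                eps=config.eps,
                cutoff_mode=config.cutoff_mode,
            )
            for sample, ctx in study.context_models.items():
                core.write_model(ctx, out / f"context_{sample}.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if study is not None:
        stage = "fva_compare"
        try:
            tests = disease.compare_fva_max(study, config.fva_fraction, config.alpha)
            disease.tests_to_frame(tests).to_csv(out / "fva_group_tests.csv", index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = "knockout"
        try:
            vol = disease.knockout_volcano(study)
            disease.volcano_to_frame(vol).to_csv(out / "knockout_volcano.csv", index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = "sample"
        try:
            if config.n_samples > 0:
                _sampling_stage(study, config, out)
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        stage = "fva"
        try:
            ranges = fva(model, fraction_of_optimum=config.fva_fraction)
            ranges_to_frame(ranges).to_csv(out / "fva_ranges.csv", index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- community -------------------------------------------------------
    stage = "community"
    try:
        if config.run_community:
            host = core.add_lumen_module(model, ["glc[e]"]) \
                if "glc[lu]" not in model.metabolites else model
            if config.member_models:
                abund = _read_tsv_map(config.abundances) if config.abundances else {}
                members = [
                    (taxon, core.load_model(path), abund.get(taxon, 1.0))
                    for taxon, path in config.member_models.items()
                ]
            else:
                members = synth.make_toy_microbiome(spec)
            diet = _read_tsv_map(config.diet) if config.diet else {"glc[lu]": 10.0}
            com = build_community(host, members, diet=diet)
            sol = cooperative_tradeoff(com, config.tradeoff_fraction)
            accounts = exchange_accounting(sol)
            pd.DataFrame(
                [dataclasses.asdict(a) for a in accounts]
            ).to_csv(out / "exchange_accounting.csv", index=False)
            summary = {
                "status": sol.status,
                "host_biomass_flux": sol.host_biomass_flux,
                "community_growth": sol.community_growth,
                "member_growth": sol.member_growth,
                "directional_lists": directional_lists(accounts),
                "unit": config.unit,
            }
            (out / "community.json").write_text(json.dumps(summary, indent=1) + "\n")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    logger.info("pipeline complete: %s", out)
    return out


def _sampling_stage(study, config: PipelineConfig, out: Path) -> None:
    """ACHR-sample each context model and KS-compare groups per reaction."""
    rxn_filter = config.sample_reactions or None
    pooled: dict[str, dict[str, list[np.ndarray]]] = {}
    for sample, ctx in study.context_models.items():
        import zlib

        ss = sampling.achr_sample(
            ctx, config.n_samples, thinning=config.thinning,
            seed=(config.seed + zlib.crc32(sample.encode())) % (2**31),
        )
        ss.to_frame().to_csv(out / f"samples_{sample}.csv", index=False)
        group = study.groups[sample]
        for rid in ss.reactions:
            if rxn_filter is not None and rid not in rxn_filter:
                continue
            pooled.setdefault(rid, {}).setdefault(group, []).append(ss.column(rid))
    rows = []
    for rid, by_group in pooled.items():
        if "healthy" in by_group and "disease" in by_group:
            a = np.concatenate(by_group["healthy"])
            b = np.concatenate(by_group["disease"])
            d, p = sampling.ks_compare(a, b)
            rows.append({"reaction": rid, "D": d, "p_value": p})
    pd.DataFrame(rows).to_csv(out / "sampling_ks.csv", index=False)
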