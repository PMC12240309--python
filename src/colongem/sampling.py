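"""Artificially centered hit-and-run (ACHR) flux sampling.

ACHR explores the steady-state flux polytope {v : S v = 0, lb <= v <= ub}.
Warmup points are the FVA extreme flux vectors (two per reaction, capped);
each step draws a direction from the current point toward a random warmup
point relative to the running center, computes the feasible step interval
from the box bounds, and moves a uniform random distance. Recording every
``thinning``-th state decorrelates successive samples. Directions are
differences of feasible points, so every state stays on S v = 0; a periodic
least-squares reprojection removes accumulated floating-point drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .core import MetabolicModel, build_system
from .lp import _solve_lp

logger = logging.getLogger("colongem")

DEFAULT_THINNING = 1000
#: warmup points: min(2 * n_reactions, WARMUP_CAP)
WARMUP_CAP = 2000
_DIR_TOL = 1e-12
_REPROJECT_EVERY = 1000


@dataclass
class FluxSampleSet:
    """n_samples x n_reactions matrix of steady-state flux vectors."""

    reactions: list[str]
    samples: np.ndarray
    seed: int
    thinning: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=self.reactions)

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reactions.index(reaction_id)]


def _warmup_points(system, cap: int) -> np.ndarray:
    n = len(system.lb)
    points = []
    order = list(range(n))
    for j in order:
        if 2 * len(points) >= 2 * cap:
            break
        c = np.zeros(n)
        c[j] = 1.0
        for maximize in (False, True):
            if len(points) >= cap:
                break
            res = _solve_lp(system, c, maximize=maximize)
            if res.status == 0:
                points.append(res.x)
    if not points:
        raise RuntimeError("model infeasible: no warmup points")
    return np.asarray(points)


def achr_sample(
    model: MetabolicModel,
    n_samples: int,
    thinning: int = DEFAULT_THINNING,
    seed: int | None = None,
) -> FluxSampleSet:
    """Draw ``n_samples`` steady-state flux vectors with ACHR.

    Seeded and reproducible: the same seed yields identical matrices. A
    degenerate polytope (single feasible point) returns that point for every
    sample with a warning.
    """
    system = build_system(model)
    rng = np.random.default_rng(seed)
    n = len(system.lb)
    warmup = _warmup_points(system, cap=min(2 * n, WARMUP_CAP))
    center = warmup.mean(axis=0)

    spread = warmup.max(axis=0) - warmup.min(axis=0)
    if np.all(spread < 1e-9):
        logger.warning("degenerate flux polytope: returning the single point")
        samples = np.tile(warmup[0], (n_samples, 1))
        return FluxSampleSet(list(system.reactions), samples, seed or 0, thinning)

    # precompute the range-space projector for drift removal
    pinv_S = np.linalg.pinv(system.S)

    x = center.copy()
    n_kept = 0
    n_visited = warmup.shape[0]
    samples = np.empty((n_samples, n), dtype=float)
    lb, ub = system.lb, system.ub
    step = 0
    while n_kept < n_samples:
        w = warmup[rng.integers(warmup.shape[0])]
        direction = w - center
        norm = np.linalg.norm(direction)
        if norm < _DIR_TOL:
            continue
        direction = direction / norm
        # feasible step interval from the box bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_steps = (lb - x) / direction
            hi_steps = (ub - x) / direction
        pos = direction > _DIR_TOL
        neg = direction < -_DIR_TOL
        alpha_max = np.inf
        alpha_min = -np.inf
        if pos.any():
            alpha_max = min(alpha_max, hi_steps[pos].min())
            alpha_min = max(alpha_min, lo_steps[pos].max())
        if neg.any():
            alpha_max = min(alpha_max, lo_steps[neg].min())
            alpha_min = max(alpha_min, hi_steps[neg].max())
        if not np.isfinite(alpha_max) or not np.isfinite(alpha_min) or alpha_max < alpha_min:
            continue
        alpha = rng.uniform(alpha_min, alpha_max)
        x = x + alpha * direction
        step += 1
        if step % _REPROJECT_EVERY == 0:
            x = x - pinv_S @ (system.S @ x)
            np.clip(x, lb, ub, out=x)
        # running (artificial) center over all visited states
        center = (center * n_visited + x) / (n_visited + 1)
        n_visited += 1
        if step % max(thinning, 1) == 0:
            samples[n_kept] = x
            n_kept += 1
    return FluxSampleSet(list(system.reactions), samples, seed or 0, thinning)


def ks_compare(
    samples_a: FluxSampleSet | np.ndarray,
    samples_b: FluxSampleSet | np.ndarray,
    reaction: str | None = None,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of one reaction's flux law.

    Returns (D, p) where D = sup |ECDF_A - ECDF_B| with the asymptotic
    p-value.
    """
    a = samples_a.column(reaction) if isinstance(samples_a, FluxSampleSet) else np.asarray(samples_a)
    b = samples_b.column(reaction) if isinstance(samples_b, FluxSampleSet) else np.asarray(samples_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_compare needs at least two values per side")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
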