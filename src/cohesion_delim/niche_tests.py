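"""Schoener's D overlap and the niche equivalency / similarity randomizations.

The equivalency (identity) test pools the two lineages' occurrences, randomly
repartitions them at the observed sample sizes, and refits both models per
replicate; a significantly *low* observed D rejects niche identity
(one-tailed).  The similarity (background) test refits one side from random
cells of the other lineage's background region; an observed D above the upper
null quantile indicates niche conservatism, below the lower quantile niche
divergence (two-tailed).

Replicate fits reuse the feature class and regularization multiplier selected
for the observed models (full per-replicate reselection is available via
``FitConfig.reselect_per_rep``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .backgrounds import BackgroundRegion, mcp_region, threshold_region
from .climate_prep import RasterStack
from .sdm import (
    CellFeatureContext,
    FitConfig,
    SuitabilitySurface,
    fit_sdm,
    sample_background,
    thin_occurrences,
    occurrence_cells,
)
from .synthetic_data import OccurrenceSet

__all__ = [
    "NicheTestResult",
    "schoener_d",
    "equivalency_test",
    "similarity_test",
    "run_pairwise_battery",
    "merge_occurrences",
]


@dataclass
class NicheTestResult:
    kind: str  # "equivalency" | "similarity"
    direction: str
    observed_d: float
    null_d: np.ndarray
    p_lower: float
    p_upper: float
    outcome: str
    n_reps: int
    seed: int
    alpha: float
    meta: dict = field(default_factory=dict)


def schoener_d(a: SuitabilitySurface, b: SuitabilitySurface) -> float:
    """``D = 1 - 0.5 * sum_i |p_A,i - p_B,i|`` over shared non-missing cells."""
    if a.raw.shape != b.raw.shape or not np.array_equal(a.mask, b.mask):
        raise ValueError("surfaces must share grid and missing mask")
    pa = a.raw[a.mask]
    pb = b.raw[b.mask]
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def _d_vec(pa: np.ndarray, pb: np.ndarray) -> float:
    return float(1.0 - 0.5 * np.abs(pa / pa.sum() - pb / pb.sum()).sum())


def merge_occurrences(sets: Sequence[OccurrenceSet], label: str | None = None) -> OccurrenceSet:
    """Concatenate lineages into one labelled set (e.g. ``Central+South``)."""
    label = label or "+".join(s.lineage for s in sets)
    return OccurrenceSet(
        lineage=label,
        x=np.concatenate([s.x for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        provenance={"merged_from": [s.lineage for s in sets]},
    )


def equivalency_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    stack: RasterStack,
    fit_config: FitConfig | None = None,
    n_reps: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> NicheTestResult:
    """One-tailed niche identity test by pooling and repartitioning occurrences.

    ``p_lower = (1 + #{null D <= observed D}) / (n_reps + 1)``; niches are
    declared non-identical when ``p_lower < alpha``.
    """
    if n_reps < 19:
        raise ValueError("n_reps must be >= 19 for a meaningful test")
    config = fit_config or FitConfig()
    rng = np.random.default_rng(seed)

    thin_a = thin_occurrences(occ_a, stack)
    thin_b = thin_occurrences(occ_b, stack)
    n_bg = min(config.n_background, stack.n_valid)
    bg = sample_background(stack, n_bg, seed=seed)

    model_a, surf_a, _ = fit_sdm(thin_a, stack, config, background_cells=bg)
    model_b, surf_b, _ = fit_sdm(thin_b, stack, config, background_cells=bg)
    observed = schoener_d(surf_a, surf_b)

    cells_a = occurrence_cells(thin_a, stack)
    cells_b = occurrence_cells(thin_b, stack)
    pooled = np.concatenate([cells_a, cells_b])
    n_a, n_b = cells_a.size, cells_b.size

    contexts = {
        fc: CellFeatureContext(stack, bg, fc, config.hinge_knots)
        for fc in {model_a.fc, model_b.fc}
    }
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(pooled.size)
        rep_a = np.unique(pooled[perm[:n_a]])
        rep_b = np.unique(pooled[perm[n_a:]])
        if config.reselect_per_rep:
            ra = _select_raw(rep_a, stack, bg, config)
            rb = _select_raw(rep_b, stack, bg, config)
        else:
            ctx_a, ctx_b = contexts[model_a.fc], contexts[model_b.fc]
            beta_a, _ = ctx_a.fit(rep_a, model_a.rm, config.max_iter, config.tol)
            beta_b, _ = ctx_b.fit(rep_b, model_b.rm, config.max_iter, config.tol)
            ra = ctx_a.raw_surface_vector(beta_a)
            rb = ctx_b.raw_surface_vector(beta_b)
        null[r] = _d_vec(ra, rb)

    p_lower = (1 + np.sum(null <= observed)) / (n_reps + 1)
    p_upper = (1 + np.sum(null >= observed)) / (n_reps + 1)
    outcome = "not_equivalent" if p_lower < alpha else "not_significant"
    return NicheTestResult(
        kind="equivalency",
        direction=f"{occ_a.lineage}-vs-{occ_b.lineage}",
        observed_d=observed,
        null_d=null,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        outcome=outcome,
        n_reps=n_reps,
        seed=seed,
        alpha=alpha,
        meta={
            "n_a": n_a,
            "n_b": n_b,
            "fc_a": model_a.fc,
            "rm_a": model_a.rm,
            "fc_b": model_b.fc,
            "rm_b": model_b.rm,
        },
    )


def _select_raw(cells: np.ndarray, stack, bg, config) -> np.ndarray:
    """Full candidate-grid selection for one replicate (slow path)."""
    from .sdm import SDMModel, select_model, _fit_maxent_l1  # noqa: F401

    best_raw, best_aicc = None, np.inf
    for fc in config.fc_grid:
        ctx = CellFeatureContext(stack, bg, fc, config.hinge_knots)
        F_pres = ctx.features_at(cells)
        for rm in config.rm_grid:
            beta, conv = ctx.fit(cells, rm, config.max_iter, config.tol)
            if not conv:
                continue
            raw = ctx.raw_surface_vector(beta)
            k = int(np.sum(np.abs(beta) > 1e-8))
            n = cells.size
            if n - k - 1 <= 0:
                continue
            lnl = float(np.log(raw[ctx._pos[cells]]).sum())
            aicc = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
            if aicc < best_aicc:
                best_aicc, best_raw = aicc, raw
    if best_raw is None:
        raise RuntimeError("no valid replicate model")
    return best_raw


def similarity_test(
    surface_a: SuitabilitySurface,
    occ_b: OccurrenceSet,
    region_b: BackgroundRegion,
    stack: RasterStack,
    fit_config: FitConfig | None = None,
    n_reps: int = 99,
    alpha_per_tail: float = 0.025,
    seed: int = 0,
    surface_b: SuitabilitySurface | None = None,
    model_b=None,
) -> NicheTestResult:
    """Two-tailed background test of lineage A's niche against B's background.

    Observed D compares ``surface_a`` with B's SDM; each replicate draws
    ``n_b`` cells uniformly without replacement from ``region_b`` and refits
    B's model from those pseudo-occurrences.  Outcome: conservatism if the
    observed D exceeds the upper ``1 - alpha_per_tail`` null quantile,
    divergence if below the ``alpha_per_tail`` quantile, else not significant.
    """
    if n_reps < 39:
        raise ValueError("n_reps must be >= 39 for a two-tailed test at 0.025")
    config = fit_config or FitConfig()
    rng = np.random.default_rng(seed)

    thin_b = thin_occurrences(occ_b, stack)
    n_b = len(thin_b)
    if region_b.cells.size < n_b:
        raise ValueError(
            f"background region has {region_b.cells.size} cells but {n_b} are needed"
        )
    if surface_b is None or model_b is None:
        n_bg = min(config.n_background, stack.n_valid)
        bg = sample_background(stack, n_bg, seed=seed)
        model_b, surface_b, _ = fit_sdm(thin_b, stack, config, background_cells=bg)
    observed = schoener_d(surface_a, surface_b)

    ctx = CellFeatureContext(stack, model_b.background_cells, model_b.fc, config.hinge_knots)
    pa = surface_a.raw[surface_a.mask]
    null = np.empty(n_reps)
    for r in range(n_reps):
        pseudo = rng.choice(region_b.cells, size=n_b, replace=False)
        beta, _ = ctx.fit(pseudo, model_b.rm, config.max_iter, config.tol)
        null[r] = _d_vec(pa, ctx.raw_surface_vector(beta))

    p_lower = (1 + np.sum(null <= observed)) / (n_reps + 1)
    p_upper = (1 + np.sum(null >= observed)) / (n_reps + 1)
    if observed > np.quantile(null, 1 - alpha_per_tail):
        outcome = "conservatism"
    elif observed < np.quantile(null, alpha_per_tail):
        outcome = "divergence"
    else:
        outcome = "not_significant"
    return NicheTestResult(
        kind="similarity",
        direction=f"{surface_a.meta.get('lineage', 'A')}-vs-background-{occ_b.lineage}",
        observed_d=observed,
        null_d=null,
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        outcome=outcome,
        n_reps=n_reps,
        seed=seed,
        alpha=alpha_per_tail,
        meta={"n_b": n_b, "region_method": region_b.method, "fc_b": model_b.fc, "rm_b": model_b.rm},
    )


def run_pairwise_battery(
    occurrences: Mapping[str, OccurrenceSet],
    stack: RasterStack,
    fit_config: FitConfig | None = None,
    background_methods: Sequence[str] = ("mcp", "thresh50", "thresh75"),
    n_reps: int = 99,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] | None = None,
):
    """Full crossing: overlap D, equivalency, and directional similarity tests.

    For each (unordered) lineage pair and each background method the battery
    runs one equivalency test and similarity tests in both directions.
    Returns ``(results, table)`` where ``table`` is a long-format DataFrame.
    """
    import pandas as pd

    config = fit_config or FitConfig()
    labels = list(occurrences)
    if pairs is None:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]

    n_bg = min(config.n_background, stack.n_valid)
    bg = sample_background(stack, n_bg, seed=seed)
    fitted = {}
    for lab, occ in occurrences.items():
        thin = thin_occurrences(occ, stack)
        model, surface, _ = fit_sdm(thin, stack, config, background_cells=bg)
        fitted[lab] = (thin, model, surface)

    def region_for(lab: str, method: str) -> BackgroundRegion:
        thin, _, surface = fitted[lab]
        if method == "mcp":
            return mcp_region(thin, stack)
        if method == "thresh50":
            return threshold_region(surface, 0.5, stack, source_lineage=lab)
        if method == "thresh75":
            return threshold_region(surface, 0.75, stack, source_lineage=lab)
        raise ValueError(f"unknown background method {method!r}")

    results: list[NicheTestResult] = []
    rows = []
    for idx, (a, b) in enumerate(pairs):
        thin_a, model_a, surf_a = fitted[a]
        thin_b, model_b, surf_b = fitted[b]
        d_obs = schoener_d(surf_a, surf_b)
        eq = equivalency_test(
            thin_a, thin_b, stack, config, n_reps=n_reps, seed=seed + 1000 * idx
        )
        results.append(eq)
        rows.append(
            {
                "comparison": f"{a} to {b}",
                "test": "equivalency",
                "background": "",
                "direction": eq.direction,
                "n_a": len(thin_a),
                "n_b": len(thin_b),
                "observed_d": d_obs,
                "p_lower": eq.p_lower,
                "p_upper": eq.p_upper,
                "outcome": eq.outcome,
            }
        )
        for method in background_methods:
            for (sa, ob, lab_pair) in (
                (surf_a, b, (a, b)),
                (surf_b, a, (b, a)),
            ):
                region = region_for(ob, method)
                thin_ob, model_ob, surf_ob = fitted[ob]
                sim = similarity_test(
                    sa,
                    thin_ob,
                    region,
                    stack,
                    config,
                    n_reps=n_reps,
                    seed=seed + 1000 * idx + hash(method) % 997,
                    surface_b=surf_ob,
                    model_b=model_ob,
                )
                results.append(sim)
                rows.append(
                    {
                        "comparison": f"{a} to {b}",
                        "test": "similarity",
                        "background": method,
                        "direction": sim.direction,
                        "n_a": len(thin_a),
                        "n_b": len(thin_b),
                        "observed_d": sim.observed_d,
                        "p_lower": sim.p_lower,
                        "p_upper": sim.p_upper,
                        "outcome": sim.outcome,
                    }
                )
    return results, pd.DataFrame(rows)
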