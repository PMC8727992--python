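"""Global cytosolic-ratio estimation from fractionation expression tables.

The model: whole-cell (WC) expression is a theta-weighted mixture of the
per-fraction expression vectors,

    WC_i ~ theta * C_i + (1 - theta) * N_i,

because each fraction's TPMs are normalized independently while the WC
library pools the fractions' molecules with unknown weights. The single
mixture weight theta (the cytosolic ratio, CR) is estimated by minimizing
the mean squared natural-log ratio between predicted and observed WC
values,

    E(theta) = (1/n) * sum_i [ ln( (theta*C_i + (1-theta)*N_i) / W_i ) ]^2,

over genes surviving two filters: strict positivity in all three vectors
(the log requires it) and the between-range rule min(C,N) <= W <= max(C,N)
(a WC value outside that range cannot be produced by any mixture). The
generalization to k fractions replaces the scalar with simplex weights.
"""

from __future__ import annotations

import logging
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import optimize

from sfae.types import CREstimate, ExpressionTable, FractionSet, FractionTriplet

logger = logging.getLogger(__name__)

DEFAULT_THETA_TOL = 1e-6
DEFAULT_GRID_STEP = 1e-4


def filter_triplet(
    table: ExpressionTable,
    cyto: str,
    nuc: str,
    wc: str,
    gene_subset=None,
) -> FractionTriplet:
    """Select the (cytosol, nucleus, WC) samples and apply the gene filters.

    Genes with any non-positive value are removed first, then genes whose
    WC value falls outside the inclusive range spanned by the cytosol and
    nucleus values. ``gene_subset`` optionally restricts estimation to a
    caller-provided gene list (e.g. a half-life class) before filtering.

    Raises
    ------
    ValueError
        If a requested sample is absent or no gene survives.
    """
    for s in (cyto, nuc, wc):
        if s not in table.values.columns:
            raise ValueError(f"sample {s!r} not in expression table")
    sub = table.values[[cyto, nuc, wc]]
    if gene_subset is not None:
        keep = sub.index.intersection(pd.Index(gene_subset))
        sub = sub.loc[keep]
    c = sub[cyto].to_numpy(float)
    n = sub[nuc].to_numpy(float)
    w = sub[wc].to_numpy(float)

    positive = (c > 0) & (n > 0) & (w > 0)
    n_nonpos = int((~positive).sum())
    in_range = (w >= np.minimum(c, n)) & (w <= np.maximum(c, n))
    keep = positive & in_range
    n_range = int((positive & ~in_range).sum())
    logger.info(
        "triplet filter: %d genes in, %d removed non-positive, "
        "%d removed out-of-range, %d kept",
        len(sub), n_nonpos, n_range, int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("empty estimation set: no genes survive filtering")
    return FractionTriplet(
        gene_ids=sub.index.to_numpy()[keep],
        c=c[keep],
        n_vec=n[keep],
        w=w[keep],
        n_removed_nonpositive=n_nonpos,
        n_removed_out_of_range=n_range,
    )


def cost(theta: float, triplet: FractionTriplet) -> float:
    """Mean squared log-ratio error E(theta) of the mixture prediction."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    pred = theta * triplet.c + (1.0 - theta) * triplet.n_vec
    r = np.log(pred / triplet.w)
    return float(np.mean(r * r))


def _cost_grid(thetas: np.ndarray, triplet: FractionTriplet) -> np.ndarray:
    """Vectorized E(theta) over a grid of theta values."""
    pred = np.outer(thetas, triplet.c) + np.outer(1.0 - thetas, triplet.n_vec)
    r = np.log(pred / triplet.w)
    return np.mean(r * r, axis=1)


def grid_profile(triplet: FractionTriplet, step: float = 0.01) -> list[tuple[float, float]]:
    """E(theta) on the inclusive grid {0, step, ..., 1} (error-curve data)."""
    if not 0 < step <= 0.5:
        raise ValueError("step must be in (0, 0.5]")
    n_points = int(np.floor(1.0 / step)) + 1
    thetas = np.minimum(np.arange(n_points) * step, 1.0)
    errs = _cost_grid(thetas, triplet)
    return list(zip(thetas.tolist(), errs.tolist()))


def estimate_cr(
    triplet: FractionTriplet,
    tolerance: float = DEFAULT_THETA_TOL,
    verify_with_grid: bool = False,
    grid_step: float = DEFAULT_GRID_STEP,
    profile_step: float | None = None,
) -> CREstimate:
    """Estimate the cytosolic ratio theta by bounded scalar minimization.

    A bounded Brent search minimizes E(theta) on [0, 1]; with
    ``verify_with_grid`` the result is cross-checked against a dense grid
    (default step 1e-4) and the better of the two is returned. The error
    profile for plotting is attached when ``profile_step`` is given.
    """
    res = optimize.minimize_scalar(
        lambda t: cost(t, triplet),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": tolerance},
    )
    theta = float(np.clip(res.x, 0.0, 1.0))
    e_min = cost(theta, triplet)
    converged = bool(res.success)
    # the bounded search can stall short of a boundary optimum; check ends
    for t_edge in (0.0, 1.0):
        e_edge = cost(t_edge, triplet)
        if e_edge < e_min:
            theta, e_min = t_edge, e_edge

    if verify_with_grid or not converged:
        thetas = np.linspace(0.0, 1.0, int(round(1.0 / grid_step)) + 1)
        errs = _cost_grid(thetas, triplet)
        i = int(np.argmin(errs))
        if errs[i] < e_min:
            theta, e_min = float(thetas[i]), float(errs[i])
        if not converged:
            logger.warning("optimizer did not converge; grid minimum returned")

    profile = grid_profile(triplet, profile_step) if profile_step else None
    return CREstimate(
        theta=theta, e_min=e_min, n_genes=triplet.n_genes,
        converged=converged, profile=profile,
    )


def filter_fraction_set(
    table: ExpressionTable,
    fraction_samples: list[str],
    wc: str,
    gene_subset=None,
) -> FractionSet:
    """k-fraction analogue of :func:`filter_triplet`.

    Keeps genes strictly positive in every vector whose WC value lies
    within the inclusive min..max range across the k fraction values.
    """
    for s in [*fraction_samples, wc]:
        if s not in table.values.columns:
            raise ValueError(f"sample {s!r} not in expression table")
    if len(fraction_samples) < 2:
        raise ValueError("need at least two fraction samples")
    sub = table.values[list(fraction_samples)]
    wv = table.values[wc]
    if gene_subset is not None:
        keep_idx = sub.index.intersection(pd.Index(gene_subset))
        sub, wv = sub.loc[keep_idx], wv.loc[keep_idx]
    x = sub.to_numpy(float)
    w = wv.to_numpy(float)
    positive = (x > 0).all(axis=1) & (w > 0)
    in_range = (w >= x.min(axis=1)) & (w <= x.max(axis=1))
    keep = positive & in_range
    if not keep.any():
        raise ValueError("empty estimation set: no genes survive filtering")
    return FractionSet(
        gene_ids=sub.index.to_numpy()[keep],
        fractions=sub.loc[keep],
        w=w[keep],
    )


def _multifraction_cost(weights: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    pred = x @ weights
    r = np.log(pred / w)
    return float(np.mean(r * r))


def estimate_multifraction(
    fractions: FractionSet,
    tolerance: float = DEFAULT_THETA_TOL,
    verify_with_grid: bool = False,
    grid_resolution: float = 0.01,
) -> FractionSet:
    """Estimate simplex mixture weights for k >= 2 fractions against WC.

    Minimizes the same mean squared log-ratio cost with weights
    constrained to the probability simplex (sum-to-one equality plus box
    bounds, SLSQP). If all fraction vectors are identical the weights are
    not identifiable; uniform weights are returned with
    ``non_identifiable`` set.
    """
    x = fractions.fractions.to_numpy(float)
    w = fractions.w
    k = fractions.k

    if all(np.allclose(x[:, 0], x[:, j]) for j in range(1, k)):
        fractions.weights = np.full(k, 1.0 / k)
        fractions.non_identifiable = True
        return fractions

    w0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        _multifraction_cost, w0, args=(x, w),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
        options={"ftol": tolerance ** 2, "maxiter": 500},
    )
    best = np.clip(res.x, 0.0, 1.0)
    best /= best.sum()
    best_cost = _multifraction_cost(best, x, w)

    if verify_with_grid or not res.success:
        g, gc = _simplex_grid_argmin(x, w, k, grid_resolution)
        if gc < best_cost:
            best, best_cost = g, gc
    fractions.weights = best
    fractions.non_identifiable = False
    return fractions


def _simplex_grid_argmin(
    x: np.ndarray, w: np.ndarray, k: int, resolution: float,
    chunk: int = 20000,
) -> tuple[np.ndarray, float]:
    """Brute-force search over the simplex lattice at the given resolution."""
    m = int(round(1.0 / resolution))
    grid = simplex_lattice(k, m)
    logw = np.log(w)
    best, best_cost = None, np.inf
    for start in range(0, len(grid), chunk):
        g = grid[start : start + chunk]
        pred = g @ x.T
        r = np.log(pred) - logw
        costs = np.mean(r * r, axis=1)
        i = int(np.argmin(costs))
        if costs[i] < best_cost:
            best, best_cost = g[i], float(costs[i])
    return best, best_cost


def simplex_lattice(k: int, m: int) -> np.ndarray:
    """All weight vectors with components i/m summing to 1 (lattice on the simplex)."""
    combos = combinations_with_replacement(range(k), m)
    out = np.zeros((0, k))
    rows = []
    for combo in combos:
        v = np.bincount(combo, minlength=k) / m
        rows.append(v)
    if rows:
        out = np.array(rows)
    return out
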