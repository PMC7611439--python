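"""Residual diagnostics for perceptual-distance models.

Signed residuals (observed minus predicted dissimilarity), their correlation
with pair covariates such as symmetry strength and area ratio, shared-part
binning, and 2-D multidimensional-scaling embeddings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import smacof

__all__ = [
    "residual_errors",
    "correlate_residuals",
    "bin_residuals_by_shared_parts",
    "mds_embed",
]


def residual_errors(observed: pd.DataFrame, predicted) -> pd.DataFrame:
    """Per-pair signed residual = observed - predicted, with +/- 1 sd flags.

    Pairs more than one standard deviation above the mean residual are flagged
    ``under`` (model underestimated the dissimilarity), more than one sd below
    ``over``; the rest ``within``. A degenerate zero-sd residual distribution
    produces no flags.
    """
    pred = np.asarray(predicted, dtype=float)
    if len(pred) != len(observed):
        raise ValueError("predicted values not aligned with observed pairs")
    out = observed.copy().reset_index(drop=True)
    out["predicted"] = pred
    res = out["dissimilarity"].to_numpy(float) - pred
    out["residual"] = res
    mu, sd = res.mean(), res.std()
    flag = np.full(len(res), "within", dtype=object)
    if sd > 0:
        flag[res > mu + sd] = "under"
        flag[res < mu - sd] = "over"
    out["flag"] = flag
    return out


def correlate_residuals(
    residuals: pd.DataFrame,
    covariate: str,
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Pearson correlation between residuals and a covariate column.

    Returns ``{"r", "p"}`` plus bootstrap ``sd`` and 95% CI bounds when
    ``n_boot`` > 0 (pairs resampled with replacement).
    """
    if covariate not in residuals.columns:
        raise ValueError(f"unknown covariate column {covariate!r}")
    x = residuals[covariate].to_numpy(float)
    y = residuals["residual"].to_numpy(float)
    if len(x) < 10:
        raise ValueError("need at least 10 pairs")
    if np.std(x) == 0:
        raise ValueError(f"covariate {covariate!r} is constant; correlation undefined")
    r, p = stats.pearsonr(y, x)
    result = {"r": float(r), "p": float(p)}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        n = len(x)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            reps[b] = stats.pearsonr(yb, xb)[0] if np.std(xb) > 0 and np.std(yb) > 0 else 0.0
        lo, hi = np.percentile(reps, [2.5, 97.5])
        result.update(sd=float(reps.std()), ci_low=float(lo), ci_high=float(hi))
    return result


def bin_residuals_by_shared_parts(residuals: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd residual for pairs sharing 2, 1 or 0 parts.

    Empty bins are reported with NaN statistics rather than raising.
    """
    if "n_shared_parts" not in residuals.columns:
        raise ValueError("residual table needs an n_shared_parts column")
    rows = []
    for n_shared in (2, 1, 0):
        sub = residuals.loc[residuals["n_shared_parts"] == n_shared, "residual"]
        rows.append(
            {
                "n_shared_parts": n_shared,
                "n_pairs": len(sub),
                "mean_residual": float(sub.mean()) if len(sub) else np.nan,
                "sd_residual": float(sub.std(ddof=0)) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dim]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return coords


def mds_embed(
    distances: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    max_missing_frac: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Metric MDS embedding of a full pairwise distance matrix.

    Missing (NaN) off-diagonal entries below ``max_missing_frac`` are imputed
    by column means with a warning. Runs a classical-scaling solution plus
    seeded stress-majorization restarts and keeps the best-stress result.
    Returns (coordinates, embedding_r) where embedding_r is the Pearson
    correlation between embedded and input distances.
    """
    D = np.array(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distances must be a square matrix")
    n = len(D)
    off = ~np.eye(n, dtype=bool)
    missing = np.isnan(D) & off
    if missing.any():
        frac = missing.sum() / off.sum()
        if frac > max_missing_frac:
            raise ValueError(f"{frac:.0%} of entries missing; limit is {max_missing_frac:.0%}")
        warnings.warn(f"imputing {missing.sum()} missing entries by column means")
        col_means = np.nanmean(np.where(off, D, np.nan), axis=0)
        ii, jj = np.where(missing)
        D[ii, jj] = col_means[jj]
        D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    if np.any(D < 0) or not np.allclose(D, D.T):
        raise ValueError("distances must be symmetric and non-negative")

    def stress_of(coords: np.ndarray) -> float:
        diff = coords[:, None, :] - coords[None, :, :]
        emb = np.sqrt((diff**2).sum(-1))
        return float(((D - emb) ** 2)[np.triu_indices(n, 1)].sum())

    best = _classical_mds(D, dim)
    best_stress = stress_of(best)
    # refine the classical solution and random restarts by stress majorization
    inits = [best] + [None] * n_restarts
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_restarts + 1)
    for init, s in zip(inits, rng_seeds):
        coords, stress = smacof(
            D,
            n_components=dim,
            init=init,
            n_init=1,
            max_iter=500,
            eps=1e-9,
            random_state=int(s),
            normalized_stress=False,
        )
        if stress_of(coords) < best_stress:
            best, best_stress = coords, stress_of(coords)
    iu = np.triu_indices(n, 1)
    diff = best[:, None, :] - best[None, :, :]
    emb = np.sqrt((diff**2).sum(-1))[iu]
    r = stats.pearsonr(emb, D[iu])[0] if np.std(emb) > 0 and np.std(D[iu]) > 0 else 0.0
    return best, float(r)
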