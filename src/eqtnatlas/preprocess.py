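"""Expression preprocessing: filtering, normalization, hidden-factor removal.

The correction pipeline mirrors standard practice for population-scale
expression studies: quantile normalization to a standard normal within
each population, population mean centering, permutation-calibrated choice
of the number of expression principal components, and per-feature
elastic-net residualization on the retained PCs plus known covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix

__all__ = [
    "filter_probes_overlapping_variants",
    "filter_non_expressed",
    "quantile_normalize",
    "center_by_population",
    "FactorCorrection",
    "select_num_pcs",
    "regress_out_factors",
    "DEFAULT_LAMBDA2_GRID",
    "DEFAULT_LAMBDA1_FRACS",
]

logger = logging.getLogger(__name__)

# Six-point ridge-penalty grid spanning near-lasso to near-ridge behaviour.
DEFAULT_LAMBDA2_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)
# Lasso penalty as a fraction of each feature's lambda1_max.
DEFAULT_LAMBDA1_FRACS = (0.0, 0.01, 0.1)


# ---------------------------------------------------------------------------
# feature filters
# ---------------------------------------------------------------------------

def filter_probes_overlapping_variants(
    features: pd.DataFrame, variants: pd.DataFrame
) -> pd.Index:
    """Drop features whose genomic interval contains any variant.

    ``features`` must carry ``chrom``, ``start``, ``end`` (half-open).
    ``variants`` needs ``chrom`` plus either ``pos`` (point variants) or
    ``start``/``end`` (interval variants such as indels and CNVs).
    A feature is dropped iff a variant position falls in ``[start, end)``
    or a variant interval overlaps it. Retained features keep input order.
    """
    for col in ("chrom", "start", "end"):
        if col not in features.columns:
            raise ValueError(f"features lack required column {col!r}")
    bad = features.index[
        features[["chrom", "start", "end"]].isna().any(axis=1)
    ].tolist()
    if bad:
        raise ValueError(f"features lacking genomic intervals: {bad[:10]}")
    if len(variants) == 0:
        return features.index
    if "pos" in variants.columns:
        vstart = variants["pos"].to_numpy(np.int64)
        vend = vstart + 1
    else:
        vstart = variants["start"].to_numpy(np.int64)
        vend = variants["end"].to_numpy(np.int64)
    vchrom = variants["chrom"].to_numpy()

    keep = np.ones(len(features), dtype=bool)
    fs = features["start"].to_numpy(np.int64)
    fe = features["end"].to_numpy(np.int64)
    fc = features["chrom"].to_numpy()
    for chrom in np.unique(fc):
        vm = vchrom == chrom
        if not vm.any():
            continue
        s_sorted = np.sort(vstart[vm])
        e_sorted = np.sort(vend[vm])
        fm = fc == chrom
        # overlap iff  #(vstart < feature_end) - #(vend <= feature_start) > 0
        n_open = np.searchsorted(s_sorted, fe[fm], side="left")
        n_done = np.searchsorted(e_sorted, fs[fm], side="right")
        keep[fm] = (n_open - n_done) == 0
    return features.index[keep]


def filter_non_expressed(
    expr: ExpressionMatrix,
    method: str,
    threshold: float | None = None,
) -> pd.Index:
    """Drop features that appear non-expressed, preserving feature order.

    * ``mad`` — drop features whose median absolute deviation falls below
      ``threshold`` (default: the 25th percentile of all feature MADs).
    * ``median_level`` — drop features whose median is below ``threshold``
      in *every* population (``threshold`` required).
    * ``zero_median_count`` — drop features whose within-population median
      count is 0 in every population.
    """
    values = expr.values.to_numpy(float)
    pops = expr.populations
    if method == "mad":
        med = np.median(values, axis=1, keepdims=True)
        mad = np.median(np.abs(values - med), axis=1)
        thr = float(np.percentile(mad, 25.0)) if threshold is None else threshold
        keep = mad >= thr
    elif method in ("median_level", "zero_median_count"):
        if method == "median_level" and threshold is None:
            raise ValueError("median_level filtering requires an explicit threshold")
        thr = 0.0 if method == "zero_median_count" else threshold
        low_everywhere = np.ones(expr.n_features, dtype=bool)
        for pop in pops.unique():
            cols = np.flatnonzero((pops == pop).to_numpy())
            pm = np.median(values[:, cols], axis=1)
            low = pm <= 0.0 if method == "zero_median_count" else pm < thr
            low_everywhere &= low
        keep = ~low_everywhere
    else:
        raise ValueError(f"unknown non-expressed filter method {method!r}")
    return expr.feature_ids[keep]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalize each feature to a standard normal within population.

    Within each population group, values of each feature are replaced by
    normal scores Phi^-1(k/(n+1)) of their ranks; tied observations receive
    the average of the scores of the ranks they span. Output is invariant
    under any strictly monotone transform of the input.
    """
    values = expr.values.to_numpy(float).copy()
    pops = expr.populations
    for pop in pops.unique():
        cols = np.flatnonzero((pops == pop).to_numpy())
        if len(cols) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
        block = values[:, cols]
        n = block.shape[1]
        scores = stats.norm.ppf(np.arange(1, n + 1) / (n + 1.0))
        cum = np.concatenate([[0.0], np.cumsum(scores)])
        rmin = stats.rankdata(block, method="min", axis=1).astype(np.intp)
        rmax = stats.rankdata(block, method="max", axis=1).astype(np.intp)
        values[:, cols] = (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)
    return expr.with_values(values)


def center_by_population(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's population mean (all populations to mean 0)."""
    values = expr.values.to_numpy(float).copy()
    pops = expr.populations
    for pop in pops.unique():
        cols = np.flatnonzero((pops == pop).to_numpy())
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    return expr.with_values(values)


# ---------------------------------------------------------------------------
# hidden-factor correction
# ---------------------------------------------------------------------------

@dataclass
class FactorCorrection:
    """Permutation-calibrated PC selection (and downstream residualization)."""

    n_pcs: int
    eigenvalues: np.ndarray
    envelope: np.ndarray
    pcs: np.ndarray  # n_samples x n_pcs, orthonormal sample-space PCs
    n_perm: int
    upper_quantile: float
    lambda_choice: pd.DataFrame | None = None


def _sample_eigs(xc: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the sample covariance (up to min-dim rank)."""
    f, n = xc.shape
    gram = xc.T @ xc if f >= n else xc @ xc.T
    ev = np.linalg.eigvalsh(gram)[::-1]
    return np.maximum(ev, 0.0)


def select_num_pcs(
    expr: ExpressionMatrix | np.ndarray,
    n_perm: int = 100,
    upper_quantile: float = 0.975,
    seed: int = 0,
) -> FactorCorrection:
    """Choose the number of expression PCs against a permutation null.

    The null distribution of eigenvalues is built by permuting each
    feature's values across samples independently (destroying inter-feature
    correlation while preserving marginals) ``n_perm`` times. The selected
    K is the length of the leading run of observed eigenvalues exceeding
    the per-rank ``upper_quantile`` permutation envelope.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = expr.values.to_numpy(float) if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    f, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples for PC selection")
    xc = values - values.mean(axis=1, keepdims=True)
    obs = _sample_eigs(xc)
    rng = np.random.default_rng(seed)
    perm_eigs = np.empty((n_perm, len(obs)))
    for b in range(n_perm):
        order = np.argsort(rng.random((f, n)), axis=1)
        perm_eigs[b] = _sample_eigs(np.take_along_axis(xc, order, axis=1))
    envelope = np.quantile(perm_eigs, upper_quantile, axis=0)
    exceed = obs > envelope
    k = int(np.argmin(exceed)) if not exceed.all() else len(exceed)
    # sample-space PCs of the observed matrix
    if f >= n:
        w, v = np.linalg.eigh(xc.T @ xc)
        pcs = v[:, ::-1][:, :k]
    else:
        w, u = np.linalg.eigh(xc @ xc.T)
        u = u[:, ::-1][:, :k]
        s = np.sqrt(np.maximum(w[::-1][:k], 1e-30))
        pcs = (xc.T @ u) / s
    return FactorCorrection(
        n_pcs=k,
        eigenvalues=obs,
        envelope=envelope,
        pcs=pcs,
        n_perm=n_perm,
        upper_quantile=upper_quantile,
    )


# -- elastic net -----------------------------------------------------------

def _soft(c: np.ndarray, lam: np.ndarray | float) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)


def _cd_gram(
    gram: np.ndarray,
    xty: np.ndarray,
    lam1: np.ndarray,
    lam2: float,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Coordinate-descent elastic net on precomputed Gram statistics.

    Minimizes 0.5||y - Xw||^2 + lam1||w||_1 + 0.5 lam2 ||w||^2 jointly for
    every response column (``lam1`` may vary per column; the design is
    shared), using only X'X (p x p) and X'Y (p x F). Returns p x F
    coefficients.
    """
    p, nf = xty.shape
    w = np.zeros((p, nf)) if w0 is None else w0.copy()
    diag = np.diag(gram)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            c = xty[j] - gram[j] @ w + diag[j] * w[j]
            wnew = _soft(c, lam1) / (diag[j] + lam2)
            delta = max(delta, float(np.abs(wnew - w[j]).max()) if nf else 0.0)
            w[j] = wnew
        if delta < tol:
            break
    return w


def _cd_elastic_net(
    x: np.ndarray,
    y: np.ndarray,
    lam1: np.ndarray,
    lam2: float,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> np.ndarray:
    """Elastic net for responses ``y`` (n x F) on a shared design ``x``."""
    return _cd_gram(x.T @ x, x.T @ y, np.asarray(lam1, float), lam2,
                    w0=w0, tol=tol, max_iter=max_iter)


def _ridge_loo_press(x: np.ndarray, y: np.ndarray, lam2: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form leave-one-out PRESS for ridge (lam1 = 0), per column of y."""
    n, p = x.shape
    a = x.T @ x + lam2 * np.eye(p)
    ainv = np.linalg.inv(a)
    w = ainv @ (x.T @ y)
    h = np.einsum("ij,jk,ik->i", x, ainv, x)
    resid = y - x @ w
    loo = resid / np.clip(1.0 - h, 1e-12, None)[:, None]
    return w, np.einsum("ij,ij->j", loo, loo)


def regress_out_factors(
    expr: ExpressionMatrix,
    factors: FactorCorrection | int,
    covariates: str | pd.DataFrame | None = "auto",
    lambda2_grid: Sequence[float] = DEFAULT_LAMBDA2_GRID,
    lambda1_fracs: Sequence[float] = DEFAULT_LAMBDA1_FRACS,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Residualize every feature on the top-K PCs plus known covariates.

    Per feature, an elastic net of its (centered) values on the
    standardized design is fit for each point of the ridge-penalty grid
    (with the lasso penalty tried at the given fractions of that feature's
    lambda1_max); the penalty pair minimizing the leave-one-out residual
    sum of squares wins, and the feature's output is the residual from the
    winning full-data fit. With an empty design (K = 0 and no covariates)
    the output is simply the centered input.

    Returns the residual matrix and a per-feature report of the chosen
    penalties and LOO press.
    """
    if isinstance(factors, int):
        if factors > 0:
            values = expr.values.to_numpy(float)
            xc = values - values.mean(axis=1, keepdims=True)
            _, _, vt = np.linalg.svd(xc, full_matrices=False)
            pcs = vt[:factors].T
        else:
            pcs = np.zeros((expr.n_samples, 0))
        k = factors
    else:
        pcs = factors.pcs
        k = factors.n_pcs

    cov_df = None
    if isinstance(covariates, pd.DataFrame):
        cov_df = covariates.loc[expr.sample_ids]
    elif covariates == "auto":
        cols = [c for c in ("population", "sex") if c in expr.samples.columns]
        if cols:
            cov_df = pd.get_dummies(expr.samples[cols], drop_first=True).astype(float)
    elif covariates is not None:
        raise ValueError("covariates must be None, 'auto', or a DataFrame")

    blocks = [pcs]
    if cov_df is not None and cov_df.shape[1]:
        blocks.append(cov_df.to_numpy(float))
    x = np.hstack(blocks) if blocks else np.zeros((expr.n_samples, 0))
    n = expr.n_samples
    n_cov = 0 if cov_df is None else cov_df.shape[1]
    if k > n - n_cov - 1:
        raise ValueError(f"K={k} exceeds sample count minus covariates ({n - n_cov - 1})")

    y = expr.values.to_numpy(float).T  # n x F
    ymean = y.mean(axis=0, keepdims=True)
    yc = y - ymean
    nf = yc.shape[1]

    if x.shape[1] == 0:
        report = pd.DataFrame(
            {"lambda1": 0.0, "lambda2": 0.0, "press": np.einsum("ij,ij->j", yc, yc)},
            index=expr.feature_ids,
        )
        return expr.with_values(yc.T), report

    # drop constant columns, standardize the rest
    sd = x.std(axis=0)
    keep = sd > 1e-12
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    gram = x.T @ x
    xty = x.T @ yc
    lam1max = np.abs(xty).max(axis=0)
    press = np.full((len(lambda2_grid), len(lambda1_fracs), nf), np.inf)
    w_full: dict[tuple[int, int], np.ndarray] = {}
    for a, lam2 in enumerate(lambda2_grid):
        for b, frac in enumerate(lambda1_fracs):
            if frac == 0.0:
                w, pr = _ridge_loo_press(x, yc, lam2)
                w_full[(a, b)] = w
                press[a, b] = pr
                continue
            lam1 = frac * lam1max
            w = _cd_gram(gram, xty, lam1, lam2)
            w_full[(a, b)] = w
            sq = np.zeros(nf)
            for i in range(n):
                xi = x[i]
                gram_i = gram - np.outer(xi, xi)
                xty_i = xty - np.outer(xi, yc[i])
                wi = _cd_gram(gram_i, xty_i, lam1, lam2, w0=w, tol=1e-7)
                err = yc[i] - xi @ wi
                sq += err * err
            press[a, b] = sq
    flat = press.reshape(len(lambda2_grid) * len(lambda1_fracs), nf)
    winner = np.argmin(flat, axis=0)
    wa, wb = np.unravel_index(winner, (len(lambda2_grid), len(lambda1_fracs)))
    resid = np.empty_like(yc)
    lam1_out = np.empty(nf)
    lam2_out = np.empty(nf)
    for a in range(len(lambda2_grid)):
        for b in range(len(lambda1_fracs)):
            cols = np.flatnonzero((wa == a) & (wb == b))
            if len(cols) == 0:
                continue
            resid[:, cols] = yc[:, cols] - x @ w_full[(a, b)][:, cols]
            lam1_out[cols] = lambda1_fracs[b] * lam1max[cols]
            lam2_out[cols] = lambda2_grid[a]
    report = pd.DataFrame(
        {
            "lambda1": lam1_out,
            "lambda2": lam2_out,
            "press": flat[winner, np.arange(nf)],
        },
        index=expr.feature_ids,
    )
    return expr.with_values(resid.T), report
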