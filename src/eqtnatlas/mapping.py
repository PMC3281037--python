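"""cis-window association testing, eQTN assignment and empirical FDR.

Gene-level candidates are all SNPs inside the transcript or within 100 kb
of either end; exon-level candidates lie within 10 kb of either exon end,
and every exon-level test is treated as independent. Associations are
ordinary least squares of (already normalized and corrected) expression
on dosage; the per-feature minimum p defines the putative eQTN, with
exactly tied minima sharing the assignment probability equally. The
significance threshold is calibrated by permuting sample labels within
population and comparing observed and null minimum-p distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, GeneModel, GenotypeMatrix

__all__ = [
    "GENE_WINDOW",
    "EXON_WINDOW",
    "MonomorphicError",
    "AssociationResult",
    "cis_window_snps",
    "test_association",
    "CisScanner",
    "CisMapResult",
    "map_cis_qtls",
    "best_snp_weights",
    "FdrResult",
    "empirical_fdr_threshold",
]

logger = logging.getLogger(__name__)

GENE_WINDOW = 100_000
EXON_WINDOW = 10_000
_TIE_SIG_DIGITS = 12


class MonomorphicError(ValueError):
    """Dosage vector has zero variance."""


@dataclass
class AssociationResult:
    feature_id: str | None
    snp_id: str | None
    slope: float
    se: float
    tstat: float
    p: float
    n: int
    perfect_fit: bool = False


def cis_window_snps(
    chrom: str,
    start: int,
    end: int,
    genotypes: GenotypeMatrix,
    level: str = "gene",
) -> np.ndarray:
    """Candidate SNP row indices for a feature's half-open interval.

    Gene level: within the transcript or 100 kb from either end;
    exon level: within 10 kb of either exon end. Windows are half-open
    and floored at coordinate 0.
    """
    if level == "gene":
        w = GENE_WINDOW
    elif level == "exon":
        w = EXON_WINDOW
    else:
        raise ValueError(f"unknown level {level!r}")
    return genotypes.snps_in(chrom, max(0, start - w), end + w)


def test_association(
    y: np.ndarray,
    g: np.ndarray,
    feature_id: str | None = None,
    snp_id: str | None = None,
) -> AssociationResult:
    """Simple linear regression of expression on dosage.

    Pairs with missing values are dropped; needs >=3 complete pairs and a
    polymorphic dosage. The two-sided p comes from the t distribution with
    n-2 df; an exactly perfect fit is reported as p = 0 with a flag.
    """
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        raise MonomorphicError("monomorphic dosage vector")
    yc = y - y.mean()
    sxy = float(gc @ yc)
    slope = sxy / sxx
    rss = float(yc @ yc) - slope * sxy
    df = n - 2
    if rss <= max(1e-14 * float(yc @ yc), 0.0):
        return AssociationResult(feature_id, snp_id, slope, 0.0, np.inf, 0.0, n, True)
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return AssociationResult(feature_id, snp_id, slope, se, t, float(p), n)


def _round_sig(p: np.ndarray, digits: int = _TIE_SIG_DIGITS) -> np.ndarray:
    """Round to a fixed number of significant digits (0 stays 0)."""
    p = np.asarray(p, float)
    out = np.zeros_like(p)
    pos = p > 0
    if pos.any():
        mag = np.floor(np.log10(p[pos]))
        factor = 10.0 ** (digits - 1 - mag)
        out[pos] = np.round(p[pos] * factor) / factor
    return out


class CisScanner:
    """Precomputed cis candidate sets for repeated (permutation) scans.

    Centers and norms of each feature's candidate dosage sub-matrix are
    computed once; per-scan cost is then one matrix-vector product per
    feature. Monomorphic SNPs are excluded up front (flagged in
    ``n_monomorphic``).
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        gene_models: Mapping[str, GeneModel] | None = None,
        level: str = "gene",
    ) -> None:
        if list(expr.sample_ids) != list(genotypes.samples):
            genotypes = genotypes.subset_samples(list(expr.sample_ids))
        self.expr = expr
        self.genotypes = genotypes
        self.level = level
        self.feature_ids: list[str] = []
        self.gene_ids: list[str] = []
        self._cand: list[np.ndarray] = []
        self._gc: list[np.ndarray] = []
        self._gnorm: list[np.ndarray] = []
        self.n_monomorphic = 0
        self.skipped: list[str] = []
        dos = genotypes.dosages
        for fid, frow in expr.features.iterrows():
            if level == "gene":
                if gene_models is None:
                    raise ValueError("gene-level scans need gene models")
                gene = gene_models[frow["gene_id"]]
                idx = cis_window_snps(gene.chrom, gene.span_start, gene.span_end,
                                      genotypes, "gene")
            else:
                idx = cis_window_snps(frow["chrom"], int(frow["start"]),
                                      int(frow["end"]), genotypes, "exon")
            if len(idx) == 0:
                self.skipped.append(fid)
                logger.info("feature %s: empty candidate set, skipped", fid)
                continue
            g = dos[idx].astype(float)
            gc = g - g.mean(axis=1, keepdims=True)
            norm = np.sqrt(np.einsum("ij,ij->i", gc, gc))
            poly = norm > 0
            self.n_monomorphic += int((~poly).sum())
            if not poly.any():
                self.skipped.append(fid)
                continue
            self.feature_ids.append(fid)
            self.gene_ids.append(frow["gene_id"])
            self._cand.append(idx[poly])
            self._gc.append(gc[poly])
            self._gnorm.append(norm[poly])
        self.n_samples = expr.n_samples
        self._row_of = {f: i for i, f in enumerate(expr.feature_ids)}

    def n_candidates(self, i: int) -> int:
        return len(self._cand[i])

    def _corr(self, i: int, y: np.ndarray) -> tuple[np.ndarray, float]:
        yc = y - y.mean()
        syy = float(np.sqrt(yc @ yc))
        if syy == 0.0:
            return np.zeros(len(self._cand[i])), 0.0
        r = (self._gc[i] @ yc) / (self._gnorm[i] * syy)
        return np.clip(r, -1.0, 1.0), syy

    def min_p(self, values: np.ndarray) -> np.ndarray:
        """Per-feature minimum p over candidates, for a features x samples array."""
        df = self.n_samples - 2
        rmax = np.empty(len(self.feature_ids))
        for i, fid in enumerate(self.feature_ids):
            y = values[self._row_of[fid]]
            r, _ = self._corr(i, y)
            rmax[i] = np.abs(r).max()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rmax * np.sqrt(df / np.maximum(1.0 - rmax**2, 1e-300))
        return 2.0 * stats.t.sf(t, df)

    def scan_feature(self, i: int, values: np.ndarray) -> pd.DataFrame:
        """Full per-SNP association table for one feature."""
        fid = self.feature_ids[i]
        y = values[self._row_of[fid]]
        r, syy = self._corr(i, y)
        df = self.n_samples - 2
        one_m_r2 = np.maximum(1.0 - r**2, 0.0)
        perfect = one_m_r2 <= 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.where(perfect, np.nan, one_m_r2))
        p = np.where(perfect, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
        slope = r * syy / self._gnorm[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.where(perfect, 0.0, slope / t)
        idx = self._cand[i]
        return pd.DataFrame(
            {
                "feature_id": fid,
                "gene_id": self.gene_ids[i],
                "snp_id": self.genotypes.snp_ids[idx],
                "position": self.genotypes.positions[idx],
                "slope": slope,
                "se": se,
                "tstat": np.where(perfect, np.copysign(np.inf, r), t),
                "p": p,
                "n": self.n_samples,
                "perfect_fit": perfect,
            }
        )


@dataclass
class CisMapResult:
    """Best-SNP table (one row per feature) plus optional full results."""

    best: pd.DataFrame
    level: str
    full: pd.DataFrame | None = None

    def eqtn_weights(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Tie-shared eQTN probability weights (gene_id, snp_id, weight, min_p)."""
        tab = self.best if features is None else self.best.loc[list(features)]
        rows = []
        for fid, row in tab.iterrows():
            ties = row["tied_snps"]
            w = 1.0 / len(ties)
            for s in ties:
                rows.append(
                    {
                        "feature_id": fid,
                        "gene_id": row["gene_id"],
                        "snp_id": s,
                        "weight": w,
                        "min_p": row["min_p"],
                    }
                )
        return pd.DataFrame(rows, columns=["feature_id", "gene_id", "snp_id",
                                           "weight", "min_p"])


def best_snp_weights(snp_ids: Sequence[str], pvalues: Sequence[float]) -> pd.Series:
    """Equal sharing of the eQTN probability over exactly tied minimum p-values.

    P-values are compared after rounding to 12 significant digits; the t
    tied SNPs each get weight 1/t, all others 0.
    """
    p = _round_sig(np.asarray(pvalues, float))
    if len(p) == 0:
        raise ValueError("need at least one valid test")
    pmin = p.min()
    ties = p == pmin
    w = np.where(ties, 1.0 / ties.sum(), 0.0)
    return pd.Series(w, index=pd.Index(snp_ids, name="snp_id"))


def map_cis_qtls(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_models: Mapping[str, GeneModel] | None = None,
    level: str = "gene",
    return_full: bool = False,
    scanner: CisScanner | None = None,
) -> CisMapResult:
    """Exhaustive cis association scan with per-feature minimum p and ties."""
    if scanner is None:
        scanner = CisScanner(expr, genotypes, gene_models, level)
    values = expr.values.to_numpy(float)
    best_rows = []
    full_parts = [] if return_full else None
    for i, fid in enumerate(scanner.feature_ids):
        tab = scanner.scan_feature(i, values)
        if full_parts is not None:
            full_parts.append(tab)
        pr = _round_sig(tab["p"].to_numpy())
        pmin = pr.min()
        tie_mask = pr == pmin
        ties = tab["snp_id"].to_numpy()[tie_mask].tolist()
        ibest = int(np.flatnonzero(tie_mask)[0])
        best_rows.append(
            {
                "feature_id": fid,
                "gene_id": scanner.gene_ids[i],
                "n_candidates": len(tab),
                "min_p": float(tab["p"].iloc[ibest]),
                "best_snp": ties[0],
                "tied_snps": ties,
                "slope": float(tab["slope"].iloc[ibest]),
                "n": scanner.n_samples,
            }
        )
    best = pd.DataFrame(best_rows).set_index("feature_id") if best_rows else pd.DataFrame(
        columns=["gene_id", "n_candidates", "min_p", "best_snp", "tied_snps",
                 "slope", "n"]
    )
    full = pd.concat(full_parts, ignore_index=True) if full_parts else None
    return CisMapResult(best=best, level=level, full=full)


@dataclass
class FdrResult:
    cutoff: float | None
    significant: pd.Index
    table: pd.DataFrame
    n_perm: int
    target: float


def empirical_fdr_threshold(
    observed: pd.DataFrame,
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_models: Mapping[str, GeneModel] | None = None,
    level: str = "gene",
    n_perm: int = 10,
    target: float = 0.05,
    seed: int = 0,
    scanner: CisScanner | None = None,
) -> FdrResult:
    """Permutation-calibrated p-value cutoff at an empirical FDR target.

    Sample labels of the expression matrix are permuted within population
    (jointly across features, preserving their correlation) ``n_perm``
    times; FDR(t) = (mean null count of min-p <= t) / (observed count <= t)
    and the cutoff is the largest observed min-p with FDR <= target. The
    mean null count uses the add-one convention (the observed data counts
    as one more permutation), which keeps the estimator valid at the
    extreme tail when few permutations are affordable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scanner is None:
        scanner = CisScanner(expr, genotypes, gene_models, level)
    values = expr.values.to_numpy(float)
    pops = expr.populations.to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(scanner.feature_ids)))
    n = expr.n_samples
    for b in range(n_perm):
        perm = np.arange(n)
        for pop in pd.unique(pops):
            block = np.flatnonzero(pops == pop)
            perm[block] = block[rng.permutation(len(block))]
        null[b] = scanner.min_p(values[:, perm])
    null_sorted = np.sort(null.ravel())
    obs = observed["min_p"].to_numpy(float)
    order = np.argsort(obs)
    obs_sorted = obs[order]
    k = np.arange(1, len(obs_sorted) + 1)
    mean_null = (
        np.searchsorted(null_sorted, obs_sorted, side="right") + 1.0
    ) / (n_perm + 1.0)
    fdr = mean_null / k
    table = pd.DataFrame(
        {
            "feature_id": observed.index.to_numpy()[order],
            "min_p": obs_sorted,
            "mean_null_count": mean_null,
            "fdr": fdr,
        }
    )
    ok = np.flatnonzero(fdr <= target)
    if len(ok) == 0:
        logger.info("no feature passes FDR %.3f", target)
        return FdrResult(None, pd.Index([]), table, n_perm, target)
    cutoff = float(obs_sorted[ok.max()])
    significant = pd.Index(observed.index[observed["min_p"] <= cutoff])
    return FdrResult(cutoff, significant, table, n_perm, target)
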