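"""Median-polish summarization of probe/exon matrices.

Gene expression for sample i is the common (overall + row) term of
Tukey's median polish fit to the samples x probes two-way layout

    y_ij = mu + s_i + p_j + e_ij,

which is robust to a minority of deviant probes, so a QTL affecting a
single exon of a multi-exon gene leaves the gene-level summary nearly
untouched. Exon-specific ("splicing") expression is the residual e_ij of
that same fit, aggregated per exon — the gene-level signal is absorbed by
mu + s_i, leaving only exon-by-sample departures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel

__all__ = [
    "MedianPolishFit",
    "median_polish",
    "gene_expression",
    "exon_residuals",
    "SingleExonError",
    "summarize_gene_levels",
    "exon_residual_matrix",
]

logger = logging.getLogger(__name__)


class SingleExonError(ValueError):
    """Gene lacks the >=2 measured exons required for exon-specific analysis."""


@dataclass
class MedianPolishFit:
    """Additive two-way decomposition: input = overall + row + column + residual."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )

    def reconstruct(self) -> np.ndarray:
        return self.fitted() + self.residuals


def median_polish(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> MedianPolishFit:
    """Fit the additive model by alternately sweeping column and row medians.

    Columns (probes) are swept first, so that a constant offset of any
    single probe — a probe-affinity effect — is absorbed exactly into that
    probe's column effect and the sample-level summary is invariant to it.
    Medians of the effect vectors are folded into the overall term each
    pass. Iteration stops when the fitted values change by less than
    ``tol`` (max absolute change) or after ``max_iter`` passes. The
    decomposition identity holds exactly at every iteration.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(z)):
        raise ValueError("matrix contains non-finite entries")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    prev_fit = np.zeros_like(z)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rmed_of_row = np.median(row)
        overall += rmed_of_row
        row -= rmed_of_row
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cmed_of_col = np.median(col)
        overall += cmed_of_col
        col -= cmed_of_col
        fit = overall + row[:, None] + col[None, :]
        if np.max(np.abs(fit - prev_fit)) < tol:
            converged = True
            break
        prev_fit = fit
    return MedianPolishFit(
        overall=float(overall),
        row_effects=row,
        col_effects=col,
        residuals=z,
        iterations=it,
        converged=converged,
    )


def _gene_matrix(expr: ExpressionMatrix) -> tuple[np.ndarray, pd.Index, pd.Series]:
    """samples x probes matrix for one gene plus probe->exon mapping."""
    if expr.n_features == 0:
        raise ValueError("gene has no probes/exons with measurements")
    genes = expr.features["gene_id"].unique()
    if len(genes) > 1:
        raise ValueError(f"expected a single gene, got {list(genes)}")
    return (
        expr.values.to_numpy(float).T,
        expr.sample_ids,
        expr.features["exon_index"],
    )


def gene_expression(
    expr: ExpressionMatrix,
    tol: float = 1e-6,
    max_iter: int = 100,
    strategy: str = "probe",
) -> pd.Series:
    """Per-sample gene level: overall + sample effect of the median polish.

    ``strategy='probe'`` polishes the samples x probes matrix directly;
    ``strategy='exon_first'`` first polishes probes within each exon to an
    exon level, then polishes the samples x exons matrix.
    """
    mat, sample_ids, exon_of = _gene_matrix(expr)
    if strategy == "exon_first":
        exons = sorted(exon_of.unique())
        cols = []
        for ex in exons:
            sub = mat[:, (exon_of == ex).to_numpy()]
            f = median_polish(sub, tol=tol, max_iter=max_iter)
            cols.append(f.overall + f.row_effects)
        mat = np.column_stack(cols)
    elif strategy != "probe":
        raise ValueError(f"unknown summarization strategy {strategy!r}")
    fit = median_polish(mat, tol=tol, max_iter=max_iter)
    return pd.Series(fit.overall + fit.row_effects, index=sample_ids)


def exon_residuals(
    expr: ExpressionMatrix, tol: float = 1e-6, max_iter: int = 100
) -> pd.DataFrame:
    """Exon-specific levels: residuals of the gene-level polish, per exon.

    Requires at least two exons with measurements (single-exon genes carry
    no exon-specific signal and are excluded from splicing-QTL analysis).
    Residuals of probes in the same exon are combined by median. Returns
    an exons x samples DataFrame indexed by exon index.
    """
    mat, sample_ids, exon_of = _gene_matrix(expr)
    exons = sorted(pd.unique(exon_of))
    if len(exons) < 2:
        gid = expr.features["gene_id"].iloc[0]
        raise SingleExonError(
            f"gene {gid}: exon-specific analysis needs >=2 measured exons"
        )
    fit = median_polish(mat, tol=tol, max_iter=max_iter)
    rows = []
    for ex in exons:
        sub = fit.residuals[:, (exon_of == ex).to_numpy()]
        rows.append(np.median(sub, axis=1))
    return pd.DataFrame(np.asarray(rows), index=pd.Index(exons, name="exon_index"),
                        columns=sample_ids)


# ---------------------------------------------------------------------------
# multi-gene conveniences
# ---------------------------------------------------------------------------

def summarize_gene_levels(
    expr: ExpressionMatrix, strategy: str = "probe"
) -> pd.DataFrame:
    """Gene-level matrix (genes x samples) from a multi-gene feature matrix."""
    out = {}
    for gid in expr.features["gene_id"].unique():
        out[gid] = gene_expression(expr.for_gene(gid), strategy=strategy)
    return pd.DataFrame(out).T.rename_axis("gene_id")


def exon_residual_matrix(
    expr: ExpressionMatrix, gene_models: Mapping[str, GeneModel]
) -> ExpressionMatrix:
    """Exon-specific levels for every eligible gene, as an ExpressionMatrix.

    Genes with fewer than two measured exons are skipped. Feature intervals
    are the *exon* intervals from the gene models (probe intervals are
    sub-intervals and would distort window logic downstream).
    """
    feat_rows, values = [], []
    for gid in expr.features["gene_id"].unique():
        sub = expr.for_gene(gid)
        try:
            res = exon_residuals(sub)
        except SingleExonError:
            logger.info("gene %s: single measured exon, excluded from sQTN analysis", gid)
            continue
        gene = gene_models[gid]
        for ex in res.index:
            s, e = gene.exons[int(ex)]
            feat_rows.append(
                {
                    "feature_id": f"{gid}:e{int(ex):02d}:res",
                    "gene_id": gid,
                    "exon_index": int(ex),
                    "chrom": gene.chrom,
                    "start": s,
                    "end": e,
                    "platform": "exon_residual",
                }
            )
            values.append(res.loc[ex].to_numpy())
    if not feat_rows:
        raise ValueError("no gene with >=2 measured exons")
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    vals = pd.DataFrame(np.asarray(values), index=features.index,
                        columns=expr.sample_ids)
    return ExpressionMatrix(vals, features, expr.samples)
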