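"""Positional modelling of eQTN locations relative to their target genes.

Candidate SNPs of each significant gene are annotated by signed distance
from the TSS (binned) and by gene-structure context (exon / intron /
first / internal / last exon). A multinomial "softmax" prior over each
gene's candidate SNPs,

    pi_gj = exp(lambda' a_gj) / sum_k exp(lambda' a_gk),

is fit by maximum likelihood to the observed eQTN assignments, where the
observation for gene g is a tie-shared weight vector w_g over its
candidates and the log-likelihood is sum_g log sum_j w_gj pi_gj.

Four nested parameterizations are compared by AIC:

* ``M0`` — distance bins only;
* ``M1`` — adds a single intragenic indicator;
* ``M2`` — splits intragenic into exclusive intron and exon indicators;
* ``M3`` — further splits exon into non-last-exon and last-exon.

Annotation odds ratios (e.g. exon/intron) are contrasts of coefficients,
with Wald 95% confidence intervals from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import GeneModel, GenotypeMatrix

__all__ = [
    "DEFAULT_BIN_EDGES",
    "N_BINS",
    "MODELS",
    "AnnotationVector",
    "annotate_snp",
    "annotate_positions",
    "design_matrix",
    "PositionalData",
    "PositionalModelFit",
    "model_loglik",
    "fit_positional_model",
    "compare_models",
    "position_histogram",
]

# Signed-distance bin boundaries (bp from TSS, transcription-oriented).
# Bins: (-inf,-100k], (-100k,-50k], ..., (-1k,0], (0,1k], ..., (100k,inf)
DEFAULT_BIN_EDGES = np.array(
    [-100_000, -50_000, -25_000, -10_000, -5_000, -1_000,
     0, 1_000, 5_000, 10_000, 25_000, 50_000, 100_000],
    dtype=np.int64,
)
N_BINS = len(DEFAULT_BIN_EDGES) + 1  # 14
REF_BIN = 0  # most-upstream bin is the identifiability reference

MODELS = ("M0", "M1", "M2", "M3")

_MODEL_ANNOT = {
    "M0": (),
    "M1": ("intragenic",),
    "M2": ("intron", "exon"),
    "M3": ("intron", "exon_nonlast", "last_exon"),
}

_MODEL_CONTRASTS = {
    "M0": (),
    "M1": (("intragenic/intergenic", {"intragenic": 1.0}),),
    "M2": (("exon/intron", {"exon": 1.0, "intron": -1.0}),),
    "M3": (
        ("exon (except last)/intron", {"exon_nonlast": 1.0, "intron": -1.0}),
        ("last exon/intron", {"last_exon": 1.0, "intron": -1.0}),
    ),
}


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationVector:
    """Positional annotation of one SNP relative to one gene."""

    bin: int
    distance: int
    intragenic: bool
    exon: bool
    intron: bool
    first_exon: bool
    internal_exon: bool
    last_exon: bool

    def __post_init__(self) -> None:
        if self.intragenic != (self.exon or self.intron):
            raise ValueError("intragenic must equal exon-or-intron")
        if self.exon and self.intron:
            raise ValueError("exon and intron are exclusive")
        if self.exon != (self.first_exon or self.internal_exon or self.last_exon):
            raise ValueError("exon must equal first|internal|last")


def annotate_positions(
    gene: GeneModel,
    positions: np.ndarray | Sequence[int],
    edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Vectorized positional annotation of SNP positions against one gene.

    Returns a DataFrame with columns ``bin``, ``distance``, ``intragenic``,
    ``exon``, ``intron``, ``first_exon``, ``internal_exon``, ``last_exon``.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if gene.strand == "+":
        dist = pos - gene.tss
    else:
        dist = gene.tss - pos
    bins = np.searchsorted(edges, dist, side="left")

    intragenic = (pos >= gene.span_start) & (pos < gene.span_end)
    # exon membership: exons sorted by genomic start
    genomic = sorted(gene.exons)
    starts = np.array([s for s, _ in genomic], dtype=np.int64)
    ends = np.array([e for _, e in genomic], dtype=np.int64)
    gi = np.searchsorted(starts, pos, side="right") - 1
    in_exon = (gi >= 0) & (pos < ends[np.clip(gi, 0, len(ends) - 1)])
    # map genomic exon rank -> transcription-order index
    if gene.strand == "+":
        t_idx = gi
    else:
        t_idx = (gene.n_exons - 1) - gi
    t_idx = np.where(in_exon, t_idx, -1)

    exon = in_exon
    intron = intragenic & ~exon
    first = exon & (t_idx == 0) & (gene.n_exons > 1)
    last = exon & (t_idx == gene.n_exons - 1)
    internal = exon & ~first & ~last
    return pd.DataFrame(
        {
            "bin": bins.astype(np.int64),
            "distance": dist,
            "intragenic": intragenic,
            "exon": exon,
            "intron": intron,
            "first_exon": first,
            "internal_exon": internal,
            "last_exon": last,
            "exon_index": t_idx,
        }
    )


def annotate_snp(
    position: int,
    gene: GeneModel,
    edges: np.ndarray = DEFAULT_BIN_EDGES,
    flank: int = 100_000,
) -> AnnotationVector:
    """Annotate a single SNP; errors if it lies outside the cis candidate region."""
    if not (gene.span_start - flank <= position < gene.span_end + flank):
        raise ValueError(
            f"SNP at {position} outside candidate region of {gene.gene_id}"
        )
    row = annotate_positions(gene, [position], edges).iloc[0]
    return AnnotationVector(
        bin=int(row["bin"]),
        distance=int(row["distance"]),
        intragenic=bool(row["intragenic"]),
        exon=bool(row["exon"]),
        intron=bool(row["intron"]),
        first_exon=bool(row["first_exon"]),
        internal_exon=bool(row["internal_exon"]),
        last_exon=bool(row["last_exon"]),
    )


def design_matrix(
    ann: pd.DataFrame, model: str, n_bins: int = N_BINS, ref_bin: int = REF_BIN
) -> tuple[np.ndarray, list[str]]:
    """Model design matrix for annotated SNPs.

    Distance bins enter as indicator columns with ``ref_bin`` omitted
    (softmax shift invariance makes one bin redundant); annotation columns
    depend on the model. ``exon_nonlast`` means exonic but not in the last
    exon.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    bins = np.asarray(ann["bin"], dtype=np.intp)
    n = len(bins)
    bin_cols = [b for b in range(n_bins) if b != ref_bin]
    X = np.zeros((n, len(bin_cols) + len(_MODEL_ANNOT[model])))
    names: list[str] = []
    for j, b in enumerate(bin_cols):
        X[:, j] = bins == b
        names.append(f"bin_{b}")
    offset = len(bin_cols)
    for j, name in enumerate(_MODEL_ANNOT[model]):
        if name == "exon_nonlast":
            col = np.asarray(ann["exon"]) & ~np.asarray(ann["last_exon"])
        else:
            col = np.asarray(ann[name])
        X[:, offset + j] = col
        names.append(name)
    return X, names


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class PositionalData:
    """Annotated candidate sets with eQTN weights, flattened for fast fitting."""

    def __init__(
        self,
        gene_ids: list[str],
        ann_frames: list[pd.DataFrame],
        weight_arrays: list[np.ndarray],
    ) -> None:
        kept_ids, kept_ann, kept_w = [], [], []
        for gid, ann, w in zip(gene_ids, ann_frames, weight_arrays):
            w = np.asarray(w, dtype=float)
            if len(ann) == 0 or len(w) != len(ann):
                warnings.warn(f"gene {gid}: empty or mismatched candidate set, excluded")
                continue
            s = w.sum()
            if s <= 0:
                warnings.warn(f"gene {gid}: zero total eQTN weight, excluded")
                continue
            kept_ids.append(gid)
            kept_ann.append(ann)
            kept_w.append(w / s)
        if not kept_ids:
            raise ValueError("no genes with candidate SNPs and eQTN weights")
        self.gene_ids = kept_ids
        self.ann = pd.concat(kept_ann, ignore_index=True)
        counts = np.array([len(a) for a in kept_ann])
        self.ptr = np.r_[0, np.cumsum(counts)]
        self.gidx = np.repeat(np.arange(len(kept_ids)), counts)
        w = np.concatenate(kept_w)
        with np.errstate(divide="ignore"):
            self.logw = np.log(w)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_mapping(
        cls,
        eqtn_weights: pd.DataFrame,
        gene_models: Mapping[str, GeneModel],
        genotypes: GenotypeMatrix,
        flank: int = 100_000,
        edges: np.ndarray = DEFAULT_BIN_EDGES,
    ) -> "PositionalData":
        """Build from an eQTN weight table (columns gene_id, snp_id, weight).

        Candidate sets are all genotyped SNPs in the gene-level cis window;
        weights are aligned onto them (SNPs absent from the weight table get
        weight 0).
        """
        gene_ids, frames, warr = [], [], []
        for gid, grp in eqtn_weights.groupby("gene_id", sort=True):
            gene = gene_models[gid]
            idx = genotypes.snps_in(
                gene.chrom, max(0, gene.span_start - flank), gene.span_end + flank
            )
            if len(idx) == 0:
                warnings.warn(f"gene {gid}: no candidate SNPs in cis window")
                continue
            ann = annotate_positions(gene, genotypes.positions[idx], edges)
            wmap = dict(zip(grp["snp_id"], grp["weight"]))
            w = np.array([wmap.get(s, 0.0) for s in genotypes.snp_ids[idx]])
            gene_ids.append(gid)
            frames.append(ann)
            warr.append(w)
        return cls(gene_ids, frames, warr)

    def design(self, model: str) -> tuple[np.ndarray, list[str]]:
        cache = getattr(self, "_design_cache", None)
        if cache is None:
            cache = {}
            self._design_cache = cache
        if model not in cache:
            cache[model] = design_matrix(self.ann, model)
        return cache[model]


def _segment_logsumexp(x: np.ndarray, ptr: np.ndarray, gidx: np.ndarray) -> np.ndarray:
    m = np.maximum.reduceat(x, ptr[:-1])
    m = np.where(np.isfinite(m), m, 0.0)  # all -inf segment guard
    e = np.exp(x - m[gidx])
    return m + np.log(np.add.reduceat(e, ptr[:-1]))


def _loglik_grad(
    lam: np.ndarray, X: np.ndarray, data: PositionalData
) -> tuple[float, np.ndarray]:
    eta = X @ lam
    logden = _segment_logsumexp(eta, data.ptr, data.gidx)
    lognum = _segment_logsumexp(eta + data.logw, data.ptr, data.gidx)
    ll = float(np.sum(lognum - logden))
    q = np.exp(eta + data.logw - lognum[data.gidx])
    pi = np.exp(eta - logden[data.gidx])
    grad = X.T @ (q - pi)
    return ll, grad


def _segment_means(
    prob: np.ndarray, X: np.ndarray, ptr: np.ndarray
) -> np.ndarray:
    """Per-gene expectations of the annotation columns under ``prob``."""
    return np.add.reduceat(prob[:, None] * X, ptr[:-1], axis=0)


def _observed_information(
    lam: np.ndarray, X: np.ndarray, data: PositionalData
) -> np.ndarray:
    """Analytic negative Hessian of the log-likelihood.

    -d2 logL/dlam2 = sum_g [ Cov_pi_g(a) - Cov_q_g(a) ] where pi is the
    softmax prior over gene g's candidates and q is the posterior over the
    tie-shared eQTN weights.
    """
    eta = X @ lam
    logden = _segment_logsumexp(eta, data.ptr, data.gidx)
    lognum = _segment_logsumexp(eta + data.logw, data.ptr, data.gidx)
    pi = np.exp(eta - logden[data.gidx])
    q = np.exp(eta + data.logw - lognum[data.gidx])
    e2_pi = X.T @ (pi[:, None] * X)
    e2_q = X.T @ (q[:, None] * X)
    mu_pi = _segment_means(pi, X, data.ptr)
    mu_q = _segment_means(q, X, data.ptr)
    cov_pi = e2_pi - mu_pi.T @ mu_pi
    cov_q = e2_q - mu_q.T @ mu_q
    return cov_pi - cov_q


def model_loglik(
    lam: np.ndarray | Sequence[float], data: PositionalData, model: str = "M3"
) -> float:
    """Log-likelihood of the weighted-multinomial positional model.

    ``lam`` is ordered as the columns of :func:`design_matrix` for ``model``.
    """
    X, names = data.design(model)
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (len(names),):
        raise ValueError(f"expected {len(names)} coefficients for {model}")
    ll, _ = _loglik_grad(lam, X, data)
    return ll


@dataclass
class PositionalModelFit:
    """Maximum-likelihood fit of one positional model."""

    model: str
    params: pd.Series
    loglik: float
    k: int
    aic: float
    cov: pd.DataFrame
    odds_ratios: pd.DataFrame
    n_genes: int
    converged: bool
    separation: bool = False


_COEF_CAP = 15.0


def fit_positional_model(
    data: PositionalData,
    model: str = "M3",
    max_iter: int = 500,
) -> PositionalModelFit:
    """Fit the positional prior by quasi-Newton optimization from lambda = 0.

    The most-upstream distance bin is the fixed reference; coefficients are
    bounded at +/-15 to cap separation (an annotation perfectly predicting
    all eQTNs), which is reported via the ``separation`` flag.
    """
    X, names = data.design(model)
    x0 = np.zeros(len(names))
    bounds = [(-_COEF_CAP, _COEF_CAP)] * len(names)

    def negll(lam: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_grad(lam, X, data)
        return -ll, -g

    res = optimize.minimize(
        negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"positional model {model} failed to converge: {res.message}")
    lam = res.x
    separation = bool(np.any(np.abs(lam) >= _COEF_CAP - 1e-6))
    if separation:
        warnings.warn(
            f"model {model}: coefficient at bound (separation); estimate capped"
        )
    ll = -res.fun
    info = _observed_information(lam, X, data)
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((len(names), len(names)), np.nan)
    k = len(names)
    aic = 2.0 * k - 2.0 * ll
    or_rows = []
    for label, contrast in _MODEL_CONTRASTS[model]:
        c = np.array([contrast.get(n, 0.0) for n in names])
        est = float(c @ lam)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        or_rows.append(
            {
                "contrast": label,
                "log_or": est,
                "se": se,
                "odds_ratio": np.exp(est),
                "ci_low": np.exp(est - 1.959964 * se),
                "ci_high": np.exp(est + 1.959964 * se),
            }
        )
    return PositionalModelFit(
        model=model,
        params=pd.Series(lam, index=names),
        loglik=ll,
        k=k,
        aic=aic,
        cov=pd.DataFrame(cov, index=names, columns=names),
        odds_ratios=pd.DataFrame(or_rows),
        n_genes=data.n_genes,
        converged=bool(res.success),
        separation=separation,
    )


def compare_models(fits: Sequence[PositionalModelFit]) -> pd.DataFrame:
    """Delta-AIC table across fits of the same data; best model has dAIC = 0."""
    n = {f.n_genes for f in fits}
    if len(n) != 1:
        raise ValueError(f"fits computed on different gene sets: n_genes={sorted(n)}")
    tab = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    )
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab["best"] = tab["delta_aic"] == 0.0
    return tab


# ---------------------------------------------------------------------------
# Fig-1-style location histogram
# ---------------------------------------------------------------------------

def position_histogram(
    eqtn_weights: pd.DataFrame,
    gene_models: Mapping[str, GeneModel],
    genotypes: GenotypeMatrix,
    outside_bin_bp: int = 10_000,
    n_inside_bins: int = 20,
    max_dist: int = 100_000,
) -> pd.DataFrame:
    """Weight-mass histogram of eQTN locations relative to their genes.

    SNPs upstream of the TSS (or downstream of the TES) fall in physical
    distance bins of ``outside_bin_bp``; SNPs inside the transcript fall
    in ``n_inside_bins`` fractional-position bins. The ``x`` coordinate
    renders the gene body at the average gene length of the data, with
    the TSS at 0.
    """
    n_out = max_dist // outside_bin_bp
    lengths = [
        gene_models[g].span_end - gene_models[g].span_start
        for g in eqtn_weights["gene_id"].unique()
    ]
    mean_len = float(np.mean(lengths)) if lengths else 0.0
    up = np.zeros(n_out)
    inside = np.zeros(n_inside_bins)
    down = np.zeros(n_out)
    for _, row in eqtn_weights.iterrows():
        gene = gene_models[row["gene_id"]]
        pos = int(genotypes.positions[genotypes.index_of(row["snp_id"])])
        w = float(row["weight"])
        if gene.contains(pos):
            span = gene.span_end - gene.span_start
            if gene.strand == "+":
                frac = (pos - gene.span_start) / span
            else:
                frac = (gene.span_end - 1 - pos) / span
            b = min(int(frac * n_inside_bins), n_inside_bins - 1)
            inside[b] += w
        else:
            d = gene.signed_tss_distance(pos)
            if d < 0:
                b = min(int((-d - 1) // outside_bin_bp), n_out - 1)
                up[n_out - 1 - b] += w
            else:
                # downstream of the gene: distance from the TES
                if gene.strand == "+":
                    dd = pos - gene.tes
                else:
                    dd = gene.tes - 1 - pos
                b = min(int(max(dd, 0) // outside_bin_bp), n_out - 1)
                down[b] += w
    rows = []
    for i, m in enumerate(up):
        x = -(n_out - i) * outside_bin_bp + outside_bin_bp / 2
        rows.append({"region": "upstream", "bin": i, "x": x, "mass": m})
    for i, m in enumerate(inside):
        x = (i + 0.5) / n_inside_bins * mean_len
        rows.append({"region": "inside", "bin": i, "x": x, "mass": m})
    for i, m in enumerate(down):
        x = mean_len + i * outside_bin_bp + outside_bin_bp / 2
        rows.append({"region": "downstream", "bin": i, "x": x, "mass": m})
    return pd.DataFrame(rows)
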