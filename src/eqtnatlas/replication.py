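"""Cross-platform replication of eQTNs at gene and exon level.

eQTNs discovered on platform A (typically the single-probe 3' platform)
are classified into five exclusive positional categories with respect to
their target gene — first, internal or last exon, intronic, or intergenic
— and then tested in platform B both against the gene-level summary and
against each exon-specific residual within 10 kb of the eQTN. If the 3'
platform's apparent gene-level QTLs in last exons are really exon-specific
QTLs, last-category eQTNs should replicate well at the exon level and
poorly at the gene level.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .mapping import EXON_WINDOW, MonomorphicError, test_association
from .models import ExpressionMatrix, GeneModel, GenotypeMatrix

__all__ = [
    "CATEGORIES",
    "classify_eqtn_category",
    "cross_platform_test",
    "qq_summary",
    "restrict_to_shared_exons",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("first", "internal", "last", "intron", "intergenic")


def classify_eqtn_category(
    position: int, gene: GeneModel, flank: int = 100_000
) -> str:
    """Positional category of an eQTN within its gene's candidate region.

    The single exon of a 1-exon gene counts as "last" (it is the exon
    ending at the TES).
    """
    if not (gene.span_start - flank <= position < gene.span_end + flank):
        raise ValueError(
            f"SNP at {position} outside candidate region of {gene.gene_id}"
        )
    idx = gene.exon_index_at(position)
    if idx is None:
        return "intron" if gene.contains(position) else "intergenic"
    if idx == gene.n_exons - 1:
        return "last"
    if idx == 0:
        return "first"
    return "internal"


def cross_platform_test(
    eqtns: pd.DataFrame,
    gene_levels: pd.DataFrame,
    exon_resid: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_models: Mapping[str, GeneModel],
    window: int = EXON_WINDOW,
) -> pd.DataFrame:
    """Test platform-A eQTNs in platform-B gene levels and exon residuals.

    ``eqtns`` needs columns ``gene_id`` and ``snp_id``. Tests run on the
    intersection of platform-B samples and genotyped samples. Each eQTN
    gets one gene-level row (flagged missing if the gene is absent from
    platform B) plus one exon-level row per platform-B exon of that gene
    within ``window`` bp of the eQTN.
    """
    samples = [s for s in gene_levels.columns if s in genotypes.samples]
    geno = genotypes.subset_samples(samples)
    resid_vals = exon_resid.values[samples]
    rows = []
    for _, e in eqtns.iterrows():
        gid, sid = e["gene_id"], e["snp_id"]
        gene = gene_models[gid]
        pos = int(geno.positions[geno.index_of(sid)])
        cat = classify_eqtn_category(pos, gene)
        g = geno.dosages[geno.index_of(sid)].astype(float)
        base = {"gene_id": gid, "snp_id": sid, "category": cat}
        if gid in gene_levels.index:
            try:
                res = test_association(gene_levels.loc[gid, samples].to_numpy(), g)
                rows.append({**base, "level": "gene", "exon_index": pd.NA,
                             "p": res.p, "missing": False})
            except MonomorphicError:
                rows.append({**base, "level": "gene", "exon_index": pd.NA,
                             "p": np.nan, "missing": True})
        else:
            rows.append({**base, "level": "gene", "exon_index": pd.NA,
                         "p": np.nan, "missing": True})
        feats = exon_resid.features
        mask = (
            (feats["gene_id"] == gid)
            & (feats["start"] - window <= pos)
            & (pos < feats["end"] + window)
        )
        for fid in feats.index[mask]:
            try:
                res = test_association(resid_vals.loc[fid].to_numpy(), g)
                rows.append({**base, "level": "exon",
                             "exon_index": int(feats.loc[fid, "exon_index"]),
                             "p": res.p, "missing": False})
            except MonomorphicError:
                continue
    tab = pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "category", "level", "exon_index",
                       "p", "missing"]
    )
    tab["exon_index"] = tab["exon_index"].astype("Int64")
    return tab


def qq_summary(pvalues: pd.Series, categories: pd.Series) -> pd.DataFrame:
    """Observed vs expected -log10 p quantiles per positional category.

    Expected quantiles use the uniform plotting positions (i - 0.5)/n.
    Empty categories are skipped with a log note; category sizes are
    preserved in the output.
    """
    out = []
    for cat in pd.unique(categories):
        p = np.sort(pvalues[categories == cat].dropna().to_numpy(float))
        if len(p) == 0:
            logger.info("category %s: no p-values, skipped", cat)
            continue
        n = len(p)
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        observed = -np.log10(np.clip(p, 1e-300, None))
        out.append(
            pd.DataFrame(
                {"category": cat, "rank": np.arange(1, n + 1),
                 "expected": expected, "observed": observed, "n": n}
            )
        )
    if not out:
        return pd.DataFrame(columns=["category", "rank", "expected", "observed", "n"])
    return pd.concat(out, ignore_index=True)


def restrict_to_shared_exons(
    features_a: pd.DataFrame, features_b: pd.DataFrame
) -> pd.Index:
    """Keep platform-A probes whose (gene, exon) also hosts a platform-B probe.

    When platform B is a 3'-biased single-probe array this filter keeps
    mainly last-exon probes of A — the probe-placement experiment.
    """
    shared = set(
        zip(features_b["gene_id"], features_b["exon_index"])
    )
    mask = [
        (g, e) in shared
        for g, e in zip(features_a["gene_id"], features_a["exon_index"])
    ]
    return features_a.index[mask]
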