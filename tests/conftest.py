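import numpy as np
import pandas as pd
import pytest

from eqtnatlas.models import ExpressionMatrix, GeneModel, GenotypeMatrix
from eqtnatlas.synthetic import (
    SimulationConfig,
    place_eqtns,
    simulate_expression,
    simulate_gene_models,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=40, n_samples={"CEU": 30, "YRI": 30}, seed=101
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small synthetic study shared by read-only tests."""
    genes = simulate_gene_models(small_config)
    geno = simulate_genotypes(small_config, genes)
    truth = place_eqtns(genes, geno, small_config)
    exons = simulate_expression(genes, geno, truth, small_config)
    return {
        "config": small_config,
        "genes": genes,
        "gene_models": {g.gene_id: g for g in genes},
        "genotypes": geno,
        "truth": truth,
        "exons": exons,
    }


@pytest.fixture
def plus_gene():
    """5-exon gene on the + strand: exons 200 bp, introns 1000 bp, TSS=10000."""
    exons = tuple(
        (10_000 + i * 1_200, 10_000 + i * 1_200 + 200) for i in range(5)
    )
    return GeneModel(gene_id="gp", chrom="chr1", strand="+", exons=exons)


@pytest.fixture
def minus_gene():
    """3-exon gene on the - strand (transcription right to left)."""
    blocks = [(20_000, 20_300), (21_000, 21_200), (22_000, 22_500)]
    return GeneModel(
        gene_id="gm", chrom="chr1", strand="-", exons=tuple(blocks[::-1])
    )


def toy_expression(values, populations=None, gene_ids=None, exon_index=None,
                   starts=None, ends=None, platform="exon_array"):
    """Hand-built ExpressionMatrix for unit tests."""
    values = np.asarray(values, float)
    f, n = values.shape
    sample_ids = [f"s{i}" for i in range(n)]
    populations = populations or ["P1"] * n
    samples = pd.DataFrame({"population": populations}, index=sample_ids)
    feature_ids = [f"f{i}" for i in range(f)]
    features = pd.DataFrame(
        {
            "gene_id": gene_ids or ["g0"] * f,
            "exon_index": exon_index if exon_index is not None else list(range(f)),
            "chrom": "chr1",
            "start": starts if starts is not None else np.arange(f) * 100,
            "end": ends if ends is not None else np.arange(f) * 100 + 50,
            "platform": platform,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    vals = pd.DataFrame(values, index=features.index, columns=sample_ids)
    return ExpressionMatrix(vals, features, samples)


def toy_genotypes(positions, dosages, samples=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(dosages.shape[1])]
    ids = [f"v{i}" for i in range(len(positions))]
    return GenotypeMatrix(ids, [chrom] * len(positions), positions, dosages,
                         samples, enforce_maf_floor=False)
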