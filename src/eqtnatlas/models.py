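"""Core data containers shared by every pipeline stage.

Coordinates are 0-based, half-open ``[start, end)`` throughout, as in BED.
Strand affects only transcription-order semantics (which exon is "first" or
"last", which span end is the TSS) — never interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneModel", "GenotypeMatrix", "ExpressionMatrix"]


@dataclass(frozen=True)
class GeneModel:
    """A gene's strand-aware coordinates and ordered exon structure.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chrom : str
        Chromosome name.
    strand : {"+", "-"}
        Transcription strand.
    exons : tuple of (int, int)
        Half-open genomic intervals in *transcription order*: ascending
        genomic coordinates on "+", descending on "-".
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) == 0:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
        # transcription order: genomic order on +, reversed on -
        genomic = exons if self.strand == "+" else exons[::-1]
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are out of "
                    f"transcription order ([{s1},{e1}) then [{s2},{e2}))"
                )
        if self.span_end - self.span_start < 1:
            raise ValueError(f"gene {self.gene_id}: transcript span < 1 bp")

    # -- span / landmarks ------------------------------------------------
    @property
    def span_start(self) -> int:
        """Genomic start (left edge) of the transcribed region."""
        return min(s for s, _ in self.exons)

    @property
    def span_end(self) -> int:
        """Genomic end (right edge, exclusive) of the transcribed region."""
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (genomic end coordinate on '-' strand)."""
        return self.span_start if self.strand == "+" else self.span_end

    @property
    def tes(self) -> int:
        """Transcription end site — the end of the last exon."""
        return self.span_end if self.strand == "+" else self.span_start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def first_exon(self) -> tuple[int, int]:
        return self.exons[0]

    @property
    def last_exon(self) -> tuple[int, int]:
        """The exon ending at the TES (the only exon for 1-exon genes)."""
        return self.exons[-1]

    # -- membership ------------------------------------------------------
    def contains(self, pos: int) -> bool:
        """Is ``pos`` within the transcribed region (half-open)?"""
        return self.span_start <= pos < self.span_end

    def exon_index_at(self, pos: int) -> int | None:
        """Transcription-order index of the exon containing ``pos``, else None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        return None

    def signed_tss_distance(self, pos: int) -> int:
        """Transcription-oriented signed distance from the TSS.

        Negative values are upstream of the gene, positive values downstream
        (into and beyond the transcript), regardless of strand.
        """
        d = pos - self.tss
        return d if self.strand == "+" else -d


class GenotypeMatrix:
    """SNP dosages for a panel of samples.

    Dosages are minor-allele counts in {0, 1, 2}, stored as an
    ``n_snps x n_samples`` integer array. SNPs are kept sorted by
    (chrom, position); the minor-allele frequency recomputed from dosages
    agrees with the stored ``maf`` to within 1/(2n). SNPs with MAF <= 0.01
    are never retained.
    """

    MAF_FLOOR = 0.01

    def __init__(
        self,
        snp_ids: Sequence[str],
        chroms: Sequence[str],
        positions: Sequence[int],
        dosages: np.ndarray,
        samples: Sequence[str],
        maf: Sequence[float] | None = None,
        enforce_maf_floor: bool = True,
    ) -> None:
        snp_ids = np.asarray(snp_ids, dtype=object)
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        dosages = np.asarray(dosages)
        if dosages.ndim != 2 or dosages.shape[0] != len(snp_ids):
            raise ValueError("dosages must be n_snps x n_samples")
        if len(samples) != dosages.shape[1]:
            raise ValueError("sample count mismatch")
        n = dosages.shape[1]
        freq = dosages.mean(axis=1) / 2.0 if n else np.zeros(len(snp_ids))
        realized_maf = np.minimum(freq, 1.0 - freq)
        if maf is None:
            maf = realized_maf
        else:
            maf = np.asarray(maf, dtype=float)
            if n and np.any(np.abs(maf - realized_maf) > 1.0 / (2 * n) + 1e-12):
                raise ValueError("stored maf inconsistent with dosages")
        keep = np.ones(len(snp_ids), dtype=bool)
        if enforce_maf_floor:
            keep &= maf > self.MAF_FLOOR
        order = np.lexsort((positions, chroms.astype(str)))
        order = order[keep[order]]
        self.snp_ids = snp_ids[order]
        self.chroms = chroms[order]
        self.positions = positions[order]
        self.dosages = np.ascontiguousarray(dosages[order])
        self.maf = np.asarray(maf)[order]
        self.samples = list(samples)
        self._chrom_slices: dict[str, slice] | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _slices(self) -> dict[str, slice]:
        if self._chrom_slices is None:
            sl: dict[str, slice] = {}
            chroms = self.chroms.astype(str)
            if len(chroms):
                bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    sl[chroms[a]] = slice(int(a), int(b))
            self._chrom_slices = sl
        return self._chrom_slices

    def snps_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of SNPs with position in the half-open [start, end)."""
        sl = self._slices().get(chrom)
        if sl is None:
            return np.array([], dtype=np.intp)
        pos = self.positions[sl]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.intp)

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if len(hits) == 0:
            raise KeyError(snp_id)
        return int(hits[0])

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(
            self.snp_ids,
            self.chroms,
            self.positions,
            self.dosages[:, idx],
            list(samples),
            enforce_maf_floor=False,
        )


FEATURE_COLUMNS = ["gene_id", "exon_index", "chrom", "start", "end", "platform"]


class ExpressionMatrix:
    """Feature-by-sample expression values plus feature/sample metadata.

    ``values`` is a features x samples DataFrame; ``features`` is indexed by
    feature id with columns gene_id, exon_index, chrom, start, end, platform;
    ``samples`` is indexed by sample id with at least a ``population`` column
    (and optionally ``sex``). Feature ids are unique and each feature maps to
    exactly one gene.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        features: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups[:5]}")
        if not values.index.equals(features.index):
            features = features.loc[values.index]
        if not values.columns.equals(samples.index):
            samples = samples.loc[values.columns]
        missing = [c for c in ("gene_id",) if c not in features.columns]
        if missing:
            raise ValueError(f"feature metadata lacks columns: {missing}")
        self.values = values
        self.features = features
        self.samples = samples

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def populations(self) -> pd.Series:
        return self.samples["population"]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(feature_ids)
        return ExpressionMatrix(
            self.values.loc[ids], self.features.loc[ids], self.samples
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = pd.Index(sample_ids)
        return ExpressionMatrix(
            self.values[ids], self.features, self.samples.loc[ids]
        )

    def for_gene(self, gene_id: str) -> "ExpressionMatrix":
        mask = self.features["gene_id"] == gene_id
        return self.subset_features(self.features.index[mask])

    def with_values(self, values: pd.DataFrame | np.ndarray) -> "ExpressionMatrix":
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(
                values, index=self.values.index, columns=self.values.columns
            )
        return ExpressionMatrix(values, self.features, self.samples)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.features.copy(), self.samples.copy()
        )
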