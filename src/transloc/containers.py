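"""Core in-memory containers shared across the analysis modules.

Genotypes are stored as alt-allele dosages (0/1/2) with ``-1`` as the
missing sentinel; epiRAD read counts are non-negative integers.  Sample
metadata (population, translocation system, source/refuge type, library
batch) travels with the matrices so that subsetting keeps everything
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["MISSING", "GenotypeMatrix", "CountMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs dosage matrix.

    Parameters
    ----------
    genotypes : int array, shape (n_individuals, n_snps)
        Alt-allele dosage 0/1/2, ``MISSING`` (=-1) for no-calls.
    samples : DataFrame
        One row per individual; must contain an ``id`` column.  Typical
        extra columns: ``population``, ``system``, ``type`` (source/refuge),
        ``batch``.
    snps : DataFrame
        One row per SNP with at least ``chrom`` and ``pos`` (1-based, as in
        VCF).  Optional: ``ref``, ``alt``, ``locus_id``.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"samples table has {len(self.samples)} rows, expected {n}")
        if len(self.snps) != m:
            raise ValueError(f"snps table has {len(self.snps)} rows, expected {m}")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.genotypes != MISSING

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency per SNP (over a row subset if given).

        SNPs with no calls in the subset get ``nan``.
        """
        g = self.genotypes if mask is None else self.genotypes[mask]
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def missing_rate_snps(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=0)

    def missing_rate_individuals(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=1)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.genotypes[:, idx], self.samples.copy(), self.snps.iloc[idx])

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.genotypes[idx], self.samples.iloc[idx], self.snps.copy())

    def subset_population(self, populations) -> "GenotypeMatrix":
        keep = self.samples["population"].isin(np.atleast_1d(populations)).to_numpy()
        return self.take_individuals(np.flatnonzero(keep))


@dataclass
class CountMatrix:
    """Individuals x epiRAD loci read-count matrix.

    ``loci`` uses 0-based half-open genomic intervals (``chrom``, ``start``,
    ``end``).  ``norm_factors`` are composition-correction factors (TMM);
    ``lib_sizes`` default to each individual's total read count.
    """

    counts: np.ndarray
    samples: pd.DataFrame
    loci: pd.DataFrame
    norm_factors: np.ndarray | None = None
    lib_sizes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (individuals x loci)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        n, m = self.counts.shape
        if len(self.samples) != n:
            raise ValueError(f"samples table has {len(self.samples)} rows, expected {n}")
        if len(self.loci) != m:
            raise ValueError(f"loci table has {len(self.loci)} rows, expected {m}")
        self.samples = self.samples.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=1).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    def effective_lib_sizes(self) -> np.ndarray:
        """Library size x normalization factor (factor 1 when unset)."""
        f = np.ones(self.n_individuals) if self.norm_factors is None else self.norm_factors
        return self.lib_sizes * f

    def take_loci(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[:, idx], self.samples.copy(), self.loci.iloc[idx],
            norm_factors=None if self.norm_factors is None else self.norm_factors.copy(),
            lib_sizes=self.lib_sizes.copy(),
        )

    def take_individuals(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[idx], self.samples.iloc[idx], self.loci.copy(),
            norm_factors=None if self.norm_factors is None else self.norm_factors[idx],
            lib_sizes=self.lib_sizes[idx],
        )

    def subset_population(self, populations) -> "CountMatrix":
        keep = self.samples["population"].isin(np.atleast_1d(populations)).to_numpy()
        return self.take_individuals(np.flatnonzero(keep))
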