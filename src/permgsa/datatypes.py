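"""Core in-memory containers shared across the analysis modules.

Genotypes are held as an ``int8`` matrix of counts of allele1 (the A1 /
usually-minor allele), with ``-1`` marking a missing call.  Sample and SNP
metadata travel as :class:`pandas.DataFrame` objects in the order of the
source ``.fam`` / ``.bim`` files; that order is never changed by readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING_GENOTYPE = -1

#: Columns of the SNP metadata frame.
SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele1", "allele2"]
#: Columns of the sample metadata frame.
SAMPLE_COLUMNS = ["fid", "iid", "phenotype"]


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive genotype matrix plus metadata.

    Parameters
    ----------
    samples
        DataFrame with columns ``fid``, ``iid``, ``phenotype``.  The
        phenotype column is float: 0.0 = control, 1.0 = case for binary
        traits, any real value for quantitative traits, NaN = missing.
    snps
        DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``,
        ``allele1``, ``allele2``.
    genotypes
        ``int8`` array of shape (n_samples, n_snps) with entries in
        {0, 1, 2, -1}; values count copies of allele1.
    binary_trait
        True when the phenotype is case/control.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    genotypes: np.ndarray
    binary_trait: bool = False

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"genotype matrix is {n}x{m} but there are "
                f"{len(self.samples)} samples and {len(self.snps)} SNPs"
            )
        vals = np.unique(self.genotypes)
        bad = set(vals.tolist()) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"genotype entries outside {{0,1,2,missing}}: {sorted(bad)}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if self.samples[["fid", "iid"]].duplicated().any():
            raise ValueError("duplicate (fid, iid) pair in samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=float)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Positional indices of ``snp_ids`` in .bim order."""
        idx = self.snp_ids.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not in dataset: {missing[:5]}")
        return idx

    def subset_snps(self, indices) -> "GenotypeDataset":
        indices = np.asarray(indices)
        return GenotypeDataset(
            samples=self.samples.reset_index(drop=True),
            snps=self.snps.iloc[indices].reset_index(drop=True),
            genotypes=self.genotypes[:, indices],
            binary_trait=self.binary_trait,
        )


@dataclass
class GeneLocation:
    """A gene interval on a chromosome; 1-based, both ends inclusive.

    ``tss``/``tes`` are stored coordinate-normalized: tss = min(start, end),
    tes = max(start, end), independent of strand.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tss < 1 or self.tes < 1:
            raise ValueError(f"{self.gene_id}: coordinates must be >= 1")
        if self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: tss > tes after normalization")


@dataclass
class GeneSetCollection:
    """Named sets of gene symbols; gene lists are deduplicated."""

    sets: dict  # set_name -> list[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"set {name!r} has duplicate genes after construction")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class SNPGeneMap:
    """Many-to-many SNP <-> gene assignment.

    ``assignments`` maps gene_id -> list of snp_id; ``reverse`` maps
    snp_id -> list of gene_id.  The two directions are kept consistent by
    construction.
    """

    assignments: dict
    reverse: dict

    @classmethod
    def from_pairs(cls, pairs) -> "SNPGeneMap":
        assignments: dict = {}
        reverse: dict = {}
        for snp_id, gene_id in pairs:
            assignments.setdefault(gene_id, []).append(snp_id)
            reverse.setdefault(snp_id, []).append(gene_id)
        return cls(assignments=assignments, reverse=reverse)

    def genes(self):
        return list(self.assignments)

    def snps_for_gene(self, gene_id: str):
        return self.assignments.get(gene_id, [])


@dataclass
class SetSNPList:
    """A gene-set resolved to a deduplicated, ordered SNP list."""

    set_name: str
    snp_ids: list
    n_genes_mapped: int
    gene_ids: list = field(default_factory=list)
    unmapped_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"{self.set_name}: duplicate snp_id in resolved list")


@dataclass
class AssociationResult:
    """Per-SNP association p-values from one genome scan."""

    pvalues: dict  # snp_id -> float p in (0,1], absent/NaN = undefined
    model: str  # "linear" | "logistic"
    n_tested: int
    n_skipped: int


@dataclass
class CovariateTable:
    """Per-sample numeric covariates keyed by (fid, iid)."""

    table: pd.DataFrame  # indexed by (fid, iid), numeric columns

    def matrix_for(self, samples: pd.DataFrame) -> np.ndarray:
        """Covariate matrix aligned to the sample order; errors on gaps."""
        key = pd.MultiIndex.from_frame(samples[["fid", "iid"]])
        missing = key.difference(self.table.index)
        if len(missing):
            raise KeyError(f"covariates missing for samples: {list(missing[:5])}")
        return self.table.loc[key].to_numpy(dtype=float)


@dataclass
class PermutationNull:
    """Null distribution of the set statistic from phenotype permutations."""

    set_name: str
    null_stats: np.ndarray  # length NPERMS, all >= 0
    m_obs: int

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if self.null_stats.ndim != 1:
            raise ValueError("null_stats must be a vector")
        if np.any(self.null_stats < 0):
            raise ValueError("null statistics must be non-negative")

    @property
    def nperms(self) -> int:
        return len(self.null_stats)


@dataclass
class GeneSetResult:
    """Result of the self-contained (and optionally competitive) test."""

    set_name: str
    statistic: float  # sum of -log10 p over the set's SNPs
    p_self: Optional[float]  # empirical self-contained p, None if undefined
    m_obs: int
    m_eff: Optional[float]
    n_genes: int = 0
    nperms: int = 0
    p_comp: Optional[float] = None
    n_draws: int = 0


@dataclass
class DrawSpec:
    """How matched random sets are drawn for the competitive test."""

    match_mode: str = "n_genes"  # "n_genes" | "eff_snps"
    n_draws: int = 100
    snp_pool: str = "intragenic"  # "intragenic" | "intergenic" | "all"
    exclude_original: bool = True
    eff_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.match_mode not in ("n_genes", "eff_snps"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.snp_pool not in ("intragenic", "intergenic", "all"):
            raise ValueError(f"unknown snp_pool {self.snp_pool!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0 < self.eff_tolerance <= 0.5):
            raise ValueError("eff_tolerance must be in (0, 0.5]")


@dataclass
class CompetitiveResult:
    """Competitive test outcome for one gene-set."""

    set_name: str
    p_orig: float
    p_randoms: np.ndarray
    p_comp: float

    def __post_init__(self) -> None:
        self.p_randoms = np.asarray(self.p_randoms, dtype=float)


@dataclass
class PanelSpec:
    """Synthetic genotype panel: LD blocks of equicorrelated SNPs."""

    n_samples: int = 1000
    n_blocks: int = 25
    snps_per_block: int = 4
    within_block_r: float = 0.0
    maf_range: tuple = (0.1, 0.5)
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class TraitSpec:
    """Phenotype model on top of a genotype panel."""

    kind: str = "quantitative"  # "quantitative" | "binary"
    causal_snps: tuple = ()
    variance_explained_per_snp: float = 0.0  # quantitative: h2 per SNP
    odds_ratio: float = 1.0  # binary logistic mode: per-allele OR
    prevalence: float = 0.5  # binary only
    binary_mode: str = "liability"  # "liability" | "logistic"

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "quantitative":
            total = self.variance_explained_per_snp * len(self.causal_snps)
            if total >= 1:
                raise ValueError(f"total variance explained {total} must be < 1")
        if self.kind == "binary" and not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
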