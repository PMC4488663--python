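"""Synthetic genotype panels, annotations, gene-sets and phenotypes.

The genotype model is a blockwise equicorrelated latent Gaussian: within
each LD block every pair of latent variables has correlation
``within_block_r``; the latent value is cut at the Hardy-Weinberg genotype
boundaries for the SNP's allele frequency (drawn uniformly from
``maf_range``), giving additive genotype counts in {0, 1, 2}.  Blocks are
independent, so the within/between-block r-squared contrast is tunable with
a single knob.  This emulates LD structure and allele-frequency spectra; it
does not emulate recombination-distance decay, allele-frequency/LD coupling
or population stratification.

Phenotypes are either quantitative (standardized genotype scores weighted
to a target per-SNP variance explained, plus Gaussian noise) or binary via
a liability threshold at the prevalence quantile (a logistic model with a
per-allele odds ratio is available as an alternative).

Everything is reproducible bit-for-bit from the spec and its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING_GENOTYPE,
    GeneLocation,
    GeneSetCollection,
    GenotypeDataset,
    PanelSpec,
    TraitSpec,
)


def simulate_genotypes(spec: PanelSpec) -> GenotypeDataset:
    """Draw a genotype panel from the blockwise latent-Gaussian model.

    Allele1 is the minor allele; its frequency per SNP is uniform in
    ``spec.maf_range``.  Missing calls are planted uniformly at
    ``spec.missing_rate``.  The phenotype column starts missing; see
    :func:`simulate_phenotype` / :func:`with_phenotype`.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, B, K = spec.n_samples, spec.n_blocks, spec.snps_per_block
    S = B * K
    maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=S)

    r = spec.within_block_r
    shared = rng.standard_normal((n, B))
    eps = rng.standard_normal((n, S))
    Z = np.sqrt(r) * np.repeat(shared, K, axis=1) + np.sqrt(1.0 - r) * eps

    # Hardy-Weinberg genotype boundaries on the latent scale
    t_hom = stats.norm.ppf(maf**2)  # below: 2 copies of the minor allele
    t_het = stats.norm.ppf(maf**2 + 2 * maf * (1 - maf))
    G = ((Z < t_hom).astype(np.int8) + (Z < t_het).astype(np.int8))

    if spec.missing_rate > 0:
        G[rng.random((n, S)) < spec.missing_rate] = MISSING_GENOTYPE

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(S)],
            "chrom": "1",
            "pos_bp": 1 + 1000 * np.arange(S),
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "phenotype": np.nan,
        }
    )
    return GenotypeDataset(samples=samples, snps=snps, genotypes=G, binary_trait=False)


def _standardized_scores(data: GenotypeDataset, snp_ids) -> np.ndarray:
    """Mean-imputed, unit-variance genotype columns for the causal SNPs."""
    idx = data.snp_indices(snp_ids)
    G = data.genotypes[:, idx].astype(float)
    G[G < 0] = np.nan
    mean = np.nanmean(G, axis=0)
    sd = np.nanstd(G, axis=0)
    if np.any(sd <= 0):
        bad = [snp_ids[i] for i in range(len(snp_ids)) if sd[i] <= 0]
        raise ValueError(f"causal SNPs with constant genotype: {bad}")
    Z = (np.where(np.isnan(G), mean, G) - mean) / sd
    return Z


def simulate_phenotype(data: GenotypeDataset, trait: TraitSpec, rng_seed: int = 0) -> np.ndarray:
    """Phenotype vector for ``data`` under the trait model.

    Quantitative: y = sum_i sqrt(v) z_i + sqrt(1 - total v) e, with z_i the
    standardized causal genotypes, so each causal SNP explains a fraction v
    of the phenotypic variance.  Binary liability mode thresholds the same
    (unit-variance) score at the prevalence quantile; logistic mode draws
    cases from a per-allele odds-ratio model with the intercept solved to
    hit the prevalence on average.
    """
    rng = np.random.default_rng(rng_seed)
    n = data.n_samples
    causal = list(trait.causal_snps)

    if trait.kind == "quantitative":
        v = trait.variance_explained_per_snp
        total = v * len(causal)
        if total >= 1:
            raise ValueError(f"total variance explained {total} must be < 1")
        y = np.sqrt(max(0.0, 1.0 - total)) * rng.standard_normal(n)
        if causal:
            Z = _standardized_scores(data, causal)
            y = y + np.sqrt(v) * Z.sum(axis=1)
        return y

    # binary
    if trait.binary_mode == "liability":
        v = trait.variance_explained_per_snp
        total = v * len(causal)
        if total >= 1:
            raise ValueError(f"total liability variance explained {total} must be < 1")
        liab = np.sqrt(max(0.0, 1.0 - total)) * rng.standard_normal(n)
        if causal:
            Z = _standardized_scores(data, causal)
            liab = liab + np.sqrt(v) * Z.sum(axis=1)
        return (liab > stats.norm.ppf(1.0 - trait.prevalence)).astype(float)

    if trait.binary_mode == "logistic":
        score = np.zeros(n)
        if causal:
            idx = data.snp_indices(causal)
            G = data.genotypes[:, idx].astype(float)
            G[G < 0] = 0.0
            score = np.log(trait.odds_ratio) * G.sum(axis=1)
        from scipy.optimize import brentq

        def mean_prob(alpha):
            return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + score))))) - trait.prevalence

        alpha = brentq(mean_prob, -30, 30)
        prob = 1.0 / (1.0 + np.exp(-(alpha + score)))
        return (rng.random(n) < prob).astype(float)

    raise ValueError(f"unknown binary_mode {trait.binary_mode!r}")


def with_phenotype(data: GenotypeDataset, phenotype: np.ndarray, binary: bool) -> GenotypeDataset:
    """Copy of ``data`` with the phenotype column replaced."""
    samples = data.samples.copy()
    samples["phenotype"] = np.asarray(phenotype, dtype=float)
    return GenotypeDataset(samples=samples, snps=data.snps, genotypes=data.genotypes,
                           binary_trait=binary)


def _gene_sizes(n_genes: int, n_genic: int, size_range: tuple, rng) -> np.ndarray:
    """Per-gene SNP counts within ``size_range`` summing exactly to n_genic."""
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError("snps_per_gene_range must satisfy 1 <= low <= high")
    if not (n_genes * lo <= n_genic <= n_genes * hi):
        raise ValueError(
            f"infeasible tiling: {n_genes} genes of {lo}-{hi} SNPs cannot cover "
            f"{n_genic} genic SNPs"
        )
    sizes = rng.integers(lo, hi + 1, size=n_genes)
    # repair the draw so the total lands exactly on n_genic
    diff = n_genic - int(sizes.sum())
    step = 1 if diff > 0 else -1
    i = 0
    while diff != 0:
        j = i % n_genes
        if lo <= sizes[j] + step <= hi:
            sizes[j] += step
            diff -= step
        i += 1
    return sizes


def make_annotation(
    data: GenotypeDataset,
    n_genes: int,
    snps_per_gene_range: tuple = (2, 8),
    intergenic_fraction: float = 0.2,
    n_sets: int = 10,
    genes_per_set: int = 10,
    causal_snps=(),
    rng_seed: int = 0,
) -> tuple[list[GeneLocation], GeneSetCollection]:
    """Tile non-overlapping genes over the panel and assemble gene-sets.

    Genes claim consecutive runs of SNPs (so each gene interval contains
    exactly its SNPs), with the requested fraction of SNPs left intergenic,
    spread evenly between genes.  Gene-sets sample genes without
    replacement; when ``causal_snps`` is given, an extra set named
    ``SET_CAUSAL`` collects the genes containing those SNPs.
    """
    rng = np.random.default_rng(rng_seed)
    snps = data.snps.sort_values("pos_bp").reset_index(drop=True)
    S = len(snps)
    n_genic = int(round((1.0 - intergenic_fraction) * S))
    sizes = _gene_sizes(n_genes, n_genic, snps_per_gene_range, rng)

    n_intergenic = S - n_genic
    gap_sizes = np.zeros(n_genes + 1, dtype=int)
    for k in range(n_intergenic):
        gap_sizes[k % (n_genes + 1)] += 1

    genes: list[GeneLocation] = []
    gene_snps: dict = {}
    cursor = 0
    for g in range(n_genes):
        cursor += gap_sizes[g]
        run = snps.iloc[cursor:cursor + sizes[g]]
        cursor += sizes[g]
        gid = f"gene{g:04d}"
        genes.append(
            GeneLocation(gene_id=gid, chrom=str(run["chrom"].iloc[0]),
                         tss=int(run["pos_bp"].min()), tes=int(run["pos_bp"].max()))
        )
        gene_snps[gid] = list(run["snp_id"])

    sets: dict = {}
    gene_ids = [g.gene_id for g in genes]
    if genes_per_set > n_genes:
        raise ValueError(f"cannot sample {genes_per_set} genes from {n_genes}")
    for k in range(n_sets):
        chosen = [gene_ids[j] for j in rng.choice(n_genes, size=genes_per_set, replace=False)]
        sets[f"SET{k:03d}"] = chosen
    if len(causal_snps):
        causal = set(causal_snps)
        carriers = [g for g in gene_ids if causal & set(gene_snps[g])]
        uncovered = causal - {s for g in carriers for s in gene_snps[g]}
        if uncovered:
            raise ValueError(f"causal SNPs not inside any gene: {sorted(uncovered)[:5]}")
        sets["SET_CAUSAL"] = carriers
    return genes, GeneSetCollection(sets=sets)
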