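"""Competitive gene-set testing against matched random draws.

A gene-set of interest is compared with randomly drawn control sets matched
either on the number of genes or on the effective number of SNPs.  Each
control set goes through the identical self-contained permutation procedure
(the same permuted phenotypes, hence one scan for the whole run), and the
competitive p-value is the fraction of draws whose self-contained empirical
p-value is strictly smaller than the original set's.

Draw pools can be restricted to intragenic SNPs (SNPs mapped to at least
one gene), intergenic SNPs (the complement), or all SNPs; the pools test
different alternative hypotheses.  Genes are sampled without replacement
within a draw and with replacement across draws, and by default the
original set's genes are excluded from every draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import selfcontained
from .datatypes import (
    CompetitiveResult,
    CovariateTable,
    DrawSpec,
    GenotypeDataset,
    PermutationNull,
    SetSNPList,
    SNPGeneMap,
)

logger = logging.getLogger(__name__)


@dataclass
class SNPPools:
    """SNP and gene pools the competitive draws sample from."""

    intragenic: list  # SNPs mapped to >= 1 gene
    intergenic: list  # the complement within the dataset
    gene_pool: list  # genes with >= 1 mapped SNP


def build_pools(snp_gene_map: SNPGeneMap, data: GenotypeDataset) -> SNPPools:
    """Partition the dataset's SNPs into intragenic/intergenic pools."""
    mapped = set(snp_gene_map.reverse)
    intragenic, intergenic = [], []
    for snp_id in data.snps["snp_id"]:
        (intragenic if snp_id in mapped else intergenic).append(snp_id)
    gene_pool = [g for g, snps in snp_gene_map.assignments.items() if snps]
    return SNPPools(intragenic=intragenic, intergenic=intergenic, gene_pool=gene_pool)


def empirical_p_competitive(p_orig: float, p_randoms) -> float:
    """Fraction of draws with a strictly smaller self-contained p-value.

    Ties do not count toward the numerator (strict inequality), unlike the
    tie-inclusive self-contained estimator; the asymmetry is deliberate.
    """
    p_randoms = np.asarray(list(p_randoms), dtype=float)
    if p_randoms.size == 0:
        raise ValueError("empty draw vector")
    return float((p_randoms < p_orig).sum() / p_randoms.size)


def draw_matched_set(
    spec: DrawSpec,
    pools: SNPPools,
    original: SetSNPList,
    snp_gene_map: SNPGeneMap | None,
    per_gene_eff: dict | None,
    rng: np.random.Generator,
    target_eff: float | None = None,
) -> SetSNPList:
    """One random control set matched to the original per ``spec``.

    n_genes mode samples exactly as many genes as the original has (without
    replacement, uniformly from the gene pool).  eff_snps mode accumulates
    uniformly sampled genes until the cumulative per-gene effective SNP
    count lands within ``spec.eff_tolerance`` (relative) of ``target_eff``;
    with the intergenic pool it accumulates individual SNPs, each counting
    one effective SNP.
    """
    if spec.snp_pool == "intergenic":
        if spec.match_mode == "n_genes":
            raise ValueError("n_genes matching needs a gene pool; intergenic SNPs have none")
        pool = [s for s in pools.intergenic if s not in set(original.snp_ids)] \
            if spec.exclude_original else list(pools.intergenic)
        if not pool:
            raise ValueError("intergenic SNP pool is empty")
        target = float(target_eff)
        lo, hi = target * (1 - spec.eff_tolerance), target * (1 + spec.eff_tolerance)
        order = rng.permutation(len(pool))
        chosen: list = []
        for j in order:
            if len(chosen) + 1 > hi:
                break
            chosen.append(pool[j])
            if len(chosen) >= lo:
                break
        if len(chosen) < lo:
            raise ValueError(
                f"intergenic pool exhausted: reached {len(chosen)} of target {target:.2f}"
            )
        return SetSNPList(set_name=f"{original.set_name}::draw", snp_ids=chosen,
                          n_genes_mapped=0)

    gene_pool = list(pools.gene_pool)
    if spec.exclude_original:
        excluded = set(original.gene_ids)
        gene_pool = [g for g in gene_pool if g not in excluded]

    if spec.match_mode == "n_genes":
        n = max(original.n_genes_mapped, 1)
        if len(gene_pool) < n:
            raise ValueError(
                f"gene pool has {len(gene_pool)} genes; cannot match {n} without replacement"
            )
        genes = [gene_pool[j] for j in rng.choice(len(gene_pool), size=n, replace=False)]
    else:  # eff_snps
        target = float(target_eff)
        lo, hi = target * (1 - spec.eff_tolerance), target * (1 + spec.eff_tolerance)
        genes, cum = [], 0.0
        # a single greedy pass can strand itself below the tolerance band
        # when every remaining gene overshoots; retry with fresh orders
        for _attempt in range(20):
            order = rng.permutation(len(gene_pool))
            genes, cum = [], 0.0
            for j in order:
                g = gene_pool[j]
                eff = per_gene_eff.get(g)
                if eff is None:
                    continue
                if cum + eff > hi:
                    continue  # would overshoot; try a smaller gene
                genes.append(g)
                cum += eff
                if cum >= lo:
                    break
            if cum >= lo:
                break
        if cum < lo:
            raise ValueError(
                f"gene pool exhausted: accumulated effective count {cum:.2f} "
                f"short of target {target:.2f} (tolerance {spec.eff_tolerance})"
            )

    snp_ids: list = []
    seen: set = set()
    for g in genes:
        for s in snp_gene_map.snps_for_gene(g):
            if s not in seen:
                seen.add(s)
                snp_ids.append(s)
    return SetSNPList(set_name=f"{original.set_name}::draw", snp_ids=snp_ids,
                      n_genes_mapped=len(genes), gene_ids=genes)


def per_gene_effective_counts(neglog: np.ndarray, pos: dict,
                              snp_gene_map: SNPGeneMap, genes) -> dict:
    """Effective SNP count per gene from singleton-gene permutation nulls."""
    out: dict = {}
    for g in genes:
        ids = [s for s in dict.fromkeys(snp_gene_map.snps_for_gene(g)) if s in pos]
        if not ids:
            continue
        cols = np.array([pos[s] for s in ids], dtype=int)
        _, null_stats, m_obs = selfcontained.set_statistics(neglog, cols)
        if m_obs == 0:
            continue
        null = PermutationNull(set_name=g, null_stats=null_stats, m_obs=m_obs)
        try:
            out[g] = selfcontained.effective_snps(null)
        except ValueError:
            continue
    return out


def run_competitive(
    data: GenotypeDataset,
    original: SetSNPList,
    spec: DrawSpec,
    snp_gene_map: SNPGeneMap,
    nperms: int,
    model: str | None = None,
    covariates: CovariateTable | None = None,
    rng_seed: int = 0,
    smoothed: bool = False,
) -> CompetitiveResult:
    """Competitive test for one gene-set.

    One permutation scan covers the original set and every pool SNP; each
    draw's self-contained p-value is then a column-sum over that shared
    -log10(p) matrix, so all draws see identical permuted phenotypes.
    """
    rng = np.random.default_rng(rng_seed)
    pools = build_pools(snp_gene_map, data)
    if spec.snp_pool == "intergenic" and not pools.intergenic:
        raise ValueError("intergenic pool requested but every SNP maps to a gene")

    data_ids = set(data.snps["snp_id"])
    if spec.snp_pool == "intergenic":
        pool_ids = [s for s in pools.intergenic if s in data_ids]
    else:
        pool_ids = [
            s for g in pools.gene_pool for s in snp_gene_map.snps_for_gene(g) if s in data_ids
        ]
    union = list(dict.fromkeys([*original.snp_ids, *pool_ids]))

    neglog, order = selfcontained.neglog10_scan_matrix(
        data, union, nperms, model=model, covariates=covariates, rng=rng
    )
    pos = {sid: i for i, sid in enumerate(order)}

    orig_cols = np.array([pos[s] for s in original.snp_ids], dtype=int)
    stat, null_stats, m_obs = selfcontained.set_statistics(neglog, orig_cols)
    if m_obs == 0:
        raise ValueError(f"set {original.set_name}: no defined p-values")
    orig_null = PermutationNull(set_name=original.set_name, null_stats=null_stats, m_obs=m_obs)
    p_orig = selfcontained.empirical_p_selfcontained(stat, orig_null, smoothed=smoothed)

    per_gene_eff: dict | None = None
    target_eff: float | None = None
    if spec.match_mode == "eff_snps" or spec.snp_pool == "intergenic":
        target_eff = selfcontained.effective_snps(orig_null)
        if spec.snp_pool != "intergenic":
            per_gene_eff = per_gene_effective_counts(neglog, pos, snp_gene_map, pools.gene_pool)

    p_randoms = np.empty(spec.n_draws)
    for d in range(spec.n_draws):
        try:
            drawn = draw_matched_set(spec, pools, original, snp_gene_map,
                                     per_gene_eff, rng, target_eff=target_eff)
        except ValueError:
            logger.error("set %s: draw %d/%d failed; partial p_randoms=%s",
                         original.set_name, d + 1, spec.n_draws, p_randoms[:d])
            raise
        cols = np.array([pos[s] for s in drawn.snp_ids], dtype=int)
        d_stat, d_null_stats, d_m = selfcontained.set_statistics(neglog, cols)
        if d_m == 0:
            p_randoms[d] = 1.0
            continue
        d_null = PermutationNull(set_name=drawn.set_name, null_stats=d_null_stats, m_obs=d_m)
        p_randoms[d] = selfcontained.empirical_p_selfcontained(d_stat, d_null, smoothed=smoothed)

    return CompetitiveResult(
        set_name=original.set_name,
        p_orig=p_orig,
        p_randoms=p_randoms,
        p_comp=empirical_p_competitive(p_orig, p_randoms),
    )
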