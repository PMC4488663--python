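"""Positional SNP-to-gene annotation and gene-set resolution.

SNPs are assigned to a gene when they fall inside [TSS - up_flank,
TES + down_flank] on the same chromosome, coordinates 1-based and both ends
inclusive (matching .bim positions and UCSC display convention).  Flanks are
capped at 100 kb.  Flanking is applied in genomic coordinates (up = the
lower-coordinate side) irrespective of strand; pass ``strand_aware=True`` to
swap the flanks for minus-strand genes instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, SetSNPList, SNPGeneMap

logger = logging.getLogger(__name__)

MAX_FLANK_BP = 100_000


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes,
    up_flank_bp: int = 0,
    down_flank_bp: int = 0,
    strand_aware: bool = False,
) -> SNPGeneMap:
    """Assign every SNP to the genes whose (flanked) interval contains it.

    Parameters
    ----------
    snps
        SNP metadata frame with ``snp_id``, ``chrom``, ``pos_bp`` columns
        (e.g. ``GenotypeDataset.snps``).
    genes
        List of :class:`~permgsa.datatypes.GeneLocation`.
    up_flank_bp, down_flank_bp
        Regulatory-region extensions in base pairs, each at most 100 kb.
    strand_aware
        Swap up/down flanks for minus-strand genes.
    """
    if up_flank_bp < 0 or down_flank_bp < 0:
        raise ValueError("flank sizes must be non-negative")
    if up_flank_bp > MAX_FLANK_BP or down_flank_bp > MAX_FLANK_BP:
        raise ValueError(
            f"flank exceeds the {MAX_FLANK_BP // 1000} kb cap: "
            f"up={up_flank_bp}, down={down_flank_bp}"
        )
    if not genes:
        raise ValueError("empty gene list")

    pairs = []
    by_chrom = {chrom: sub for chrom, sub in snps.groupby("chrom", sort=False)}
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        up, down = up_flank_bp, down_flank_bp
        if strand_aware and gene.strand == "-":
            up, down = down, up
        lo, hi = gene.tss - up, gene.tes + down
        pos = sub["pos_bp"].to_numpy()
        hit = sub["snp_id"].to_numpy()[(pos >= lo) & (pos <= hi)]
        pairs.extend((snp_id, gene.gene_id) for snp_id in hit)
    return SNPGeneMap.from_pairs(pairs)


def resolve_set_snps(set_name: str, gene_ids, snp_gene_map: SNPGeneMap) -> SetSNPList:
    """Union the SNPs of a set's member genes, each SNP counted once.

    Genes without any mapped SNP are reported as unmapped and reduce
    ``n_genes_mapped``; a SNP shared by several member genes appears once,
    in first-encounter order.
    """
    snp_ids: list = []
    seen: set = set()
    mapped_genes: list = []
    unmapped: list = []
    for gene_id in gene_ids:
        gene_snps = snp_gene_map.snps_for_gene(gene_id)
        if not gene_snps:
            unmapped.append(gene_id)
            continue
        mapped_genes.append(gene_id)
        for snp_id in gene_snps:
            if snp_id not in seen:
                seen.add(snp_id)
                snp_ids.append(snp_id)
    if unmapped:
        logger.warning("set %s: %d gene(s) with no mapped SNPs: %s",
                       set_name, len(unmapped), unmapped[:5])
    if not snp_ids:
        logger.warning("set %s resolves to zero SNPs; it will be excluded from testing",
                       set_name)
    return SetSNPList(
        set_name=set_name,
        snp_ids=snp_ids,
        n_genes_mapped=len(mapped_genes),
        gene_ids=mapped_genes,
        unmapped_genes=unmapped,
    )


def resolve_collection(collection: GeneSetCollection, snp_gene_map: SNPGeneMap,
                       drop_empty: bool = True) -> list[SetSNPList]:
    """Resolve every set in a collection; empty sets dropped with a warning."""
    resolved = []
    for name, genes in collection:
        s = resolve_set_snps(name, genes, snp_gene_map)
        if s.snp_ids or not drop_empty:
            resolved.append(s)
    return resolved


def export_map(snp_gene_map: SNPGeneMap, path) -> None:
    """Audit export of the SNP-gene assignment as a two-column TSV."""
    rows = [(snp, gene) for gene, snps in snp_gene_map.assignments.items() for snp in snps]
    pd.DataFrame(rows, columns=["snp_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def singleton_sets(snp_gene_map: SNPGeneMap) -> list[SetSNPList]:
    """One SetSNPList per gene — the gene-based test is the set engine on these."""
    return [
        SetSNPList(set_name=g, snp_ids=list(dict.fromkeys(snps)), n_genes_mapped=1, gene_ids=[g])
        for g, snps in snp_gene_map.assignments.items()
        if snps
    ]
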