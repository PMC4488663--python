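"""Self-contained gene and gene-set testing by phenotype permutation.

The set statistic is the sum of -log10 of the per-SNP association p-values
over all SNPs in the set.  Its null distribution is built by permuting the
phenotype (genotypes and covariates stay fixed) and re-running the
association scan; the empirical self-contained p-value is the fraction of
permuted statistics that equal or exceed the observed one.  The same
permuted phenotypes are shared by every set in a run, so a genome-wide run
costs one association scan per permutation.

Under the null, -log10(P) of a single SNP is 1/(2 ln 10) = 0.217 times a
chi-square with 2 df, so the sum over M independent SNPs has variance
0.189 M (0.189 = 4 * 0.217^2 = 1/ln^2 10).  Comparing that expectation with
the observed variance of the permutation null yields the effective number
of SNPs in the set, m_eff = 0.189 m_obs^2 / var(null sums): under
independence m_eff = m_obs, and LD inflates the variance, shrinking m_eff.

When only summary statistics are available, the permutation null is built
from a reference genotype panel with phenotypes simulated under the null
(independent standard-normal draws), and the observed statistic from the
user-supplied per-SNP p-values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import association
from .datatypes import CovariateTable, GeneSetResult, GenotypeDataset, PermutationNull, SetSNPList

logger = logging.getLogger(__name__)

#: -log10(P) ~ CHI2_SCALE * chi2(2 df) under the null (rounds to 0.217)
CHI2_SCALE = 1.0 / (2.0 * math.log(10.0))
#: per-SNP variance of the null sum for independent SNPs (rounds to 0.189)
VAR_COEF = 4.0 * CHI2_SCALE**2

#: below this many permutations the variance-based m_eff is unstable
MIN_PERMS_FOR_EFF = 30


def sum_neglog10(pvals) -> float:
    """Sum of -log10 over p-values in (0, 1]; empty input gives 0."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        logger.warning("empty p-value list; statistic 0")
        return 0.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.log10(p).sum())


def permute_phenotype(phenotype, rng) -> np.ndarray:
    """Uniformly random permutation of the phenotype entries.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`; the
    genotype and covariate rows are left untouched by the caller.
    """
    phenotype = np.asarray(phenotype)
    if phenotype.shape[0] < 2:
        raise ValueError("phenotype must have length >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.permutation(phenotype)


def empirical_p_selfcontained(real_stat: float, null: PermutationNull,
                              smoothed: bool = False) -> float:
    """Fraction of permuted statistics >= the observed one (ties count).

    With ``smoothed=True`` the (k+1)/(N+1) estimator is used instead, which
    cannot return an exact zero.
    """
    if null.nperms == 0:
        raise ValueError("empty permutation null")
    k = int((null.null_stats >= real_stat).sum())
    if smoothed:
        return (k + 1) / (null.nperms + 1)
    return k / null.nperms


def effective_snps(null: PermutationNull) -> float:
    """Effective number of independent SNPs from the permutation null.

    m_eff = 0.189 m_obs^2 / var(null sums), with the sample variance taken
    over permutations (N-1 denominator).  Equals m_obs when the SNPs are
    independent; smaller under LD.
    """
    if null.m_obs < 1:
        raise ValueError("m_obs must be >= 1")
    if null.nperms < 2:
        raise ValueError("need at least 2 permutations for a variance")
    if null.nperms < MIN_PERMS_FOR_EFF:
        logger.warning("set %s: m_eff from only %d permutations is unstable",
                       null.set_name, null.nperms)
    var = float(np.var(null.null_stats, ddof=1))
    if var <= 0:
        raise ValueError(f"set {null.set_name}: degenerate permutation null (zero variance)")
    return VAR_COEF * null.m_obs**2 / var


def qq_points(pvals) -> list[tuple[float, float]]:
    """(expected, observed) -log10 quantile pairs for a QQ plot.

    Observed -log10(p) sorted descending, paired with -log10(i/(n+1)) for
    ranks i = 1..n.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    obs = np.sort(-np.log10(p))[::-1]
    exp = -np.log10(np.arange(1, p.size + 1) / (p.size + 1.0))
    return list(zip(exp.tolist(), obs.tolist()))


# ---------------------------------------------------------------------------
# permutation engine

def neglog10_scan_matrix(
    data: GenotypeDataset,
    snp_ids,
    nperms: int,
    model: str | None = None,
    covariates: CovariateTable | None = None,
    rng=0,
) -> tuple[np.ndarray, list]:
    """-log10 p-value matrix of shape (1 + nperms, n_snps).

    Row 0 is the observed phenotype; rows 1..nperms are permutations drawn
    from ``rng``.  NaN marks undefined p-values.  Returns the matrix and
    the SNP id order of its columns.
    """
    model = model or association.default_model(data)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    snp_ids = list(snp_ids)
    idx = data.snp_indices(snp_ids)

    phen = data.phenotype
    keep = ~np.isnan(phen)
    y = phen[keep]
    G = data.genotypes[keep][:, idx]
    C = covariates.matrix_for(data.samples.loc[keep]) if covariates is not None else None

    Y = np.empty((1 + nperms, y.shape[0]))
    Y[0] = y
    for i in range(nperms):
        Y[1 + i] = rng.permutation(y)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(association.pvalue_matrix(G, Y, model, C))
    return neglog, snp_ids


def set_statistics(neglog: np.ndarray, col_index: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Observed statistic, null statistics and m_obs for one SNP column set.

    SNPs undefined in the observed scan are excluded from the sum and from
    m_obs; a p-value undefined only in a permuted scan is skipped in that
    permutation's sum (same exclusion rule on both sides of the comparison).
    """
    cols = np.asarray(col_index)
    sub = neglog[:, cols]
    defined = ~np.isnan(sub[0])
    sub = sub[:, defined]
    m_obs = int(defined.sum())
    if m_obs == 0:
        return 0.0, np.zeros(neglog.shape[0] - 1), 0
    stat = float(sub[0].sum())
    null_stats = np.nansum(sub[1:], axis=1)
    return stat, null_stats, m_obs


def run_selfcontained(
    data: GenotypeDataset,
    sets: list[SetSNPList],
    nperms: int,
    model: str | None = None,
    covariates: CovariateTable | None = None,
    rng_seed: int = 0,
    smoothed: bool = False,
) -> list[tuple[GeneSetResult, PermutationNull]]:
    """Self-contained test for every set, sharing one permutation scan.

    The gene-based test is the same engine applied to singleton sets (see
    :func:`permgsa.annotation.singleton_sets`).
    """
    if nperms < 1:
        raise ValueError("nperms must be >= 1")
    union: list = list(dict.fromkeys(s for st in sets for s in st.snp_ids))
    neglog, order = neglog10_scan_matrix(
        data, union, nperms, model=model, covariates=covariates, rng=rng_seed
    )
    pos = {sid: i for i, sid in enumerate(order)}

    out = []
    for st in sets:
        cols = np.array([pos[s] for s in st.snp_ids], dtype=int)
        stat, null_stats, m_obs = set_statistics(neglog, cols)
        null = PermutationNull(set_name=st.set_name, null_stats=null_stats, m_obs=m_obs)
        if m_obs == 0:
            logger.warning("set %s: no defined p-values; p_self undefined", st.set_name)
            result = GeneSetResult(
                set_name=st.set_name, statistic=0.0, p_self=None, m_obs=0,
                m_eff=None, n_genes=st.n_genes_mapped, nperms=nperms,
            )
        else:
            p_self = empirical_p_selfcontained(stat, null, smoothed=smoothed)
            try:
                m_eff = effective_snps(null)
            except ValueError:
                m_eff = None
            result = GeneSetResult(
                set_name=st.set_name, statistic=stat, p_self=p_self, m_obs=m_obs,
                m_eff=m_eff, n_genes=st.n_genes_mapped, nperms=nperms,
            )
        out.append((result, null))
    return out


# ---------------------------------------------------------------------------
# summary-statistics mode

def null_from_reference(
    reference: GenotypeDataset,
    sets: list[SetSNPList],
    nperms: int,
    rng_seed: int = 0,
    min_coverage: float = 0.5,
) -> dict:
    """Permutation-style nulls for each set from a reference panel.

    Phenotypes are simulated under the null as independent standard-normal
    draws (one vector per permutation) and scanned with the linear model on
    the reference genotypes.  SNPs absent from the panel are dropped with a
    warning; a set with less than ``min_coverage`` of its SNPs covered is
    excluded.  Returns set_name -> (PermutationNull, covered snp ids).
    """
    if nperms < 1:
        raise ValueError("nperms must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ref_ids = set(reference.snps["snp_id"])

    covered: dict = {}
    for st in sets:
        inside = [s for s in st.snp_ids if s in ref_ids]
        dropped = len(st.snp_ids) - len(inside)
        if dropped:
            logger.warning("set %s: %d/%d SNPs not in the reference panel; dropped",
                           st.set_name, dropped, len(st.snp_ids))
        if len(st.snp_ids) == 0 or len(inside) / len(st.snp_ids) < min_coverage:
            logger.error("set %s: <%d%% of SNPs covered by the reference; excluded",
                         st.set_name, int(100 * min_coverage))
            continue
        covered[st.set_name] = inside

    union = list(dict.fromkeys(s for ids in covered.values() for s in ids))
    if not union:
        return {}
    idx = reference.snp_indices(union)
    G = reference.genotypes[:, idx]
    Y = rng.standard_normal((nperms, reference.n_samples))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(association.pvalue_matrix(G, Y, "linear"))
    pos = {sid: i for i, sid in enumerate(union)}

    out = {}
    for name, ids in covered.items():
        cols = np.array([pos[s] for s in ids], dtype=int)
        sub = neglog[:, cols]
        null_stats = np.nansum(sub, axis=1)
        out[name] = (PermutationNull(set_name=name, null_stats=null_stats, m_obs=len(ids)), ids)
    return out


def run_selfcontained_summary(
    summary_pvals: dict,
    reference: GenotypeDataset,
    sets: list[SetSNPList],
    nperms: int,
    rng_seed: int = 0,
    smoothed: bool = False,
) -> list[tuple[GeneSetResult, PermutationNull]]:
    """Self-contained test from per-SNP summary p-values plus a panel.

    The observed statistic sums the supplied p-values over the set's SNPs
    that are both in the summary table and in the reference panel, so the
    observed and null statistics cover the same SNPs.
    """
    usable = [
        SetSNPList(
            set_name=st.set_name,
            snp_ids=[s for s in st.snp_ids if s in summary_pvals],
            n_genes_mapped=st.n_genes_mapped,
            gene_ids=st.gene_ids,
        )
        for st in sets
    ]
    nulls = null_from_reference(reference, usable, nperms, rng_seed=rng_seed)
    by_name = {st.set_name: st for st in usable}
    out = []
    for name, (null, ids) in nulls.items():
        st = by_name[name]
        stat = sum_neglog10([summary_pvals[s] for s in ids])
        p_self = empirical_p_selfcontained(stat, null, smoothed=smoothed)
        try:
            m_eff = effective_snps(null)
        except ValueError:
            m_eff = None
        out.append((
            GeneSetResult(set_name=name, statistic=stat, p_self=p_self,
                          m_obs=null.m_obs, m_eff=m_eff,
                          n_genes=st.n_genes_mapped, nperms=nperms),
            null,
        ))
    return out


def write_null_dump(nulls: list[PermutationNull], path) -> None:
    """Audit TSV of the permutation null: set_name, perm_index, statistic."""
    rows = [
        (null.set_name, i, stat)
        for null in nulls
        for i, stat in enumerate(null.null_stats)
    ]
    pd.DataFrame(rows, columns=["set_name", "perm_index", "statistic"]).to_csv(
        path, sep="\t", index=False
    )
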