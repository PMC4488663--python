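"""Per-SNP association testing and genotype quality control.

The per-SNP model is additive: phenotype ~ intercept [+ covariates] +
genotype count, with a Wald test on the genotype coefficient (linear
regression for quantitative traits, logistic for case/control).  Samples
with a missing genotype are dropped per SNP; samples with a missing
phenotype or missing covariates are dropped globally.

Because the permutation engine re-runs the genome scan for every permuted
phenotype, the fitters are vectorized: closed-form weighted least squares
across SNPs and permutations for the linear model, and a batched
Newton-Raphson IRLS for the logistic model (at most 100 iterations,
convergence tolerance 1e-8 on the update step; non-convergence yields an
undefined p-value).  A SNP whose genotype is constant among analyzed
samples is undefined as well.

QC follows standard GWAS practice: drop SNPs with minor allele frequency
below 0.01, Hardy-Weinberg exact-test p below 1e-5 (computed in controls
for case/control data), or per-SNP missing rate above 5%.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
from scipy import stats

from .datatypes import AssociationResult, CovariateTable, GenotypeDataset

logger = logging.getLogger(__name__)

MAX_LOGISTIC_ITER = 100
LOGISTIC_TOL = 1e-8


# ---------------------------------------------------------------------------
# quality control

def minor_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency, missing entries ignored."""
    G = np.asarray(genotypes, dtype=float)
    mask = G >= 0
    counts = np.where(mask, G, 0.0).sum(axis=0)
    n_called = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = counts / (2.0 * n_called)
    freq = np.where(n_called == 0, np.nan, freq)
    return np.minimum(freq, 1.0 - freq)


@lru_cache(maxsize=100_000)
def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over the distribution of heterozygote counts conditional on the
    observed allele counts, the probabilities no larger than that of the
    observed configuration (the standard SNP exact test).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log-probabilities of each possible het count
    from scipy.special import gammaln

    rare_hom = (n_rare - het_values) // 2
    common_hom = n - het_values - rare_hom
    logp = (
        het_values * np.log(2.0)
        - gammaln(rare_hom + 1)
        - gammaln(het_values + 1)
        - gammaln(common_hom + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[het_values == n_het][0]
    # numerical slack so that the observed configuration always counts itself
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    data: GenotypeDataset,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    missing_max: float = 0.05,
) -> GenotypeDataset:
    """Drop SNPs failing MAF, HWE exact-test, or missing-rate thresholds.

    For case/control data the HWE test is computed in controls only; for
    quantitative traits, in all samples.
    """
    for name, val in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                      ("missing_max", missing_max)):
        if not (0 <= val <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    G = data.genotypes
    n = data.n_samples

    maf = minor_allele_freq(G)
    fail_maf = ~(maf >= maf_min)  # NaN (all-missing) fails too

    miss_rate = (G < 0).sum(axis=0) / n
    fail_miss = miss_rate > missing_max

    if data.binary_trait:
        controls = data.phenotype == 0.0
        G_hwe = G[controls]
    else:
        G_hwe = G
    hwe_p = np.array([
        hwe_exact_p(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        for col in G_hwe.T
    ])
    fail_hwe = hwe_p < hwe_p_min

    keep = ~(fail_maf | fail_miss | fail_hwe)
    logger.info(
        "QC: %d/%d SNPs kept (removed: %d MAF<%g, %d HWE p<%g, %d missing>%g)",
        keep.sum(), len(keep), fail_maf.sum(), maf_min, fail_hwe.sum(), hwe_p_min,
        fail_miss.sum(), missing_max,
    )
    if not keep.any():
        raise ValueError("QC removed every SNP")
    return data.subset_snps(np.where(keep)[0])


# ---------------------------------------------------------------------------
# vectorized fitters

def _degenerate_snps(Gm: np.ndarray, m: np.ndarray, q: int) -> np.ndarray:
    """SNPs with a constant genotype among analyzed samples, or too few
    samples for q parameters.  ``Gm`` has missing entries zeroed."""
    S = Gm.shape[1]
    mean = np.divide(Gm.sum(axis=0), m, out=np.zeros(S), where=m > 0)
    mean_sq = np.divide((Gm * Gm).sum(axis=0), m, out=np.zeros(S), where=m > 0)
    gvar = mean_sq - mean * mean
    return (gvar <= 1e-12) | (m < q + 1)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def linear_scan(
    G: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Wald p-values for the genotype slope, all SNPs x all phenotype rows.

    Parameters
    ----------
    G
        (n_samples, n_snps) genotype counts, -1 = missing.
    Y
        (n_pheno, n_samples) phenotype rows (no missing values).
    covariates
        Optional (n_samples, n_cov) numeric matrix.

    Returns
    -------
    (n_pheno, n_snps) array of two-sided p-values, NaN where undefined
    (constant genotype among analyzed samples or too few samples).
    """
    G = np.asarray(G, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, S = G.shape
    X = _design(n, covariates)
    k = X.shape[1]
    q = k + 1

    M = (G >= 0).astype(float)
    Gm = G * M  # missing zeroed
    m = M.sum(axis=0)  # analyzed samples per SNP

    # per-SNP normal-equation blocks independent of the phenotype
    XtX = np.einsum("ni,ns,nj->sij", X, M, X)  # (S,k,k)
    Xtg = np.einsum("ni,ns->si", X, Gm)  # (S,k)
    gtg = (Gm * Gm).sum(axis=0)  # (S,)
    A = np.empty((S, q, q))
    A[:, :k, :k] = XtX
    A[:, :k, k] = Xtg
    A[:, k, :k] = Xtg
    A[:, k, k] = gtg

    undefined = _degenerate_snps(Gm, m, q)
    A[undefined] = np.eye(q)  # placeholder, masked out below

    with np.errstate(all="ignore"):
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
            cond_bad = np.linalg.cond(A) > 1e10
            undefined = undefined | cond_bad

    no_missing = bool((m == n).all())
    if no_missing:
        XtY = X.T @ Y.T  # (k,P)
        gtY = Gm.T @ Y.T  # (S,P)
        yty = (Y * Y).sum(axis=1)  # (P,)
        b = np.empty((q, S, Y.shape[0]))
        b[:k] = XtY[:, None, :]
        b[k] = gtY
        m_sp = np.broadcast_to(m[:, None], gtY.shape)
        yty_sp = np.broadcast_to(yty[None, :], gtY.shape)
    else:
        MY = np.einsum("ns,pn->snp", M, Y, optimize=True)  # heavy; (S,n,P)
        XtY = np.einsum("ni,snp->isp", X, MY, optimize=True)
        gtY = np.einsum("ns,pn->sp", Gm, Y)
        yty_sp = np.einsum("ns,pn->sp", M, Y * Y)
        b = np.empty((q, S, Y.shape[0]))
        b[:k] = XtY
        b[k] = gtY
        m_sp = np.broadcast_to(m[:, None], gtY.shape)

    beta = np.einsum("sij,jsp->isp", Ainv, b)  # (q,S,P)
    rss = yty_sp - np.einsum("isp,isp->sp", beta, b)
    rss = np.maximum(rss, 0.0)  # guard cancellation on (near-)exact fits
    df = m_sp - q
    with np.errstate(all="ignore"):
        sigma2 = rss / df
        var_last = Ainv[:, k, k][:, None] * sigma2
        tstat = beta[k] / np.sqrt(var_last)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)  # (S,P)
    pvals[np.isinf(tstat)] = 0.0  # exact fit: zero residual variance
    pvals[np.isnan(tstat)] = np.nan
    out = pvals.T.copy()  # (P,S)
    out[:, undefined] = np.nan
    # exact fits: p numerically 0 is reported as the smallest positive float
    out = np.where(out == 0.0, np.nextafter(0.0, 1.0), out)
    return out


def _logistic_chunk(G, Y, X, M, undefined):
    """Batched Newton-Raphson for one chunk of phenotype rows."""
    n, S = G.shape
    P = Y.shape[0]
    k = X.shape[1]
    q = k + 1
    Gz = np.where(M > 0, G, 0.0)

    beta = np.zeros((P, S, q))
    converged = np.zeros((P, S), dtype=bool)
    for _ in range(MAX_LOGISTIC_ITER):
        eta = np.einsum("ni,psi->pns", X, beta[:, :, :k]) + Gz[None] * beta[:, None, :, k]
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu) * M[None]
        R = (Y[:, :, None] - mu) * M[None]

        grad = np.empty((P, S, q))
        grad[:, :, :k] = np.einsum("ni,pns->psi", X, R)
        grad[:, :, k] = np.einsum("ns,pns->ps", Gz, R)

        H = np.empty((P, S, q, q))
        H[:, :, :k, :k] = np.einsum("ni,pns,nj->psij", X, W, X)
        Hxg = np.einsum("ni,pns,ns->psi", X, W, Gz)
        H[:, :, :k, k] = Hxg
        H[:, :, k, :k] = Hxg
        H[:, :, k, k] = np.einsum("pns,ns->ps", W, Gz * Gz)
        # tiny ridge keeps the batched solve alive on degenerate problems;
        # those end up flagged non-converged or undefined anyway
        H += 1e-10 * np.eye(q)

        try:
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("psij,psj->psi", np.linalg.pinv(H), grad)
        beta = beta + delta
        step = np.abs(delta).max(axis=2)
        newly = step < LOGISTIC_TOL
        converged = converged | newly
        if converged.all():
            break

    # final Wald statistic from the last Hessian
    with np.errstate(all="ignore"):
        Hinv_gg = np.linalg.inv(H)[:, :, k, k]
        z = beta[:, :, k] / np.sqrt(Hinv_gg)
        pvals = stats.chi2.sf(z * z, df=1)
    pvals[~converged] = np.nan
    pvals[~np.isfinite(z)] = np.nan
    pvals[:, undefined] = np.nan
    return np.where(pvals == 0.0, np.nextafter(0.0, 1.0), pvals)


def logistic_scan(
    G: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | None = None,
    chunk_elems: int = 8_000_000,
) -> np.ndarray:
    """Wald p-values from additive logistic regression, batched over SNPs
    and phenotype rows.  Same conventions as :func:`linear_scan`; phenotype
    rows must be 0/1.
    """
    G = np.asarray(G, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, S = G.shape
    X = _design(n, covariates)
    q = X.shape[1] + 1
    M = (G >= 0).astype(float)
    m = M.sum(axis=0)
    undefined = _degenerate_snps(G * M, m, q)

    P = Y.shape[0]
    rows_per_chunk = max(1, int(chunk_elems / max(1, n * S)))
    out = np.empty((P, S))
    for start in range(0, P, rows_per_chunk):
        stop = min(P, start + rows_per_chunk)
        out[start:stop] = _logistic_chunk(G, Y[start:stop], X, M, undefined)
    return out


def pvalue_matrix(
    G: np.ndarray,
    phenotypes: np.ndarray,
    model: str,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Dispatch a (n_pheno x n_snps) scan to the model-appropriate fitter."""
    if model == "linear":
        return linear_scan(G, phenotypes, covariates)
    if model == "logistic":
        return logistic_scan(G, phenotypes, covariates)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# public per-dataset interface

def _prepare(data: GenotypeDataset, covariates: CovariateTable | None):
    """Drop phenotype-missing samples; align covariates."""
    phen = data.phenotype
    keep = ~np.isnan(phen)
    C = covariates.matrix_for(data.samples.loc[keep]) if covariates is not None else None
    return data.genotypes[keep], phen[keep], C


def default_model(data: GenotypeDataset) -> str:
    return "logistic" if data.binary_trait else "linear"


def test_snp(
    data: GenotypeDataset,
    snp_index: int,
    model: str | None = None,
    covariates: CovariateTable | None = None,
) -> float | None:
    """Association p-value for one SNP; None when undefined."""
    model = model or default_model(data)
    _check_model(data, model)
    G, y, C = _prepare(data, covariates)
    p = pvalue_matrix(G[:, [snp_index]], y[None, :], model, C)[0, 0]
    return None if np.isnan(p) else float(p)


def test_all_snps(
    data: GenotypeDataset,
    model: str | None = None,
    covariates: CovariateTable | None = None,
) -> AssociationResult:
    """Association scan over every SNP in the dataset."""
    model = model or default_model(data)
    _check_model(data, model)
    G, y, C = _prepare(data, covariates)
    pv = pvalue_matrix(G, y[None, :], model, C)[0]
    ids = data.snps["snp_id"]
    pvalues = {sid: float(p) for sid, p in zip(ids, pv) if not np.isnan(p)}
    n_skipped = int(np.isnan(pv).sum())
    if n_skipped:
        logger.info("%d/%d SNPs skipped (undefined p-values)", n_skipped, len(ids))
    return AssociationResult(
        pvalues=pvalues, model=model, n_tested=len(ids) - n_skipped, n_skipped=n_skipped
    )


def _check_model(data: GenotypeDataset, model: str) -> None:
    if model == "logistic" and not data.binary_trait:
        raise ValueError("logistic model requires a case/control phenotype")
    if model == "linear" and data.binary_trait:
        raise ValueError("linear model requires a quantitative phenotype")
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
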